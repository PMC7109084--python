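# Methods

## Protonation model

Ionizable side chains (Asp, Glu, His, Tyr, Lys, Arg, Cys) are treated as
independent two-state titratable sites. Per-residue pKa values come from
external predictors, supplied as a table with one column per predictor; no
predictor is reimplemented here.

**Consensus rule.** A residue's pKa is accepted when at least two
predictors agree: the consensus value is the arithmetic mean of the largest
predictor subset that is pairwise within `agreement_tol` (default 0.5 pKa
units — the predictors' "similar values" notion is not quantified anywhere
authoritative, so 0.5 is this package's convention, roughly the typical
inter-predictor scatter for solvent-exposed sites). Ties between
equal-sized subsets go to the smaller internal spread, then to the subset
containing the lexicographically first predictor name, making the rule
deterministic and independent of dict insertion order. Residues with no
agreeing pair are flagged unresolved and must be resolved or dropped by the
caller before state assignment.

**State assignment.** At pH `ph` with margin `m` (default 0.1 pH units),
a site holds its proton iff pKa ≥ ph − m. This is the majority species of
the Henderson–Hasselbalch equilibrium with a small tolerance absorbing
predictor noise near the threshold; the margin is placed on the inclusive
(protonated) side. Charges follow the residue class: Asp/Glu 0/−1,
His +1/0, Lys/Arg +1/0, Tyr/Cys 0/−1 (protonated/deprotonated). Note the
His rule is the same inequality as for the acids — His picks up +1 when the
pH falls below its pKa — which is the direction required both by acid–base
chemistry and by the worked CD1d example (4 His protonate at pH 4.5, not at
pH 7).

**Net charge** is the sum of formal side-chain charges. Free N/C termini
(+1/−1 per chain) cancel pairwise and are excluded by default so that net
charges match side-chain-only counting (18 basic − 17 acidic = +1 for the
CD1d α1/α2 composition).

**Charge/radius maps.** For grid electrostatics, each residue's formal
charge is placed on one representative side-chain atom (Asp CG, Glu CD,
His ND1, Lys NZ, Arg CZ, Tyr OH, Cys SG); all other atoms are neutral.
Radii are element-based van der Waals values (C 1.70, N 1.55, O 1.52,
S 1.80, H 1.20 Å). This residue-level model deliberately ignores partial
charges: the pH-driven changes of interest are carried entirely by formal
charges, and a force-field charge set would add precision the rest of the
model does not support.

## Linearized Poisson–Boltzmann solver

The reduced potential u = eV/kT (V in kT/e) solves

    ∇·(ε(r) ∇u) − ε_s κ̄²(r) u = −4π l_B Σ_i q_i δ(r − r_i)

with lengths in Å and charges in units of e; l_B = e²/(4πε₀k_BT) is the
vacuum Bjerrum length (≈ 539 Å at 310 K). ε(r) is ε_protein (default 4)
inside the van der Waals atom-sphere union and ε_solvent (default 78.54)
outside — a node-center containment rule, simpler than a solvent-excluded
surface and documented as a deviation from molecular-surface-based tools.
κ̄² is the Debye parameter of a monovalent salt,
κ² [Å⁻²] = 8π (l_B/ε_s) N_A I·10⁻²⁷ with I in mol/L (≈ (8.0 Å)⁻² at
0.150 M, 310 K), zeroed inside the molecule plus a 2 Å ion-exclusion
(Stern) shell.

Numerics: 7-point finite-difference stencil with harmonic-mean face
dielectrics; point charges spread trilinearly onto their 8 surrounding
nodes; Dirichlet boundary values are a superposition of Debye–Hückel terms,
one per charge (linear in the charge vector, so the discrete solution obeys
superposition and sign symmetry exactly). Sequential focusing solves a
coarse grid spanning 1.7× the molecular extent, then the fine lattice
(129³ nodes, 0.5 Å default) with boundary values interpolated from the
coarse solution; charges outside the fine lattice contribute only through
those boundary values. The symmetric positive-definite system is solved by
diagonally preconditioned conjugate gradients to a 10⁻⁶ relative residual.
The solver is *linear* PB by design: at 0.15 M and visualization-level
potentials it reproduces the sign/shape structure that matters here;
nonlinear Picard iteration would be an extension, not a correction to any
result reported by this package.

Against closed forms (uniform dielectric, single +1 charge), the
65³-coarse → 129³-fine solve agrees with the Coulomb and screened
Debye–Hückel potentials to well under 5 % for r ∈ [5, 15] Å; refinement
tests confirm the error is discretization-dominated. The electric field is
E = −∇V by central differences (one-sided at boundaries), in (kT/e)/Å —
the field-output unit convention of this package. Grids serialize to the
OpenDX scalar dialect (z-index fastest) readable by common visualization
tools.

## Pocket detection and occupancy

A voxel lattice (default 0.8 Å) covers the molecule plus a margin. A voxel
is protein if its center lies within atom radius + probe radius (1.4 Å) of
any atom center. Two candidate criteria sit behind one interface:

- `psp_scan` (default): a solvent voxel is buried if at least
  `scan_threshold` (default 3) of the 7 scan axes through it (x, y, z and
  the four body diagonals) hit protein on *both* sides within the lattice;
  rays are unlimited, which keeps the criterion parameter-free.
- `dog`: difference of Gaussians on the solvent indicator (narrow width
  2.0 Å, ratio 1.5, response threshold 0.08): enclosed solvent responds
  positively when the narrow Gaussian still sees solvent but the wide one
  is protein-diluted.

Candidates are clustered by 26-connectivity; clusters under
`min_pocket_voxels` (30) are discarded; volume = voxel count × spacing³.
No authoritative parameter set exists for either criterion at this level of
abstraction, so all defaults are calibrated against analytic fixtures
(hollow spheres of known volume: within 15 % for radii 3–8 Å, rotation
invariance within 10 %), not recovered from any external tool.

Trajectory analyses bin every frame on the lattice of frame 0; frames
should be rigid-body aligned first (an unaligned trajectory triggers a
warning, not an error, since volume totals are still meaningful).
Occupancy(v) is the fraction of frames in which voxel v belongs to a
pocket; occupancy shells (lo, hi] partition persistence classes. Volume
time series are optionally smoothed by a Savitzky–Golay filter
(scipy, `mode="interp"` so endpoints use truncated-window polynomial fits;
default window 51 frames, order 3 — a convention, as no smoothing
parameters are authoritative).

## Gaussian network model

K = D − A on the Cα contact graph with cutoff 7.3 Å (the common Cα-GNM
default of the server family used for such analyses; configurable).
Eigenvalues/vectors from a dense symmetric eigensolver; modes with
λ < 10⁻⁸·λ_max are zero modes, and "mode 1" always means the lowest
non-zero mode. The per-residue amplitude of a mode set S is
Σ_{k∈S} u_{k,i}²/λ_k — the squared-fluctuation (1/λ) weighting; an
unweighted u² variant is switchable since plotted "amplitude" conventions
vary. The decomposition always uses the full complex; chain restriction
happens on the profile, matching the practice of computing modes in the
presence of β2-microglobulin but plotting only the α chain. Profiles are
expected to match external GNM servers in shape, not scale.

## Groove geometry

Portal aperture: per-frame Euclidean Cα–Cα distance between the flanking
residue pair, summarized as mean ± sample standard deviation. The
per-isotype default pairs ship as a bundled table (CD1a S77–N151, CD1b
F77–Y151, CD1c L77–Y152 / D80–Y155, CD1d F77–D151, CD1e F73–Y144); residue
type mismatches warn rather than fail, since author numbering varies
between depositions.

Helix bending: three Cα residue pairs define three midpoints m1, m2, m3;
the reported deviation from linearity is 180° minus the angle at m2. The
exact anchor residues used in prior work are not recoverable, so the
default convention splits a portal helix into thirds (anchors fully
configurable).

RMSD uses closed-form least-squares rigid superposition with proper
rotations only (no reflections). The 2D correspondence projection is
classical (Torgerson) metric MDS on the double-centered squared
pairwise-RMSD matrix, keeping the top two eigenvectors — a lightweight
analogue of alignment-server correspondence analysis; three structures
embed their RMSD matrix exactly.

## Synthetic data: what it emulates, and what it does not

- **Charge scenarios** encode printed ionizable-residue arithmetic: the
  composition, the set of residues whose consensus pKa lies between the
  two pH values (the "flip set"), and the reference net charges.
  Flip acids get pKa 5.5, flip His 6.0, non-flip acids 3.0–3.5, bases
  10.4–12.5; three predictor columns agree within 0.2 (seeded jitter).
  Where a full composition is not printed (GM2AP, SapA dimer), the
  composition is chosen to reproduce the printed net charges: GM2AP
  8 Asp + 7 Glu + 3 His + 4 Lys + 4 Arg (−7), SapA dimer per chain
  6 Asp + 4 Glu + 1 Lys + 1 Arg (−8 each); the His total of the CD1d
  domain equals its flip set (4) since only the flips are printed.
- **Portal scaffolds**: two ideal antiparallel α-helices (rise 1.5
  Å/residue, 100°/residue, Cα radius 2.3 Å) along x, at a given axis
  separation in y, 8 Å above a flat pseudo-atom sheet. At small
  separations the helix walls and sheet enclose a groove tunnel under the
  portal (detectable pocket on the central column); at ≥ ~20 Å the space
  is open solvent. Aperture residues sit at mid-helix.
- **Breathing trajectories**: aperture follows
  d(t) = d_∞ + (d₀ − d_∞)e^(−t/τ) + N(0, σ²) (or a stationary
  Ornstein–Uhlenbeck variant), realized by rigid translation of one helix
  along the aperture axis — so the recovered aperture equals the
  prescribed series exactly at σ = 0. Frame interval defaults to 0.04 ns
  (the 100 ns / 2,500 frame storage convention of production runs).
- **Cavity probes**: concentric Fibonacci-sphere layers of carbon
  pseudo-atoms whose probe-inflated union leaves an interior cavity of
  exactly the requested radius; construction fails loudly if a flood-fill
  leak test finds the shell unsealed at probe radius 1.4 Å.

All generators are deterministic given a seed. What passing tests on these
fixtures shows: the measurement machinery (charge accounting, field
solves, pocket volumetrics, mode algebra, geometry) is correct against
analytic and brute-force oracles. What they do not show: anything about
real conformational ensembles — the scaffolds are rigid-backbone
constructs without side-chain packing, solvent structure, or force-field
energetics, so quantities that depend on real dynamics (MD-average
apertures, real cavity-volume traces) are out of reach by design and are
not claimed.

## Pipeline

`groovescope.pipeline.run_pipeline` executes configured stages (scenario,
simulate, protonate, pbsolve, field, pockets, occupancy, gnm, geometry) in
dependency order from one YAML config, writing every output with a SHA-256
checksum into `manifest.json`. A stage failure is recorded, dependents are
skipped, and the run exits nonzero; identical config + seed gives
identical checksums for the deterministic stages.

## Problem sizes and numerical conventions

Default test and driver sizes are desk-scale by choice: PB oracles run at
33³–129³ nodes, pocket fixtures at ≤ ~45³ voxels, trajectories at
100–2,500 frames of a ~250-atom scaffold. Zero-mode tolerance 10⁻⁸
(relative), solver residual 10⁻⁶, PDB coordinate round-trip tolerance
10⁻³ Å (format precision), alignment invariance asserted at 10⁻⁹ Å.
Degenerate inputs fail with named errors: empty structures, collinear
alignment selections, coincident bend midpoints, unresolved consensus
entries, unsealed cavity shells.

## Known limitations

- Linear (not nonlinear) PB; van der Waals dielectric boundary (no
  solvent-excluded surface); two-level focusing only.
- Protonation is independent-site; no coupled titration, no structural
  relaxation on protonation, hydrogens are never built (charges live on
  heavy-atom representatives).
- Pocket criteria are deliberately parameter-light; they are calibrated to
  analytic fixtures, and absolute volumes for real proteins will differ
  from tools using other surface definitions.
- Multi-model PDB is the only trajectory format; binary formats are out of
  scope.
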