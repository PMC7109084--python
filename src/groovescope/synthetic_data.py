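"""Synthetic fixtures: pKa charge scenarios, two-helix portal scaffolds,
breathing trajectories with prescribed aperture time courses, and hollow
cavity probes of analytically known volume.

The charge scenarios encode the printed ionizable-residue arithmetic of the
systems studied (CD1d α1/α2 domain, GM2AP, the saposin-A dimer, and the
Pru p 3 allergen): which residue classes flip protonation state between
pH 7 and pH 4.5, and the resulting net charges. Scenario pKa tables carry
three concordant predictor columns so the consensus rule is exercised
end-to-end. All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import MODEL_PKA
from .protonation import PkaTable, ResidueKey
from .structure_io import AtomRecord, Structure, Trajectory

__all__ = [
    "ScenarioPreset",
    "PRESETS",
    "make_pka_scenario",
    "make_portal_scaffold",
    "make_breathing_trajectory",
    "make_cavity_probe",
    "portal_aperture_indices",
]

# consensus pKa values used for scenario construction:
#   flip Asp/Glu 5.5  -> charged at pH 7 (5.5 < 6.9), neutral at 4.5 (5.5 >= 4.4)
#   flip His     6.0  -> neutral at pH 7, +1 at pH 4.5
#   non-flip acids use values far below 4.4, bases far above 7
_FLIP_PKA = {"ASP": 5.5, "GLU": 5.5, "HIS": 6.0}
_STATIC_PKA = {"ASP": 3.0, "GLU": 3.5, "HIS": 8.5,
               "LYS": MODEL_PKA["LYS"], "ARG": MODEL_PKA["ARG"],
               "TYR": MODEL_PKA["TYR"], "CYS": MODEL_PKA["CYS"]}


@dataclass(frozen=True)
class ResidueGroup:
    chain: str
    res_name: str
    count: int
    n_flip: int = 0
    pka_override: float | None = None


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    groups: tuple[ResidueGroup, ...]
    reference_charges: tuple[int, int]   # (net at pH 7, net at pH 4.5)


PRESETS: dict[str, ScenarioPreset] = {
    # 7 Asp + 10 Glu vs 9 Lys + 9 Arg -> +1 at pH 7;
    # 1 Asp + 2 Glu + 4 His flip -> +8 at pH 4.5
    "CD1d_a1a2": ScenarioPreset("CD1d_a1a2", (
        ResidueGroup("A", "ASP", 7, n_flip=1),
        ResidueGroup("A", "GLU", 10, n_flip=2),
        ResidueGroup("A", "HIS", 4, n_flip=4),
        ResidueGroup("A", "LYS", 9),
        ResidueGroup("A", "ARG", 9),
    ), (+1, +8)),
    # net -7 at pH 7; 2 Glu + 3 His flip -> -2 at pH 4.5
    "GM2AP": ScenarioPreset("GM2AP", (
        ResidueGroup("A", "ASP", 8),
        ResidueGroup("A", "GLU", 7, n_flip=2),
        ResidueGroup("A", "HIS", 3, n_flip=3),
        ResidueGroup("A", "LYS", 4),
        ResidueGroup("A", "ARG", 4),
    ), (-7, -2)),
    # two chains, -8 each at pH 7; 6 acidic flips in chain D, 2 in chain C
    "SapA_dimer": ScenarioPreset("SapA_dimer", (
        ResidueGroup("C", "ASP", 6, n_flip=2),
        ResidueGroup("C", "GLU", 4),
        ResidueGroup("C", "LYS", 1),
        ResidueGroup("C", "ARG", 1),
        ResidueGroup("D", "ASP", 6, n_flip=4),
        ResidueGroup("D", "GLU", 4, n_flip=2),
        ResidueGroup("D", "LYS", 1),
        ResidueGroup("D", "ARG", 1),
    ), (-16, -8)),
    # single Asp with pKa < 4.0 (never protonates) + 4 Lys + 4 Arg -> +7 at both
    "PruP3": ScenarioPreset("PruP3", (
        ResidueGroup("A", "ASP", 1, pka_override=3.2),
        ResidueGroup("A", "LYS", 4),
        ResidueGroup("A", "ARG", 4),
    ), (+7, +7)),
}

# minimal heavy-atom residue templates: backbone + path to the representative
# side-chain atom, with local coordinates (Å) that keep bonded geometry sane
_SIDE_CHAINS: dict[str, list[tuple[str, str, np.ndarray]]] = {
    "ASP": [("CB", "C", np.array([0.0, 1.5, 0.0])), ("CG", "C", np.array([0.0, 2.5, 1.2]))],
    "GLU": [("CB", "C", np.array([0.0, 1.5, 0.0])), ("CG", "C", np.array([0.0, 2.5, 1.2])),
            ("CD", "C", np.array([0.0, 3.9, 1.2]))],
    "HIS": [("CB", "C", np.array([0.0, 1.5, 0.0])), ("ND1", "N", np.array([0.0, 2.6, 1.0]))],
    "LYS": [("CB", "C", np.array([0.0, 1.5, 0.0])), ("NZ", "N", np.array([0.0, 3.2, 1.8]))],
    "ARG": [("CB", "C", np.array([0.0, 1.5, 0.0])), ("CZ", "C", np.array([0.0, 3.4, 1.6]))],
    "TYR": [("CB", "C", np.array([0.0, 1.5, 0.0])), ("OH", "O", np.array([0.0, 4.2, 1.0]))],
    "CYS": [("CB", "C", np.array([0.0, 1.5, 0.0])), ("SG", "S", np.array([0.0, 2.8, 0.6]))],
    "ALA": [("CB", "C", np.array([0.0, 1.5, 0.0]))],
    "GLY": [],
}


def _residue_atoms(res_name: str, res_seq: int, chain: str, ca: np.ndarray,
                   serial0: int) -> list[AtomRecord]:
    atoms = [AtomRecord(serial0, "CA", "C", res_name, res_seq, chain, tuple(ca))]
    for i, (name, elem, off) in enumerate(_SIDE_CHAINS.get(res_name, []), start=1):
        atoms.append(AtomRecord(serial0 + i, name, elem, res_name, res_seq, chain,
                                tuple(ca + off)))
    return atoms


def make_pka_scenario(preset: str | ScenarioPreset,
                      seed: int = 0) -> tuple[Structure, PkaTable]:
    """Structure + 3-column pKa table realizing a preset's charge arithmetic.

    Within each residue group the first `n_flip` residues receive consensus
    pKa values that change their protonation state between pH 7 and pH 4.5;
    the rest sit far from both pH values. The three predictor columns agree
    within 0.2 pKa units (a small seeded jitter keeps them non-identical).
    """
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise KeyError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
        preset = PRESETS[preset]
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    entries: dict[ResidueKey, dict[str, float]] = {}
    serial = 1
    res_seq_by_chain: dict[str, int] = {}
    pos = 0
    for grp in preset.groups:
        for k in range(grp.count):
            res_seq = res_seq_by_chain.get(grp.chain, 0) + 1
            res_seq_by_chain[grp.chain] = res_seq
            ca = np.array([4.0 * pos, 0.0, 0.0])
            pos += 1
            recs = _residue_atoms(grp.res_name, res_seq, grp.chain, ca, serial)
            serial += len(recs)
            atoms.extend(recs)
            if grp.pka_override is not None:
                base = grp.pka_override
            elif k < grp.n_flip:
                base = _FLIP_PKA[grp.res_name]
            else:
                base = _STATIC_PKA[grp.res_name]
            jitter = rng.uniform(-0.05, 0.05, size=3)
            entries[ResidueKey(grp.chain, res_seq, grp.res_name)] = {
                "propka": round(base + jitter[0], 3),
                "hpp": round(base + jitter[1], 3),
                "rosetta": round(base + jitter[2], 3),
            }
    return Structure(atoms), PkaTable(entries)


# ---------------------------------------------------------------------------
# portal scaffold

_HELIX_RADIUS = 2.3     # Å, Cα helix radius
_HELIX_RISE = 1.5       # Å per residue
_HELIX_TWIST = 100.0    # degrees per residue


def _ideal_helix(n_res: int, axis_origin: np.ndarray, direction: int) -> np.ndarray:
    """Cα positions of an ideal α-helix along ±x starting at axis_origin."""
    t = np.arange(n_res)
    ang = np.radians(_HELIX_TWIST * t)
    x = axis_origin[0] + direction * _HELIX_RISE * t
    y = axis_origin[1] + _HELIX_RADIUS * np.cos(ang)
    z = axis_origin[2] + _HELIX_RADIUS * np.sin(ang)
    return np.stack([x, y, z], axis=1)


def portal_aperture_indices(n_res_per_helix: int) -> tuple[tuple[str, int], tuple[str, int]]:
    """(chain, res_seq) of the designated mid-helix aperture residues."""
    mid = n_res_per_helix // 2 + 1
    return ("A", mid), ("B", mid)


def make_portal_scaffold(separation: float, n_res_per_helix: int = 15,
                         composition: str | None = None,
                         helix_z: float = 8.0, with_sheet: bool = True) -> Structure:
    """Two antiparallel ideal α-helices over a flat pseudo-atom sheet.

    The helices run along x at axis separation `separation` in y, centered
    above a z=0 sheet of pseudo-atoms. At small separations the space
    between the helix walls and the sheet becomes an enclosed groove tunnel
    (the portal analogue); at large separations it is open to solvent.
    Residue identities come from a scenario preset name (cycled over its
    composition) or default to ALA. The designated aperture residues sit at
    mid-helix on each chain.
    """
    if separation <= 0:
        raise ValueError("separation must be > 0")
    length = (n_res_per_helix - 1) * _HELIX_RISE
    a_axis = np.array([-length / 2, -separation / 2, helix_z])
    b_axis = np.array([+length / 2, +separation / 2, helix_z])
    helixA = _ideal_helix(n_res_per_helix, a_axis, +1)
    helixB = _ideal_helix(n_res_per_helix, b_axis, -1)  # antiparallel

    res_names = ["ALA"] * (2 * n_res_per_helix)
    if composition is not None:
        preset = PRESETS[composition] if isinstance(composition, str) else composition
        seq = [g.res_name for g in preset.groups for _ in range(g.count)]
        res_names = [seq[i % len(seq)] for i in range(2 * n_res_per_helix)]

    atoms: list[AtomRecord] = []
    serial = 1
    for chain, helix in (("A", helixA), ("B", helixB)):
        for i, ca in enumerate(helix):
            rn = res_names[(0 if chain == "A" else n_res_per_helix) + i]
            recs = _residue_atoms(rn, i + 1, chain, ca, serial)
            serial += len(recs)
            atoms.extend(recs)
    if with_sheet:
        margin = 4.0
        xs = np.arange(-length / 2 - margin, length / 2 + margin + 1e-9, 2.0)
        ys = np.arange(-separation / 2 - margin, separation / 2 + margin + 1e-9, 2.0)
        res_seq = 1
        for x in xs:
            for y in ys:
                atoms.append(AtomRecord(serial, "CA", "C", "DUM", res_seq, "S",
                                        (float(x), float(y), 0.0)))
                serial += 1
                res_seq += 1
    return Structure(atoms)


def make_breathing_trajectory(scaffold: Structure, d0: float, d_inf: float,
                              tau: float, noise_sd: float, n_frames: int,
                              seed: int, frame_interval: float = 0.04,
                              model: str = "relaxation") -> Trajectory:
    """Trajectory whose aperture follows a prescribed stochastic time course.

    relaxation: d(t) = d_inf + (d0 - d_inf) exp(-t/tau) + N(0, noise_sd)
    ou:         stationary Ornstein-Uhlenbeck around d_inf starting at d0

    Realized by rigid translation of helix chain B along the line joining
    the two designated aperture Cα atoms, so the recovered aperture equals
    the prescribed series exactly when noise_sd = 0.
    """
    if n_frames < 2:
        raise ValueError("need >= 2 frames")
    n_res = max(a.res_seq for a in scaffold.atoms if a.chain_id == "A")
    (ca_chain, ca_res), (cb_chain, cb_res) = portal_aperture_indices(n_res)
    ia = scaffold.atom_index(ca_chain, ca_res, "CA")
    ib = scaffold.atom_index(cb_chain, cb_res, "CA")
    base = scaffold.coords()
    u = base[ib] - base[ia]
    d_base = np.linalg.norm(u)
    u = u / d_base

    rng = np.random.default_rng(seed)
    t = np.arange(n_frames, dtype=float)
    if model == "relaxation":
        d = d_inf + (d0 - d_inf) * np.exp(-t / tau)
        if noise_sd > 0:
            d = d + rng.normal(0.0, noise_sd, size=n_frames)
    elif model == "ou":
        d = np.empty(n_frames)
        d[0] = d0
        a = np.exp(-1.0 / tau)
        sd_step = noise_sd * np.sqrt(1 - a * a)
        shocks = rng.normal(0.0, 1.0, size=n_frames)
        for i in range(1, n_frames):
            d[i] = d_inf + (d[i - 1] - d_inf) * a + sd_step * shocks[i]
    else:
        raise ValueError(f"unknown breathing model {model!r}")

    b_mask = np.array([a.chain_id == cb_chain for a in scaffold.atoms])
    frames = []
    for dk in d:
        f = base.copy()
        f[b_mask] += (dk - d_base) * u
        frames.append(f)
    return Trajectory(scaffold, frames, frame_interval=frame_interval)


def groove_pocket_volume(pocket_set, column_halfwidth: float = 1.2) -> float:
    """Total volume (Å^3) of detected pockets on the scaffold's groove axis.

    A pocket counts as the inter-helix groove when it owns a voxel on the
    vertical column through the scaffold center (|x|, |y| < halfwidth); the
    shallow helix/sheet corner concavities found at large separations never
    reach that column.
    """
    lat = pocket_set.lattice
    total = 0.0
    for p in pocket_set.pockets:
        xyz = lat.origin + lat.spacing * p.voxels
        on_axis = (np.abs(xyz[:, 0]) < column_halfwidth) & \
                  (np.abs(xyz[:, 1]) < column_halfwidth)
        if on_axis.any():
            total += p.volume
    return total


# ---------------------------------------------------------------------------
# cavity probe

_PROBE_ATOM_RADIUS = 1.7   # carbon pseudo-atoms
_PROBE_SOLVENT = 1.4       # probe radius assumed by the seal construction


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def make_cavity_probe(r_cavity: float, r_shell: float,
                      atom_spacing: float = 1.2) -> Structure:
    """Hollow pseudo-atom shell with an interior cavity of radius r_cavity.

    Atom centers are laid on concentric Fibonacci-sphere layers starting at
    r_cavity + atom_radius + probe_radius, so the probe-inflated atom union
    leaves a spherical cavity of the requested radius. Raises if the shell
    is not sealed against a 1.4 Å probe (leak test by flood fill).
    """
    if not r_shell > r_cavity > 0:
        raise ValueError("need r_shell > r_cavity > 0")
    if atom_spacing > 2.0:
        raise ValueError("atom_spacing must be <= 2 Å to seal the shell")
    r_inner = r_cavity + _PROBE_ATOM_RADIUS + _PROBE_SOLVENT
    thickness = r_shell - r_cavity
    n_layers = max(2, int(np.ceil(thickness / atom_spacing)) + 1)
    radii = np.linspace(r_inner, r_inner + thickness, n_layers)
    atoms: list[AtomRecord] = []
    serial = 1
    for li, R in enumerate(radii):
        n = max(12, int(np.ceil(4 * np.pi * R * R / atom_spacing ** 2)))
        # offset alternate layers so gaps do not align radially
        pts = _fibonacci_sphere(n) * R
        if li % 2:
            ang = atom_spacing / R
            c, s = np.cos(ang), np.sin(ang)
            rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            pts = pts @ rot.T
        for p in pts:
            atoms.append(AtomRecord(serial, "CA", "C", "DUM", serial, "P" if serial <= 9999 else "Q",
                                    tuple(p)))
            serial += 1
    probe = Structure(atoms)
    _check_sealed(probe, r_cavity)
    return probe


def _check_sealed(probe: Structure, r_cavity: float) -> None:
    """Flood-fill leak test: the central cavity must not reach the boundary."""
    from scipy import ndimage

    from .pocket_dynamics import Lattice, PocketConfig, _protein_mask
    cfg = PocketConfig(spacing=0.8)
    coords = probe.coords()
    radii = np.full(len(coords), _PROBE_ATOM_RADIUS)
    lat = Lattice.around(coords, radii, cfg)
    protein = _protein_mask(lat, coords, radii, cfg.probe_radius)
    labels, _ = ndimage.label(~protein)
    center_lab = labels[tuple(lat.index_of(np.zeros(3)))]
    if center_lab == 0:
        raise ValueError("cavity center classified as protein; shell too thick/tight")
    border = np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
    ])
    if center_lab in border:
        raise ValueError("cavity shell is not sealed at probe radius 1.4 Å "
                         "(interior connects to bulk solvent)")
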