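"""Structures and multi-model trajectories: PDB reading/writing, domain
selection, rigid-body frame alignment and PQR output.

The atom model is a flat ordered list of records (chain -> residue -> atom
order as in the file). Multi-model PDB files are the only trajectory format:
each MODEL block becomes one frame over the shared topology of model 1.
Author residue numbering is authoritative throughout; no renumbering.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .params import element_radius

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "ParseError",
    "read_structure",
    "write_pdb",
    "select_domain",
    "align_frames",
    "write_pqr",
    "superpose",
]


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    temp_factor: float = 0.0
    icode: str = ""
    het: bool = False

    def __post_init__(self):
        if not self.element:
            raise ValueError(f"atom {self.name} has empty element symbol")
        if not all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name} has non-finite coordinates")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain, res_seq[+icode], res_name) key; insertion code folded in."""
        seq = self.res_seq if not self.icode else f"{self.res_seq}{self.icode}"
        return (self.chain_id, seq, self.res_name)


@dataclass
class Structure:
    atoms: list[AtomRecord]
    model_id: int = 1

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, xyz=tuple(p)) for a, p in zip(self.atoms, xyz)]
        return Structure(atoms, self.model_id)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self) -> list[tuple[str, int, str]]:
        """Residue keys in file order (no duplicates)."""
        seen: dict[tuple, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def atom_index(self, chain_id: str, res_seq: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain_id == chain_id and a.res_seq == res_seq and a.name == name:
                return i
        raise KeyError(f"no atom {name} in residue {chain_id}:{res_seq}")

    def select_indices(self, chain: str | None = None,
                       res_range: tuple[int, int] | None = None,
                       names: tuple[str, ...] | None = None) -> np.ndarray:
        idx = []
        for i, a in enumerate(self.atoms):
            if chain is not None and a.chain_id != chain:
                continue
            if res_range is not None and not res_range[0] <= a.res_seq <= res_range[1]:
                continue
            if names is not None and a.name not in names:
                continue
            idx.append(i)
        return np.array(idx, dtype=int)


@dataclass
class Trajectory:
    topology: Structure
    frames: list[np.ndarray]
    frame_interval: float = 0.04  # ns between stored frames
    aligned: bool = field(default=False, compare=False)

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        n = len(self.topology)
        for k, f in enumerate(self.frames):
            if np.asarray(f).shape != (n, 3):
                raise ValueError(f"frame {k} does not match topology atom count {n}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> Structure:
        s = self.topology.with_coords(self.frames[i])
        s.model_id = i + 1
        return s

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


# ---------------------------------------------------------------------------
# PDB reading

def _prescan_pdb(text: str) -> int:
    """Validate fixed-width ATOM/HETATM records; return atom-record count.

    Raises ParseError naming the 1-based line number of the first bad record.
    """
    n = 0
    for ln, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        n += 1
        if len(line) < 54:
            raise ParseError(f"line {ln}: truncated {rec} record")
        try:
            int(line[6:11])
            int(line[22:26])
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise ParseError(f"line {ln}: malformed fixed-width field ({exc})") from None
    return n


def _pick_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties broken toward altloc 'A'."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        key = (-atom.occ, atom.altloc or "A")
        prev_key = (-prev.occ, prev.altloc or "A")
        if key < prev_key:
            by_name[atom.name] = atom
    return list(by_name.values())


def read_structure(pdb_text: str, frame_interval: float = 0.04) -> Trajectory:
    """Parse PDB text into a Trajectory (one frame per MODEL block).

    Files without MODEL records yield a single frame. HETATM records are
    retained and flagged. Alternate locations are collapsed to the
    highest-occupancy conformer.
    """
    if _prescan_pdb(pdb_text) == 0:
        raise ParseError("no ATOM/HETATM records in input")
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ParseError("no models parsed from input")

    def model_atoms(model: gemmi.Model) -> list[AtomRecord]:
        out = []
        for chain in model:
            for res in chain:
                het = res.het_flag == "H"
                for atom in _pick_altloc(res):
                    out.append(AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element.name or atom.name[:1],
                        res_name=res.name,
                        res_seq=res.seqid.num,
                        chain_id=chain.name,
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=atom.occ,
                        temp_factor=atom.b_iso,
                        icode=(res.seqid.icode or "").strip(),
                        het=het,
                    ))
        return out

    topo_atoms = model_atoms(st[0])
    topology = Structure(topo_atoms, model_id=1)
    frames = [topology.coords()]
    for model in list(st)[1:]:
        recs = model_atoms(model)
        if len(recs) != len(topo_atoms):
            raise ParseError(
                f"model {model.num} has {len(recs)} atoms, topology has {len(topo_atoms)}"
            )
        frames.append(np.array([a.xyz for a in recs], dtype=float))
    return Trajectory(topology, frames, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# PDB writing

def _pdb_atom_line(a: AtomRecord, serial: int) -> str:
    rec = "HETATM" if a.het else "ATOM"
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    x, y, z = a.xyz
    return (f"{rec:<6s}{serial:>5d} {name:<4s} {a.res_name:<3s} {a.chain_id:1s}"
            f"{a.res_seq:>4d}{a.icode or ' ':1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{a.occupancy:6.2f}{a.temp_factor:6.2f}          {a.element:>2s}")


def write_pdb(obj: Structure | Trajectory) -> str:
    """Serialize a Structure or Trajectory as (multi-model) PDB text."""
    if isinstance(obj, Structure):
        frames = [obj.coords()]
        topo = obj
    else:
        frames, topo = obj.frames, obj.topology
    out = io.StringIO()
    multi = len(frames) > 1
    for m, xyz in enumerate(frames, start=1):
        if multi:
            out.write(f"MODEL     {m:>4d}\n")
        for i, (a, p) in enumerate(zip(topo.atoms, xyz), start=1):
            out.write(_pdb_atom_line(replace(a, xyz=tuple(p)), i) + "\n")
        if multi:
            out.write("ENDMDL\n")
    out.write("END\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Selections and alignment

def select_domain(s: Structure, chain: str, res_range: tuple[int, int]) -> Structure:
    """Atoms of `chain` with author residue number in the inclusive range."""
    if chain not in s.chains():
        raise KeyError(f"chain {chain!r} not present (have {s.chains()})")
    lo, hi = res_range
    atoms = [a for a in s.atoms if a.chain_id == chain and lo <= a.res_seq <= hi]
    if not atoms:
        raise ValueError(f"empty selection: chain {chain} residues {lo}-{hi}")
    return Structure(atoms, s.model_id)


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None):
    """Least-squares rigid superposition of `mobile` onto `reference`.

    Returns (R, t, rmsd): proper rotation matrix, translation, and the
    post-fit RMSD. Reflections are excluded.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc, weights=weights)
    R = rot.as_matrix()
    moved = (mobile - mc) @ R.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return R, rc - mc @ R.T, rmsd


def _check_not_collinear(xyz: np.ndarray) -> None:
    if len(xyz) < 3:
        raise ValueError("alignment selection needs >= 3 atoms")
    centered = xyz - xyz.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("alignment selection is (near-)collinear")


def align_frames(t: Trajectory, selection: np.ndarray) -> Trajectory:
    """Superpose every frame onto frame 0 over the atom-index `selection`."""
    selection = np.asarray(selection, dtype=int)
    ref = t.frames[0][selection]
    _check_not_collinear(ref)
    new_frames = [t.frames[0].copy()]
    for f in t.frames[1:]:
        R, trans, _ = superpose(f[selection], ref)
        new_frames.append(f @ R.T + trans)
    out = Trajectory(t.topology, new_frames, frame_interval=t.frame_interval)
    out.aligned = True
    return out


# ---------------------------------------------------------------------------
# PQR

def write_pqr(s: Structure, charges, radii) -> str:
    """Whitespace-delimited PQR: occupancy/B-factor replaced by charge/radius.

    `charges` and `radii` are sequences over s.atoms (e and Å). The summed
    written charge matches the input sum to the printed precision (4 d.p.).
    """
    charges = np.asarray(charges, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if charges.shape != (len(s),) or radii.shape != (len(s),):
        raise ValueError("charges/radii must cover every atom exactly once")
    bad = np.flatnonzero(~np.isfinite(charges) | ~np.isfinite(radii))
    if bad.size:
        a = s.atoms[bad[0]]
        raise ValueError(f"missing charge/radius for atom {a.chain_id}:{a.res_seq}:{a.name}")
    if np.any(radii <= 0):
        raise ValueError("all radii must be > 0")
    lines = []
    for i, a in enumerate(s.atoms):
        rec = "HETATM" if a.het else "ATOM"
        x, y, z = a.xyz
        lines.append(f"{rec} {i + 1} {a.name} {a.res_name} {a.chain_id} {a.res_seq} "
                     f"{x:.3f} {y:.3f} {z:.3f} {charges[i]:.4f} {radii[i]:.4f}")
    return "\n".join(lines) + "\n"


def read_pqr(text: str) -> tuple[Structure, np.ndarray, np.ndarray]:
    """Read the whitespace-delimited PQR dialect written by write_pqr."""
    atoms, charges, radii = [], [], []
    for ln, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if not parts or parts[0] not in ("ATOM", "HETATM"):
            continue
        if len(parts) != 11:
            raise ParseError(f"line {ln}: expected 11 whitespace-separated PQR fields")
        _, serial, name, resn, chain, resseq, x, y, z, q, r = parts
        atoms.append(AtomRecord(
            serial=int(serial), name=name, element=name[:1], res_name=resn,
            res_seq=int(resseq), chain_id=chain,
            xyz=(float(x), float(y), float(z)), het=parts[0] == "HETATM",
        ))
        charges.append(float(q))
        radii.append(float(r))
    if not atoms:
        raise ParseError("no atoms in PQR input")
    return Structure(atoms), np.array(charges), np.array(radii)


def default_radii(s: Structure) -> np.ndarray:
    """Element-based van der Waals radii for every atom."""
    return np.array([element_radius(a.element) for a in s.atoms])
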