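"""Groove geometry along trajectories: portal aperture, helix bending,
RMSD traces and a classical-MDS projection of pairwise RMSD matrices.

The portal aperture is the Cα-Cα distance between one residue on each of
the two helices flanking the groove entrance (e.g. F77 on α1 and D151 on α2
of CD1d). Helix bending is measured from three midpoints of Cα pairs placed
along a helix: the deviation from linearity, 180° minus the angle at the
central midpoint. Default aperture pairs per CD1 isotype ship as a bundled
table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .pocket_dynamics import TimeSeries
from .structure_io import Structure, Trajectory, superpose

__all__ = [
    "AperturePair",
    "BendAnchors",
    "aperture_trace",
    "bend_angle_trace",
    "rmsd_trace",
    "rmsd_mds",
    "isotype_aperture_pairs",
]


@dataclass(frozen=True)
class AperturePair:
    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    expected_a: str | None = None   # residue codes for sanity warnings
    expected_b: str | None = None


@dataclass(frozen=True)
class BendAnchors:
    """Three Cα residue pairs; each pair's midpoint is one bending anchor."""
    pairs: tuple[tuple[tuple[str, int], tuple[str, int]], ...]

    def __post_init__(self):
        if len(self.pairs) != 3:
            raise ValueError("bend anchors need exactly 3 residue pairs")
        flat = [r for pair in self.pairs for r in pair]
        if len(set(flat)) != 6:
            raise ValueError("the six anchor residues must be distinct")


def isotype_aperture_pairs() -> dict[str, AperturePair]:
    """Bundled per-isotype aperture residue pairs (chain left generic 'A')."""
    with resources.files("groovescope.data").joinpath("aperture_pairs.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    out = {}
    for _, row in df.iterrows():
        out[row["isotype"]] = AperturePair(
            "A", int(row["res_a"]), "A", int(row["res_b"]),
            expected_a=row["resname_a"], expected_b=row["resname_b"],
        )
    return out


def _ca_index(topo: Structure, chain: str, res_seq: int, expected: str | None = None) -> int:
    import warnings
    try:
        idx = topo.atom_index(chain, res_seq, "CA")
    except KeyError:
        raise KeyError(f"residue {chain}:{res_seq} has no Cα atom in topology") from None
    if expected is not None and topo.atoms[idx].res_name != expected:
        warnings.warn(f"residue {chain}:{res_seq} is {topo.atoms[idx].res_name}, "
                      f"expected {expected}", stacklevel=3)
    return idx


def aperture_trace(t: Trajectory, pair: AperturePair) -> TimeSeries:
    """Per-frame Euclidean Cα-Cα distance of the aperture pair (Å)."""
    ia = _ca_index(t.topology, pair.chain_a, pair.res_a, pair.expected_a)
    ib = _ca_index(t.topology, pair.chain_b, pair.res_b, pair.expected_b)
    d = np.array([np.linalg.norm(f[ia] - f[ib]) for f in t.frames])
    return TimeSeries(t.times(), d, units="Å")


def bend_angle_trace(t: Trajectory, anchors: BendAnchors) -> TimeSeries:
    """Deviation from helix linearity (degrees): 180° minus the midpoint angle."""
    idx = [[_ca_index(t.topology, c, r) for (c, r) in pair] for pair in anchors.pairs]
    out = []
    for f in t.frames:
        m1, m2, m3 = (0.5 * (f[i] + f[j]) for i, j in idx)
        v1, v2 = m1 - m2, m3 - m2
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 < 1e-9 or n2 < 1e-9:
            raise ValueError("coincident bend anchors: angle undefined")
        cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
        out.append(180.0 - np.degrees(np.arccos(cosang)))
    return TimeSeries(t.times(), np.array(out), units="deg")


def _pair_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    _, _, rmsd = superpose(a, b)
    return rmsd


def rmsd_trace(t: Trajectory, reference: Structure, selection: np.ndarray,
               ref_selection: np.ndarray | None = None) -> TimeSeries:
    """Per-frame RMSD (Å) over `selection` after optimal rigid superposition."""
    selection = np.asarray(selection, int)
    ref_selection = selection if ref_selection is None else np.asarray(ref_selection, int)
    if len(selection) != len(ref_selection):
        raise ValueError("selection sizes differ between trajectory and reference")
    ref = reference.coords()[ref_selection]
    vals = [_pair_rmsd(f[selection], ref) for f in t.frames]
    return TimeSeries(t.times(), np.array(vals), units="Å")


def rmsd_mds(structures: list[Structure], selection: np.ndarray) -> np.ndarray:
    """Classical (Torgerson) MDS of the pairwise superposed-RMSD matrix.

    Returns (n, 2) coordinates; similar structures land near each other.
    Three structures embed their RMSD matrix exactly (any 3-point metric is
    planar).
    """
    if len(structures) < 3:
        raise ValueError("need >= 3 structures")
    selection = np.asarray(selection, int)
    coords = []
    for s in structures:
        c = s.coords()
        if selection.max() >= len(c):
            raise ValueError("selection exceeds atom count of a structure")
        coords.append(c[selection])
    n = len(coords)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _pair_rmsd(coords[i], coords[j])
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, v = w[order[:2]], v[:, order[:2]]
    return v * np.sqrt(np.clip(w, 0, None))
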