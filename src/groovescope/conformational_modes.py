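"""Gaussian network model (GNM) normal modes.

The GNM represents a protein as its Cα contact graph: residues i, j are
connected when their Cα atoms lie within a cutoff distance (default 7.3 Å).
The Kirchhoff (graph-Laplacian) matrix K = D - A is eigendecomposed; the
low-frequency non-zero modes describe the dominant collective fluctuations,
with per-residue squared amplitudes weighted by 1/eigenvalue. Modes are
computed on the full deposited complex; profiles can be restricted to one
chain afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .structure_io import Structure

__all__ = ["KirchhoffMatrix", "ModeSet", "build_kirchhoff", "gnm_modes", "mode_profile"]

ZERO_MODE_RTOL = 1e-8


@dataclass
class KirchhoffMatrix:
    matrix: np.ndarray                  # (n, n) symmetric Laplacian
    cutoff: float                       # Å
    labels: list[tuple[str, int]]       # (chain, res_seq) per Cα node

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ModeSet:
    eigenvalues: np.ndarray             # ascending
    eigenvectors: np.ndarray            # columns, orthonormal
    n_zero: int
    labels: list[tuple[str, int]]

    def nonzero_mode(self, k: int) -> tuple[float, np.ndarray]:
        """1-based index over non-zero modes (mode 1 = lowest non-zero)."""
        n_nonzero = len(self.eigenvalues) - self.n_zero
        if not 1 <= k <= n_nonzero:
            raise IndexError(f"mode {k} out of range (have {n_nonzero} non-zero modes)")
        i = self.n_zero + k - 1
        return float(self.eigenvalues[i]), self.eigenvectors[:, i]


def build_kirchhoff(s: Structure, cutoff: float = 7.3) -> KirchhoffMatrix:
    """Cα contact Laplacian: K[i,j] = -1 for contacts within cutoff, row sums 0."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    ca_idx = s.select_indices(names=("CA",))
    for chain in s.chains():
        if not any(s.atoms[i].chain_id == chain for i in ca_idx):
            raise ValueError(f"chain {chain!r} has no Cα atoms")
    if len(ca_idx) < 2:
        raise ValueError("need >= 2 Cα atoms")
    coords = s.coords()[ca_idx]
    labels = [(s.atoms[i].chain_id, s.atoms[i].res_seq) for i in ca_idx]
    dists = squareform(pdist(coords))
    adj = (dists <= cutoff) & ~np.eye(len(ca_idx), dtype=bool)
    K = np.diag(adj.sum(axis=1)).astype(float) - adj.astype(float)
    return KirchhoffMatrix(K, cutoff, labels)


def gnm_modes(k: KirchhoffMatrix, n_modes: int | None = None) -> ModeSet:
    """Ascending eigenpairs of the Kirchhoff matrix; zero modes identified.

    `n_modes` limits the number of *non-zero* modes retained (all zero modes
    are always kept so that indexing stays anchored at mode 1).
    """
    try:
        w, v = eigh(k.matrix)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise RuntimeError(f"eigendecomposition failed: {exc}") from exc
    w = np.clip(w, -1e-9, None)
    lam_max = max(w[-1], 1e-30)
    n_zero = int(np.sum(w < ZERO_MODE_RTOL * lam_max))
    if n_modes is not None:
        keep = n_zero + n_modes
        w, v = w[:keep], v[:, :keep]
    return ModeSet(w, v, n_zero, k.labels)


def mode_profile(m: ModeSet, mode_indices: list[int], chain: str | None = None,
                 weighted: bool = True) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Per-residue amplitude of the selected non-zero modes (1-based indices).

    amplitude_i = sum_k u_{k,i}^2 / lambda_k (squared-fluctuation convention);
    `weighted=False` drops the 1/lambda factor. Returns (labels, amplitudes),
    restricted to `chain` if given; the decomposition itself always uses the
    full complex.
    """
    amp = np.zeros(len(m.labels))
    for k in mode_indices:
        lam, u = m.nonzero_mode(k)
        amp += u ** 2 / lam if weighted else u ** 2
    if chain is None:
        return list(m.labels), amp
    sel = [i for i, (c, _) in enumerate(m.labels) if c == chain]
    if not sel:
        raise ValueError(f"no residues on chain {chain!r}")
    return [m.labels[i] for i in sel], amp[sel]
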