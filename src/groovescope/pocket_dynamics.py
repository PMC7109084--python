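"""Grid-based pocket detection and trajectory occupancy analysis.

Two detection criteria behind one interface:

``psp_scan`` (default) — LIGSITE-style protein-solvent-protein scanning: a
solvent voxel is a pocket candidate when at least `scan_threshold` of the 7
scan axes through it (x, y, z and the four body diagonals) hit protein on
*both* sides within the lattice. Rays are unlimited (they terminate at the
lattice boundary).

``dog`` — difference-of-Gaussians on the solvent indicator: enclosed solvent
responds positively when a narrow Gaussian sees mostly solvent but a wider
one is already protein-diluted; candidates are solvent voxels above a fixed
response threshold.

Candidates are clustered by 26-connectivity; clusters below
`min_pocket_voxels` are discarded. Trajectory analyses bin every frame on
the lattice of frame 0 (frames must be pre-aligned for per-voxel occupancy
to be meaningful).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import savgol_filter

from .structure_io import Structure, Trajectory, default_radii

__all__ = [
    "PocketConfig",
    "Pocket",
    "PocketSet",
    "OccupancyGrid",
    "TimeSeries",
    "Lattice",
    "detect_pockets",
    "volume_trace",
    "occupancy_grid",
    "occupancy_shell",
    "savitzky_golay",
]

_SCAN_AXES = np.array([
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 1), (1, -1, 1), (1, 1, -1), (1, -1, -1),
], dtype=int)


@dataclass
class PocketConfig:
    spacing: float = 0.8          # Å voxel edge
    probe_radius: float = 1.4     # Å solvent probe
    scan_threshold: int = 3       # of the 7 scan axes
    min_pocket_voxels: int = 30
    method: str = "psp_scan"      # or "dog"
    dog_sigma: float = 2.0        # Å, narrow Gaussian width
    dog_ratio: float = 1.5        # wide/narrow width ratio
    dog_threshold: float = 0.08   # response cut on the positive tail

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if not 1 <= self.scan_threshold <= 7:
            raise ValueError("scan_threshold must be in [1, 7]")
        if self.method not in ("psp_scan", "dog"):
            raise ValueError(f"unknown pocket method {self.method!r}")


@dataclass
class Lattice:
    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    @classmethod
    def around(cls, coords: np.ndarray, radii: np.ndarray, cfg: PocketConfig) -> "Lattice":
        margin = radii.max() + 2 * cfg.probe_radius
        lo = coords.min(axis=0) - margin
        hi = coords.max(axis=0) + margin
        dims = tuple(int(np.ceil((hi[i] - lo[i]) / cfg.spacing)) + 1 for i in range(3))
        return cls(origin=lo, spacing=cfg.spacing, dims=dims)

    def voxel_volume(self) -> float:
        return self.spacing ** 3

    def index_of(self, point: np.ndarray) -> tuple[int, int, int]:
        idx = np.rint((np.asarray(point) - self.origin) / self.spacing).astype(int)
        return tuple(idx)


@dataclass
class Pocket:
    voxels: np.ndarray           # (n, 3) integer lattice indices
    volume: float                # Å^3 = n * spacing^3
    centroid: np.ndarray         # Å


@dataclass
class PocketSet:
    lattice: Lattice
    pockets: list[Pocket]

    def total_volume(self) -> float:
        return float(sum(p.volume for p in self.pockets))

    def mask(self) -> np.ndarray:
        m = np.zeros(self.lattice.dims, dtype=bool)
        for p in self.pockets:
            m[p.voxels[:, 0], p.voxels[:, 1], p.voxels[:, 2]] = True
        return m


@dataclass
class OccupancyGrid:
    lattice: Lattice
    occupancy: np.ndarray        # per-voxel fraction of frames in a pocket

    def __post_init__(self):
        occ = self.occupancy
        if occ.min() < 0 or occ.max() > 1 + 1e-12:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class TimeSeries:
    time: np.ndarray
    values: np.ndarray
    units: str = ""
    time_units: str = "ns"

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.values = np.asarray(self.values, float)
        if np.any(np.diff(self.time) < 0):
            raise ValueError("time axis must be monotone non-decreasing")

    def mean(self) -> float:
        return float(self.values.mean())

    def std(self) -> float:
        return float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0


# ---------------------------------------------------------------------------
# protein mask + scan machinery

def _protein_mask(lat: Lattice, coords: np.ndarray, radii: np.ndarray,
                  probe: float) -> np.ndarray:
    mask = np.zeros(lat.dims, dtype=bool)
    ax = [lat.origin[i] + lat.spacing * np.arange(lat.dims[i]) for i in range(3)]
    for c, r in zip(coords, radii + probe):
        lo = [max(0, int(np.ceil((c[i] - r - lat.origin[i]) / lat.spacing))) for i in range(3)]
        hi = [min(lat.dims[i] - 1, int(np.floor((c[i] + r - lat.origin[i]) / lat.spacing)))
              for i in range(3)]
        if any(lo[i] > hi[i] for i in range(3)):
            continue
        d2 = ((ax[0][lo[0]:hi[0] + 1][:, None, None] - c[0]) ** 2
              + (ax[1][lo[1]:hi[1] + 1][None, :, None] - c[1]) ** 2
              + (ax[2][lo[2]:hi[2] + 1][None, None, :] - c[2]) ** 2)
        mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= d2 <= r * r
    return mask


def _shift(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Shift boolean grid by voxel offset d, zero-filling."""
    out = np.zeros_like(a)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax in range(3):
        if d[ax] > 0:
            dst[ax] = slice(d[ax], None)
            src[ax] = slice(None, -d[ax])
        elif d[ax] < 0:
            dst[ax] = slice(None, d[ax])
            src[ax] = slice(-d[ax], None)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _occluded(protein: np.ndarray, d: np.ndarray) -> np.ndarray:
    """True at v if some protein voxel lies at v + k*d for k >= 1 (in-lattice)."""
    steps = max(protein.shape)
    hit = np.zeros_like(protein)
    cur = protein
    for _ in range(steps):
        cur = _shift(cur, -np.asarray(d))  # cur[v] <- cur[v + d]
        if not cur.any():
            break
        hit |= cur
    return hit


def _psp_candidates(protein: np.ndarray, threshold: int) -> np.ndarray:
    count = np.zeros(protein.shape, dtype=np.int8)
    for d in _SCAN_AXES:
        count += (_occluded(protein, d) & _occluded(protein, -d)).astype(np.int8)
    return (~protein) & (count >= threshold)


def _dog_candidates(protein: np.ndarray, cfg: PocketConfig) -> np.ndarray:
    solvent = (~protein).astype(float)
    s1 = cfg.dog_sigma / cfg.spacing
    s2 = cfg.dog_ratio * s1
    response = ndimage.gaussian_filter(solvent, s1) - ndimage.gaussian_filter(solvent, s2)
    return (~protein) & (response > cfg.dog_threshold)


def detect_pockets(frame: Structure, cfg: PocketConfig | None = None,
                   lattice: Lattice | None = None,
                   radii: np.ndarray | None = None) -> PocketSet:
    """Pocket voxel clusters for one structure (optionally on a fixed lattice)."""
    cfg = cfg or PocketConfig()
    if len(frame) == 0:
        raise ValueError("structure has no atoms")
    coords = frame.coords()
    radii = default_radii(frame) if radii is None else np.asarray(radii, float)
    lat = lattice or Lattice.around(coords, radii, cfg)
    protein = _protein_mask(lat, coords, radii, cfg.probe_radius)
    if cfg.method == "psp_scan":
        cand = _psp_candidates(protein, cfg.scan_threshold)
    else:
        cand = _dog_candidates(protein, cfg)
    labels, n = ndimage.label(cand, structure=np.ones((3, 3, 3), dtype=int))
    pockets = []
    if n:
        sizes = np.bincount(labels.ravel())
        for lab in range(1, n + 1):
            if sizes[lab] < cfg.min_pocket_voxels:
                continue
            vox = np.argwhere(labels == lab)
            centroid = lat.origin + lat.spacing * vox.mean(axis=0)
            pockets.append(Pocket(vox, sizes[lab] * lat.voxel_volume(), centroid))
    pockets.sort(key=lambda p: -p.volume)
    return PocketSet(lat, pockets)


def _shared_lattice(t: Trajectory, cfg: PocketConfig) -> Lattice:
    radii = default_radii(t.topology)
    return Lattice.around(t.frames[0], radii, cfg)


def _warn_if_unaligned(t: Trajectory) -> None:
    if t.n_frames > 1 and not t.aligned:
        warnings.warn("trajectory has not been aligned; per-voxel statistics "
                      "mix rigid-body motion into pocket dynamics", stacklevel=3)


def volume_trace(t: Trajectory, cfg: PocketConfig | None = None,
                 site: np.ndarray | None = None) -> TimeSeries:
    """Per-frame pocket volume (Å^3); restricted to the site pocket if given.

    With `site`, the volume counts pockets containing the seed voxel, or the
    pocket with the nearest centroid when none contains it.
    """
    cfg = cfg or PocketConfig()
    _warn_if_unaligned(t)
    lat = _shared_lattice(t, cfg)
    radii = default_radii(t.topology)
    vols = []
    for f in range(t.n_frames):
        ps = detect_pockets(t.frame(f), cfg, lattice=lat, radii=radii)
        if not ps.pockets:
            vols.append(0.0)
            continue
        if site is None:
            vols.append(ps.total_volume())
        else:
            sv = np.asarray(lat.index_of(site))
            containing = [p for p in ps.pockets
                          if np.any(np.all(p.voxels == sv, axis=1))]
            if containing:
                vols.append(float(sum(p.volume for p in containing)))
            else:
                nearest = min(ps.pockets,
                              key=lambda p: float(np.linalg.norm(p.centroid - np.asarray(site))))
                vols.append(nearest.volume)
    return TimeSeries(t.times(), np.array(vols), units="Å^3")


def occupancy_grid(t: Trajectory, cfg: PocketConfig | None = None) -> OccupancyGrid:
    """Per-voxel fraction of frames in which the voxel belongs to a pocket."""
    cfg = cfg or PocketConfig()
    _warn_if_unaligned(t)
    lat = _shared_lattice(t, cfg)
    radii = default_radii(t.topology)
    counts = np.zeros(lat.dims, dtype=np.int32)
    for f in range(t.n_frames):
        ps = detect_pockets(t.frame(f), cfg, lattice=lat, radii=radii)
        counts += ps.mask()
    return OccupancyGrid(lat, counts / t.n_frames)


def occupancy_shell(g: OccupancyGrid, lo: float, hi: float) -> tuple[np.ndarray, float]:
    """Voxels with lo < occupancy <= hi, and their total volume in Å^3."""
    if not 0 <= lo < hi <= 1:
        raise ValueError("need 0 <= lo < hi <= 1")
    sel = (g.occupancy > lo) & (g.occupancy <= hi)
    vox = np.argwhere(sel)
    return vox, vox.shape[0] * g.lattice.voxel_volume()


def savitzky_golay(s: TimeSeries, window: int = 51, order: int = 3) -> TimeSeries:
    """Local least-squares polynomial smoothing (endpoints by truncated fits)."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be < window")
    if len(s.values) < window:
        raise ValueError(f"series length {len(s.values)} < window {window}")
    smoothed = savgol_filter(s.values, window_length=window, polyorder=order,
                             mode="interp")
    return TimeSeries(s.time.copy(), smoothed, units=s.units, time_units=s.time_units)
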