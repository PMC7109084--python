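"""Linearized Poisson-Boltzmann electrostatics on focused finite-difference
lattices, electric fields as the negative potential gradient, and OpenDX
scalar-grid I/O.

The reduced potential u(r) = e*V(r)/kT (i.e. V in kT/e units) satisfies

    div( eps(r) grad u ) - eps_s * kappa_bar(r)^2 * u = -4*pi*lB * sum_i q_i delta(r - r_i)

with lengths in Å, charges q_i in units of e, eps(r) the relative
permittivity (eps_protein inside the van der Waals atom-sphere union,
eps_solvent outside), and lB = e^2/(4 pi eps0 kB T) the vacuum Bjerrum
length (~539 Å at 310 K). kappa_bar^2 is the Debye screening parameter of a
monovalent salt, zeroed inside the molecule plus an ion-exclusion shell:

    kappa^2 [1/Å^2] = 8 * pi * (lB/eps_s) * NA * I[mol/L] * 1e-27

Discretization: 7-point variable-coefficient stencil with harmonic-mean
face dielectrics; point charges spread to their 8 surrounding nodes
(trilinear). Dirichlet boundaries: a superposition of Debye-Hückel terms,
one per charge, on the coarse grid (linear in the charges, so the discrete
solution obeys superposition exactly); sequential focusing interpolates the
coarse solution onto the fine-grid boundary. The symmetric positive
definite system is solved by diagonally preconditioned conjugate gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import cg

from .protonation import ChargeRadiusAssignment
from .structure_io import Structure

__all__ = [
    "SolverConfig",
    "ScalarGrid",
    "VectorGrid",
    "grid_node_count",
    "solve_lpb",
    "compute_field",
    "sample_surface_potential",
    "write_dx",
    "read_dx",
    "SolverError",
]

# physical constants (SI)
_E = 1.602176634e-19      # C
_EPS0 = 8.8541878128e-12  # F/m
_KB = 1.380649e-23        # J/K
_NA = 6.02214076e23       # 1/mol


def bjerrum_length_vacuum(temperature: float) -> float:
    """e^2/(4 pi eps0 kB T) in Å."""
    return _E ** 2 / (4 * np.pi * _EPS0 * _KB * temperature) * 1e10


def debye_kappa2(ionic_strength: float, eps_solvent: float, temperature: float) -> float:
    """Squared Debye parameter (1/Å^2) for a monovalent salt."""
    lb_solvent = bjerrum_length_vacuum(temperature) / eps_solvent
    return 8 * np.pi * lb_solvent * _NA * ionic_strength * 1e-27


class SolverError(RuntimeError):
    pass


@dataclass
class SolverConfig:
    eps_protein: float = 4.0
    eps_solvent: float = 78.54
    ionic_strength: float = 0.150   # mol/L NaCl
    temperature: float = 310.0      # K
    fine_dim: int = 129             # nodes per axis, odd
    fine_spacing: float = 0.5       # Å
    coarse_dim: int = 65
    coarse_factor: float = 1.7      # coarse extent multiple of molecular extent
    ion_exclusion: float = 2.0      # Å Stern shell
    tol: float = 1e-6
    max_iter: int = 20000
    focus: bool = True

    def __post_init__(self):
        if self.fine_dim % 2 == 0:
            raise ValueError("fine_dim must be odd")
        if self.fine_spacing <= 0:
            raise ValueError("spacings must be > 0")
        if min(self.eps_protein, self.eps_solvent) < 1:
            raise ValueError("relative permittivities must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


def grid_node_count(cfg: SolverConfig) -> int:
    """Nodes in the fine lattice (fine_dim cubed)."""
    return cfg.fine_dim ** 3


@dataclass
class ScalarGrid:
    origin: np.ndarray          # Å, (3,)
    spacing: np.ndarray         # Å per axis, (3,)
    values: np.ndarray          # (nx, ny, nz)
    units: str = "kT/e"

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.spacing = np.asarray(self.spacing, float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("grid needs >= 2 nodes per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[i] + self.spacing[i] * np.arange(self.dims[i])
                     for i in range(3))

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(self.axes(), self.values,
                                       bounds_error=False, fill_value=np.nan)


@dataclass
class VectorGrid:
    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray          # (nx, ny, nz, 3)
    units: str = "(kT/e)/Å"

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.spacing = np.asarray(self.spacing, float)
        if self.values.ndim != 4 or self.values.shape[3] != 3:
            raise ValueError("vector grid values must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("vector grid values must be finite")

    @property
    def dims(self):
        return self.values.shape[:3]


# ---------------------------------------------------------------------------
# lattice helpers

def _node_axes(origin, spacing, dims):
    return [origin[i] + spacing[i] * np.arange(dims[i]) for i in range(3)]


def _stamp_spheres(origin, spacing, dims, centers, radii) -> np.ndarray:
    """Boolean mask of nodes whose centers lie inside any atom sphere."""
    mask = np.zeros(dims, dtype=bool)
    ax = _node_axes(origin, spacing, dims)
    for c, r in zip(centers, radii):
        lo = [max(0, int(np.ceil((c[i] - r - origin[i]) / spacing[i]))) for i in range(3)]
        hi = [min(dims[i] - 1, int(np.floor((c[i] + r - origin[i]) / spacing[i])))
              for i in range(3)]
        if any(lo[i] > hi[i] for i in range(3)):
            continue
        xs = ax[0][lo[0]:hi[0] + 1][:, None, None]
        ys = ax[1][lo[1]:hi[1] + 1][None, :, None]
        zs = ax[2][lo[2]:hi[2] + 1][None, None, :]
        d2 = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2
        mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= d2 <= r * r
    return mask


def _spread_charges(origin, spacing, dims, centers, charges,
                    drop_outside: bool = False) -> np.ndarray:
    """Trilinear charge spreading onto the 8 surrounding nodes (units: e)."""
    q = np.zeros(dims)
    centers = np.atleast_2d(np.asarray(centers, float))
    charges = np.atleast_1d(np.asarray(charges, float))
    frac = (centers - origin) / spacing
    base = np.floor(frac).astype(int)
    outside = np.any(base < 0, axis=1) | np.any(base + 1 > np.array(dims) - 1, axis=1)
    if outside.any():
        if not drop_outside:
            raise SolverError("charge lies outside the lattice")
        # focused fine level: exterior charges act through the boundary values
        frac, base, charges = frac[~outside], base[~outside], charges[~outside]
        if base.size == 0:
            return q
    w = frac - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wt = (np.where(dx, w[:, 0], 1 - w[:, 0])
                      * np.where(dy, w[:, 1], 1 - w[:, 1])
                      * np.where(dz, w[:, 2], 1 - w[:, 2]))
                np.add.at(q, (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz),
                          wt * charges)
    return q


def _boundary_mask(dims) -> np.ndarray:
    edge = np.zeros(dims, dtype=bool)
    edge[0, :, :] = edge[-1, :, :] = True
    edge[:, 0, :] = edge[:, -1, :] = True
    edge[:, :, 0] = edge[:, :, -1] = True
    return edge


def _dh_boundary(origin, spacing, dims, centers, charges, lb, eps_s, kappa):
    """Superposed Debye-Hückel terms (one per charge) on the boundary nodes.

    Linear in the charges, so the discrete solution inherits superposition
    and sign symmetry exactly.
    """
    ax = _node_axes(origin, spacing, dims)
    edge = _boundary_mask(dims)
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X[edge], Y[edge], Z[edge]], axis=1)
    vals = np.zeros(pts.shape[0])
    for c, q in zip(np.atleast_2d(centers), np.atleast_1d(charges)):
        if q == 0:
            continue
        r = np.maximum(np.linalg.norm(pts - c, axis=1), 1e-6)
        vals += lb * q * np.exp(-kappa * r) / (eps_s * r)
    out = np.zeros(dims)
    out[edge] = vals
    return out


def _solve_on_grid(origin, spacing, dims, centers, charges, radii, cfg: SolverConfig,
                   boundary: np.ndarray, drop_outside: bool = False) -> np.ndarray:
    """Solve the discretized linear PB system with Dirichlet boundary values."""
    nx, ny, nz = dims
    h = spacing  # (3,) — may differ per axis
    lb = bjerrum_length_vacuum(cfg.temperature)

    inside = _stamp_spheres(origin, spacing, dims, centers, radii)
    eps = np.where(inside, cfg.eps_protein, cfg.eps_solvent)

    kappa2 = debye_kappa2(cfg.ionic_strength, cfg.eps_solvent, cfg.temperature)
    if kappa2 > 0:
        excl = _stamp_spheres(origin, spacing, dims, centers,
                              np.asarray(radii) + cfg.ion_exclusion)
        kmap = np.where(excl, 0.0, kappa2 * cfg.eps_solvent)
    else:
        kmap = np.zeros(dims)

    rho = _spread_charges(origin, spacing, dims, centers, charges, drop_outside)
    vol = h[0] * h[1] * h[2]
    source = 4 * np.pi * lb * rho / vol  # RHS of -div(eps grad u) + eps_s k^2 u = 4 pi lB rho

    u = boundary.copy()
    interior = np.zeros(dims, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    idx = -np.ones(dims, dtype=np.int64)
    n_unknown = int(interior.sum())
    idx[interior] = np.arange(n_unknown)

    def face_eps(axis):
        """Harmonic-mean dielectric on faces between node i and i+1 along axis."""
        a = eps
        b = np.roll(eps, -1, axis=axis)
        return 2.0 * a * b / (a + b)

    diag = kmap[interior].astype(float).copy()
    rows, cols, vals = [], [], []
    b_vec = source[interior].copy()

    ii = np.argwhere(interior)
    for axis in range(3):
        fe = face_eps(axis)
        for side in (-1, +1):
            nb = ii.copy()
            nb[:, axis] += side
            # face between node and neighbor
            face = ii.copy()
            if side == -1:
                face[:, axis] -= 1
            w = fe[face[:, 0], face[:, 1], face[:, 2]] / h[axis] ** 2
            diag += w
            nb_flat = idx[nb[:, 0], nb[:, 1], nb[:, 2]]
            is_interior = nb_flat >= 0
            rows.append(np.arange(n_unknown)[is_interior])
            cols.append(nb_flat[is_interior])
            vals.append(-w[is_interior])
            # boundary neighbor: move to RHS
            bmask = ~is_interior
            if bmask.any():
                bv = u[nb[bmask, 0], nb[bmask, 1], nb[bmask, 2]]
                np.add.at(b_vec, np.arange(n_unknown)[bmask], w[bmask] * bv)

    A = sparse.csr_matrix(
        (np.concatenate(vals + [diag]),
         (np.concatenate(rows + [np.arange(n_unknown)]),
          np.concatenate(cols + [np.arange(n_unknown)]))),
        shape=(n_unknown, n_unknown),
    )
    M = sparse.diags(1.0 / A.diagonal())
    x, info = cg(A, b_vec, rtol=cfg.tol, maxiter=cfg.max_iter, M=M)
    if info != 0:
        res = np.linalg.norm(A @ x - b_vec) / max(np.linalg.norm(b_vec), 1e-300)
        raise SolverError(f"CG did not converge in {cfg.max_iter} iterations "
                          f"(relative residual {res:.3e})")
    u[interior] = x
    return u


def solve_lpb(assignment: ChargeRadiusAssignment, cfg: SolverConfig | None = None,
              center: np.ndarray | None = None) -> ScalarGrid:
    """Sequential-focusing linearized PB solve; potential in kT/e.

    A coarse grid spanning `coarse_factor` times the molecular extent is
    solved with Debye-Hückel monopole boundary values, then the fine lattice
    (fine_dim nodes, fine_spacing Å) is re-solved with boundary values
    interpolated from the coarse solution.
    """
    cfg = cfg or SolverConfig()
    s = assignment.structure
    if len(s) == 0:
        raise ValueError("assignment has no atoms")
    coords = s.coords()
    charges = np.asarray(assignment.charges, float)
    radii = np.asarray(assignment.radii, float)
    lb = bjerrum_length_vacuum(cfg.temperature)
    kappa = np.sqrt(debye_kappa2(cfg.ionic_strength, cfg.eps_solvent, cfg.temperature))

    if center is None:
        center = 0.5 * (coords.min(axis=0) + coords.max(axis=0))
    center = np.asarray(center, float)

    fine_extent = (cfg.fine_dim - 1) * cfg.fine_spacing
    mol_extent = float(np.max(coords.max(axis=0) - coords.min(axis=0) + 2 * radii.max()))
    coarse_extent = max(cfg.coarse_factor * mol_extent, 1.2 * fine_extent)
    if mol_extent > coarse_extent:
        raise SolverError("molecule larger than the coarse lattice")

    fine_origin = center - fine_extent / 2
    fine_dims = (cfg.fine_dim,) * 3
    fine_spacing = np.full(3, cfg.fine_spacing)

    if cfg.focus and coarse_extent > fine_extent:
        c_dims = (cfg.coarse_dim,) * 3
        c_spacing = np.full(3, coarse_extent / (cfg.coarse_dim - 1))
        c_origin = center - coarse_extent / 2
        c_bc = _dh_boundary(c_origin, c_spacing, c_dims, coords, charges, lb,
                            cfg.eps_solvent, kappa)
        c_u = _solve_on_grid(c_origin, c_spacing, c_dims, coords, charges, radii,
                             cfg, c_bc)
        interp = RegularGridInterpolator(_node_axes(c_origin, c_spacing, c_dims), c_u)
        ax = _node_axes(fine_origin, fine_spacing, fine_dims)
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        f_bc = np.zeros(fine_dims)
        edge = _boundary_mask(fine_dims)
        f_bc[edge] = interp(pts[edge])
    else:
        f_bc = _dh_boundary(fine_origin, fine_spacing, fine_dims, coords, charges, lb,
                            cfg.eps_solvent, kappa)

    u = _solve_on_grid(fine_origin, fine_spacing, fine_dims, coords, charges, radii,
                       cfg, f_bc, drop_outside=cfg.focus and coarse_extent > fine_extent)
    return ScalarGrid(fine_origin, fine_spacing, u, units="kT/e")


def compute_field(v: ScalarGrid) -> VectorGrid:
    """E = -grad V: central differences inside, one-sided at the boundary."""
    if min(v.dims) < 3:
        raise ValueError("field needs >= 3 nodes per axis")
    gx, gy, gz = np.gradient(v.values, *(v.spacing[i] for i in range(3)))
    E = -np.stack([gx, gy, gz], axis=-1)
    return VectorGrid(v.origin.copy(), v.spacing.copy(), E, units=f"({v.units})/Å")


def sample_surface_potential(v: ScalarGrid, s: Structure, probe_offset: float = 1.4,
                             radii: np.ndarray | None = None) -> np.ndarray:
    """Potential interpolated at atom centers pushed outward from the centroid.

    Each atom is displaced along the direction away from the molecular
    centroid by (radius + probe_offset). Points falling outside the lattice
    yield NaN.
    """
    from .structure_io import default_radii
    coords = s.coords()
    radii = default_radii(s) if radii is None else np.asarray(radii, float)
    centroid = coords.mean(axis=0)
    d = coords - centroid
    norm = np.linalg.norm(d, axis=1, keepdims=True)
    d = np.where(norm > 1e-9, d / np.maximum(norm, 1e-9), np.array([0.0, 0.0, 1.0]))
    pts = coords + d * (radii[:, None] + probe_offset)
    return v.interpolator()(pts)


# ---------------------------------------------------------------------------
# OpenDX scalar format

def write_dx(g: ScalarGrid, comment: str = "") -> str:
    """OpenDX scalar grid; data ordered with the last (z) index fastest."""
    nx, ny, nz = g.dims
    lines = []
    if comment:
        for c in comment.splitlines():
            lines.append(f"# {c}")
    lines.append(f"object 1 class gridpositions counts {nx} {ny} {nz}")
    lines.append("origin {:.6e} {:.6e} {:.6e}".format(*g.origin))
    lines.append(f"delta {g.spacing[0]:.6e} 0.000000e+00 0.000000e+00")
    lines.append(f"delta 0.000000e+00 {g.spacing[1]:.6e} 0.000000e+00")
    lines.append(f"delta 0.000000e+00 0.000000e+00 {g.spacing[2]:.6e}")
    lines.append(f"object 2 class gridconnections counts {nx} {ny} {nz}")
    lines.append(f"object 3 class array type double rank 0 items {nx * ny * nz} data follows")
    flat = g.values.ravel(order="C")
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{x:.6e}" for x in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    return "\n".join(lines) + "\n"


def read_dx(text: str) -> ScalarGrid:
    """Parse the OpenDX scalar dialect written by write_dx (and APBS-style files)."""
    dims = None
    origin = None
    deltas = []
    data: list[float] = []
    n_items = None
    in_data = False
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if in_data and n_items is not None and len(data) < n_items:
            try:
                data.extend(float(tok) for tok in stripped.split())
                continue
            except ValueError:
                in_data = False  # trailing attribute/object lines
        if stripped.startswith("object") and "gridpositions" in stripped:
            toks = stripped.split()
            try:
                dims = tuple(int(t) for t in toks[-3:])
            except ValueError:
                raise ValueError(f"malformed gridpositions header: {stripped!r}")
        elif stripped.startswith("origin"):
            origin = np.array([float(t) for t in stripped.split()[1:4]])
        elif stripped.startswith("delta"):
            deltas.append([float(t) for t in stripped.split()[1:4]])
        elif stripped.startswith("object") and "class array" in stripped:
            toks = stripped.split()
            n_items = int(toks[toks.index("items") + 1])
            in_data = True
    if dims is None or origin is None or len(deltas) < 3:
        raise ValueError("malformed DX header: missing gridpositions/origin/delta")
    if n_items is None or len(data) < n_items:
        raise ValueError("malformed DX data section")
    spacing = np.array([deltas[0][0], deltas[1][1], deltas[2][2]])
    values = np.array(data[:n_items]).reshape(dims, order="C")
    return ScalarGrid(origin, spacing, values)


def write_vector_dx(v: VectorGrid, stem: str) -> dict[str, str]:
    """Three scalar DX documents (one per component), keyed by filename."""
    out = {}
    for i, comp in enumerate("xyz"):
        g = ScalarGrid(v.origin.copy(), v.spacing.copy(), np.ascontiguousarray(v.values[..., i]),
                       units=v.units)
        out[f"{stem}_E{comp}.dx"] = write_dx(g, comment=f"E{comp} component, {v.units}")
    return out
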