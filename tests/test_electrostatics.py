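import numpy as np
import pytest

from groovescope.electrostatics import (ScalarGrid, SolverConfig, bjerrum_length_vacuum,
                                        compute_field, debye_kappa2, grid_node_count,
                                        read_dx, sample_surface_potential, solve_lpb,
                                        write_dx)
from groovescope.protonation import ChargeRadiusAssignment
from groovescope.structure_io import AtomRecord, Structure


def point_charge(q=1.0, pos=(0.0, 0.0, 0.0)):
    s = Structure([AtomRecord(1, "CA", "C", "DUM", 1, "A", tuple(pos))])
    return ChargeRadiusAssignment(s, np.array([q]), np.array([1.7]))


def uniform_cfg(dim=33, spacing=1.0, ionic=0.0):
    """Homogeneous medium (protein eps = solvent eps) for analytic oracles."""
    return SolverConfig(eps_protein=78.54, eps_solvent=78.54, ionic_strength=ionic,
                        ion_exclusion=0.0, fine_dim=dim, fine_spacing=spacing,
                        coarse_dim=17, focus=False)


class TestGridNodeCount:
    def test_default_is_129_cubed(self):
        assert grid_node_count(SolverConfig()) == 2_146_689

    @pytest.mark.parametrize("dim,expected", [(65, 274_625), (3, 27)])
    def test_small_lattices(self, dim, expected):
        assert grid_node_count(SolverConfig(fine_dim=dim)) == expected

    def test_even_dim_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SolverConfig(fine_dim=128)


class TestSolveLpb:
    def test_zero_charges_zero_potential(self):
        asg = point_charge(q=0.0)
        g = solve_lpb(asg, uniform_cfg(dim=17))
        assert np.abs(g.values).max() < 1e-12

    def test_coulomb_oracle_small_grid(self):
        """Uniform eps, no salt: V = lB q / (eps r) in kT/e."""
        g = solve_lpb(point_charge(), uniform_cfg(dim=33, spacing=1.0))
        lb = bjerrum_length_vacuum(310.0)
        interp = g.interpolator()
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            r = rng.uniform(5.0, 14.0)
            u = float(interp(v * r)[0])
            assert u == pytest.approx(lb / 78.54 / r, rel=0.05)

    def test_debye_huckel_oracle_small_grid(self):
        g = solve_lpb(point_charge(), uniform_cfg(dim=33, spacing=1.0, ionic=0.150))
        lb = bjerrum_length_vacuum(310.0)
        kappa = np.sqrt(debye_kappa2(0.150, 78.54, 310.0))
        interp = g.interpolator()
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            r = rng.uniform(5.0, 14.0)
            u = float(interp(v * r)[0])
            assert u == pytest.approx(lb / 78.54 * np.exp(-kappa * r) / r, rel=0.05)

    def test_superposition_and_sign_symmetry(self):
        """Linear operator: V(q1+q2) = V(q1) + V(q2); V(-q) = -V(q)."""
        s = Structure([AtomRecord(1, "CA", "C", "DUM", 1, "A", (-3.0, 0.0, 0.0)),
                       AtomRecord(2, "CA", "C", "DUM", 2, "A", (3.0, 0.0, 0.0))])
        radii = np.array([1.7, 1.7])
        cfg = SolverConfig(fine_dim=25, fine_spacing=1.0, coarse_dim=17, focus=False)
        g12 = solve_lpb(ChargeRadiusAssignment(s, np.array([1.0, -1.0]), radii), cfg)
        g1 = solve_lpb(ChargeRadiusAssignment(s, np.array([1.0, 0.0]), radii), cfg)
        g2 = solve_lpb(ChargeRadiusAssignment(s, np.array([0.0, -1.0]), radii), cfg)
        gneg = solve_lpb(ChargeRadiusAssignment(s, np.array([-1.0, 1.0]), radii), cfg)
        scale = np.abs(g12.values).max()
        assert np.abs(g12.values - (g1.values + g2.values)).max() < 1e-4 * max(scale, 1)
        assert np.abs(g12.values + gneg.values).max() < 1e-9

    def test_mesh_refinement_improves_coulomb_fit(self):
        """Halving the spacing reduces the worst deviation from the closed form."""
        lb = bjerrum_length_vacuum(310.0)

        def max_err(dim, spacing):
            g = solve_lpb(point_charge(), uniform_cfg(dim=dim, spacing=spacing))
            interp = g.interpolator()
            errs = []
            for r in np.linspace(4.0, 9.0, 12):
                u = float(interp([[r, 0.0, 0.0]])[0])
                errs.append(abs(u / (lb / 78.54 / r) - 1))
            return max(errs)

        assert max_err(41, 0.5) < max_err(21, 1.0)

    def test_focused_solution_matches_coarse_at_boundary(self):
        cfg = SolverConfig(eps_protein=78.54, eps_solvent=78.54, ionic_strength=0.0,
                           ion_exclusion=0.0, fine_dim=21, fine_spacing=1.0,
                           coarse_dim=21, coarse_factor=3.0, focus=True)
        g = solve_lpb(point_charge(), cfg)
        # boundary nodes carry interpolated coarse values: finite, decaying outward
        assert np.all(np.isfinite(g.values))
        assert g.values[0, 10, 10] < g.values[5, 10, 10]

    def test_nonconvergence_reports_residual(self):
        cfg = uniform_cfg(dim=33)
        cfg.max_iter = 2
        from groovescope.electrostatics import SolverError
        with pytest.raises(SolverError, match="residual"):
            solve_lpb(point_charge(), cfg)


class TestComputeField:
    def test_constant_potential_zero_field(self):
        g = ScalarGrid(np.zeros(3), np.ones(3), np.full((5, 5, 5), 3.3))
        assert np.abs(compute_field(g).values).max() == 0

    def test_linear_ramp_exact_at_interior(self):
        x = np.arange(7) * 0.5
        vals = np.broadcast_to(2.0 * x[:, None, None], (7, 7, 7)).copy()
        E = compute_field(ScalarGrid(np.zeros(3), np.full(3, 0.5), vals)).values
        assert np.allclose(E[1:-1, :, :, 0], -2.0)
        assert np.abs(E[..., 1:]).max() < 1e-12

    def test_point_charge_field_points_outward(self):
        g = solve_lpb(point_charge(), uniform_cfg(dim=21))
        E = compute_field(g).values
        ax = g.axes()
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        rvec = np.stack([X, Y, Z], axis=-1)
        r = np.linalg.norm(rvec, axis=-1)
        mask = (r > 3) & (r < 8)
        dots = np.sum(E[mask] * rvec[mask], axis=-1)
        assert np.all(dots > 0)


class TestSurfaceSampling:
    def test_constant_grid_samples_constant(self, scaffold14):
        g = ScalarGrid(np.array([-60.0, -60, -60]), np.full(3, 2.0),
                       np.full((61, 61, 61), 1.5))
        vals = sample_surface_potential(g, scaffold14, probe_offset=1.4)
        assert np.allclose(vals, 1.5)

    def test_positive_charge_gives_positive_surface(self):
        g = solve_lpb(point_charge(), uniform_cfg(dim=25))
        atoms = [AtomRecord(i + 1, "CA", "C", "DUM", i + 1, "A", tuple(p))
                 for i, p in enumerate([(3.0, 0, 0), (0, 3.0, 0), (0, 0, -3.0)])]
        vals = sample_surface_potential(g, Structure(atoms), probe_offset=1.0)
        assert np.all(vals > 0)

    def test_linearity_in_charge(self):
        cfg = uniform_cfg(dim=25)
        g1 = solve_lpb(point_charge(q=1.0), cfg)
        g2 = solve_lpb(point_charge(q=2.0), cfg)
        atoms = [AtomRecord(1, "CA", "C", "DUM", 1, "A", (4.0, 1.0, 0.0)),
                 AtomRecord(2, "CA", "C", "DUM", 2, "A", (-2.0, -4.0, 1.0))]
        s = Structure(atoms)
        v1 = sample_surface_potential(g1, s, probe_offset=1.0)
        v2 = sample_surface_potential(g2, s, probe_offset=1.0)
        assert np.allclose(v2, 2 * v1, rtol=1e-4)

    def test_outside_grid_flagged_nan(self):
        g = ScalarGrid(np.zeros(3), np.ones(3), np.zeros((4, 4, 4)))
        s = Structure([AtomRecord(1, "CA", "C", "DUM", 1, "A", (50.0, 0, 0))])
        assert np.isnan(sample_surface_potential(g, s, probe_offset=1.0)).all()


class TestOpenDx:
    def test_small_round_trip(self, rng):
        g = ScalarGrid(np.array([1.0, -2.0, 0.5]), np.array([0.5, 0.5, 1.0]),
                       rng.normal(size=(3, 3, 3)))
        back = read_dx(write_dx(g))
        assert back.dims == g.dims
        assert np.allclose(back.origin, g.origin)
        assert np.abs(back.values - g.values).max() < 1e-6

    def test_three_per_line_scientific(self, rng):
        g = ScalarGrid(np.zeros(3), np.ones(3), rng.normal(size=(4, 5, 3)))
        text = write_dx(g)
        data_lines = [ln for ln in text.splitlines()
                      if ln and ln[0] in "-0123456789" and "e" in ln]
        assert all(len(ln.split()) <= 3 for ln in data_lines)
        assert read_dx(text).dims == (4, 5, 3)

    def test_apbs_style_header_parsed(self):
        text = """# Potential from an external PB tool
object 1 class gridpositions counts 2 2 2
origin 0.0 0.0 0.0
delta 1.0 0.0 0.0
delta 0.0 1.0 0.0
delta 0.0 0.0 1.0
object 2 class gridconnections counts 2 2 2
object 3 class array type double rank 0 items 8 data follows
1.0 2.0 3.0
4.0 5.0 6.0
7.0 8.0
attribute "dep" string "positions"
"""
        g = read_dx(text)
        assert g.dims == (2, 2, 2)
        assert g.values[0, 0, 0] == 1.0 and g.values[1, 1, 1] == 8.0

    def test_malformed_header_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            read_dx("object 1 class gridpositions counts 2 2\n")
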