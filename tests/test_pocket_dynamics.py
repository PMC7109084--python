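import numpy as np
import pytest

from groovescope.pocket_dynamics import (Lattice, PocketConfig, TimeSeries,
                                         _protein_mask, detect_pockets,
                                         occupancy_grid, occupancy_shell,
                                         savitzky_golay, volume_trace)
from groovescope.structure_io import AtomRecord, Structure, Trajectory, default_radii
from groovescope.synthetic_data import make_cavity_probe


def slab_structure(gap=6.0, half=8.0, spacing=1.5):
    """Two parallel dense atom slabs separated by `gap` along z."""
    atoms = []
    serial = 1
    xs = np.arange(-half, half + 1e-9, spacing)
    for z0 in (-gap / 2 - 1.5, gap / 2 + 1.5):
        for zoff in (0.0, spacing):
            for x in xs:
                for y in xs:
                    atoms.append(AtomRecord(serial, "CA", "C", "DUM", serial, "A",
                                            (float(x), float(y), z0 + np.sign(z0) * zoff)))
                    serial += 1
    return Structure(atoms)


class TestDetectPockets:
    def test_spherical_cavity_volume(self):
        probe = make_cavity_probe(5.0, 8.0)
        ps = detect_pockets(probe)
        assert len(ps.pockets) >= 1
        assert ps.pockets[0].volume == pytest.approx(4 / 3 * np.pi * 5 ** 3, rel=0.15)

    def test_isolated_atom_has_no_pockets(self):
        s = Structure([AtomRecord(1, "CA", "C", "DUM", 1, "A", (0., 0., 0.))])
        assert detect_pockets(s).pockets == []

    def test_slab_gap_matches_brute_force_oracle(self):
        """PSP criterion re-derived voxel by voxel with explicit ray walks."""
        s = slab_structure()
        cfg = PocketConfig(spacing=1.0)
        ps = detect_pockets(s, cfg)
        coords, radii = s.coords(), default_radii(s)
        lat = ps.lattice
        protein = _protein_mask(lat, coords, radii, cfg.probe_radius)
        dirs = [(1, 0, 0), (0, 1, 0), (0, 0, 1),
                (1, 1, 1), (1, -1, 1), (1, 1, -1), (1, -1, -1)]

        def ray_hits(idx, d):
            p = np.array(idx)
            while True:
                p = p + d
                if np.any(p < 0) or np.any(p >= np.array(lat.dims)):
                    return False
                if protein[tuple(p)]:
                    return True

        expected = np.zeros(lat.dims, dtype=bool)
        it = np.ndindex(*lat.dims)
        for idx in it:
            if protein[idx]:
                continue
            n = sum(1 for d in dirs
                    if ray_hits(idx, np.array(d)) and ray_hits(idx, -np.array(d)))
            expected[idx] = n >= cfg.scan_threshold
        got = ps.mask()
        # clusters below min size are dropped from `got`; compare on large clusters
        from scipy import ndimage
        labels, nlab = ndimage.label(expected, structure=np.ones((3, 3, 3), dtype=int))
        sizes = np.bincount(labels.ravel())
        keep = np.isin(labels, [l for l in range(1, nlab + 1)
                                if sizes[l] >= cfg.min_pocket_voxels]) & expected
        assert np.array_equal(got, keep)

    def test_threshold_monotonicity(self):
        probe = make_cavity_probe(4.0, 7.0)
        strict = detect_pockets(probe, PocketConfig(scan_threshold=7, min_pocket_voxels=1))
        loose = detect_pockets(probe, PocketConfig(scan_threshold=3, min_pocket_voxels=1))
        assert strict.mask()[loose.mask() == False].sum() == 0  # noqa: E712

    def test_rotation_invariance_within_discretization(self):
        from scipy.spatial.transform import Rotation
        probe = make_cavity_probe(5.0, 8.0)
        v0 = detect_pockets(probe).pockets[0].volume
        R = Rotation.from_euler("xyz", [30, 0, 0], degrees=True).as_matrix()
        rotated = probe.with_coords(probe.coords() @ R.T)
        v1 = detect_pockets(rotated).pockets[0].volume
        assert v1 == pytest.approx(v0, rel=0.10)

    def test_dog_method_finds_enclosed_cavity(self):
        probe = make_cavity_probe(5.0, 8.0)
        ps = detect_pockets(probe, PocketConfig(method="dog"))
        assert ps.pockets, "difference-of-Gaussians misses an enclosed sphere"
        center = np.array(ps.lattice.index_of(np.zeros(3)))
        assert any(np.any(np.all(p.voxels == center, axis=1)) for p in ps.pockets)


def two_state_trajectory(n_frames=6):
    """Alternates between a sealed cavity probe and a 'burst' open shell."""
    closed = make_cavity_probe(4.0, 6.5)
    coords = closed.coords()
    # "burst" frame: shell moved off the shared lattice, cavity gone
    open_coords = coords + np.array([0.0, 0.0, 200.0])
    frames = [coords if k % 2 == 0 else open_coords for k in range(n_frames)]
    t = Trajectory(closed, frames)
    t.aligned = True
    return t


class TestTrajectoryAnalyses:
    def test_static_trajectory_constant_volume(self):
        probe = make_cavity_probe(4.0, 6.5)
        t = Trajectory(probe, [probe.coords()] * 3)
        t.aligned = True
        ts = volume_trace(t)
        assert np.ptp(ts.values) == 0
        assert ts.values[0] > 0

    def test_empty_frames_zero_volume(self):
        s = Structure([AtomRecord(1, "CA", "C", "DUM", 1, "A", (0., 0., 0.))])
        t = Trajectory(s, [s.coords()] * 3)
        t.aligned = True
        assert np.all(volume_trace(t).values == 0)

    def test_shrinking_cavity_monotone_volume(self):
        """Frames scaled toward closure give a non-increasing volume trend."""
        probe = make_cavity_probe(6.0, 9.0)
        base = probe.coords()
        scales = [1.0, 0.92, 0.84, 0.76]
        t = Trajectory(probe, [base * s for s in scales])
        t.aligned = True
        ts = volume_trace(t, site=np.zeros(3))
        assert all(b <= a for a, b in zip(ts.values, ts.values[1:]))
        assert ts.values[-1] < ts.values[0]

    def test_unaligned_trajectory_warns(self):
        probe = make_cavity_probe(4.0, 6.5)
        t = Trajectory(probe, [probe.coords()] * 2)
        with pytest.warns(UserWarning, match="aligned"):
            volume_trace(t)

    def test_occupancy_half_on_alternating_trajectory(self):
        t = two_state_trajectory(6)
        og = occupancy_grid(t)
        center = tuple(og.lattice.index_of(np.zeros(3)))
        assert og.occupancy[center] == pytest.approx(0.5)

    def test_occupancy_binary_for_identical_frames(self):
        probe = make_cavity_probe(4.0, 6.5)
        t = Trajectory(probe, [probe.coords()] * 4)
        t.aligned = True
        og = occupancy_grid(t)
        assert set(np.unique(og.occupancy)) <= {0.0, 1.0}

    def test_single_frame_occupancy_equals_detection_mask(self):
        probe = make_cavity_probe(4.0, 6.5)
        t = Trajectory(probe, [probe.coords()])
        t.aligned = True
        og = occupancy_grid(t)
        ps = detect_pockets(probe, PocketConfig(), lattice=og.lattice,
                            radii=default_radii(probe))
        assert np.array_equal(og.occupancy == 1.0, ps.mask())


class TestOccupancyShells:
    def test_shells_partition_nonzero_voxels(self):
        og = occupancy_grid(two_state_trajectory(6))
        shells = [(0.0, 0.6), (0.6, 0.8), (0.8, 1.0)]
        total = sum(occupancy_shell(og, lo, hi)[0].shape[0] for lo, hi in shells)
        assert total == int((og.occupancy > 0).sum())

    def test_alternating_voxel_lands_in_middle_shell(self):
        og = occupancy_grid(two_state_trajectory(6))
        vox, _ = occupancy_shell(og, 0.4, 0.6)
        center = np.array(og.lattice.index_of(np.zeros(3)))
        assert np.any(np.all(vox == center, axis=1))

    def test_upper_bound_includes_permanent_voxels(self):
        probe = make_cavity_probe(4.0, 6.5)
        t = Trajectory(probe, [probe.coords()] * 3)
        t.aligned = True
        og = occupancy_grid(t)
        vox, vol = occupancy_shell(og, 0.8, 1.0)
        assert vol == pytest.approx(int((og.occupancy == 1).sum()) * og.lattice.voxel_volume())

    def test_invalid_bounds_rejected(self):
        og = occupancy_grid(two_state_trajectory(2))
        with pytest.raises(ValueError):
            occupancy_shell(og, 0.8, 0.6)


class TestSavitzkyGolay:
    def test_constant_series_unchanged(self):
        ts = TimeSeries(np.arange(100.0), np.full(100, 7.0))
        assert np.allclose(savitzky_golay(ts, 11, 3).values, 7.0)

    def test_cubic_polynomial_exact_at_interior(self):
        t = np.arange(200.0)
        vals = 1e-4 * t ** 3 - 0.02 * t ** 2 + 0.3 * t - 2
        sm = savitzky_golay(TimeSeries(t, vals), 21, 3)
        assert np.abs(sm.values[10:-10] - vals[10:-10]).max() < 1e-8

    def test_noise_variance_reduced(self, rng):
        vals = rng.normal(size=500)
        sm = savitzky_golay(TimeSeries(np.arange(500.0), vals), 51, 3)
        assert sm.values.var() < vals.var()

    def test_window_longer_than_series_rejected(self):
        ts = TimeSeries(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValueError, match="window"):
            savitzky_golay(ts, 11, 3)
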