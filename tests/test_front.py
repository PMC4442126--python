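"""Occupancy maps, front extraction and curvature fits."""

import numpy as np
import pytest

from afpice.front import (
    FrontSurface,
    compare_gibbs_thomson,
    extract_front,
    fit_cylinder,
    occupancy_map,
)
from afpice.synthetic import GrowthScenario, front_height, generate_growth_trajectory
from afpice.thermo import TIP4P
from afpice.traj import ROLE_WATER_O, Trajectory


def static_traj(points, box, n_frames=10):
    coords = np.tile(np.asarray(points, float)[None, :, :], (n_frames, 1, 1))
    return Trajectory(coords=coords, box=box, roles=np.full(len(points), ROLE_WATER_O))


class TestOccupancy:
    def test_immobile_lattice_gives_unit_occupancy_at_sites(self):
        pts = np.array([[5.0, 5.0, 5.0], [10.0, 10.0, 10.0]])
        traj = static_traj(pts, (15.0, 15.0, 15.0))
        with pytest.warns(UserWarning, match="frames"):
            grid = occupancy_map(traj)
        idx = np.floor(pts / grid.voxel).astype(int)
        assert grid.occupancy[tuple(idx.T)] == pytest.approx(1.0)

    def test_empty_region_has_zero_occupancy(self):
        traj = static_traj(np.array([[2.0, 2.0, 2.0]]), (20.0, 20.0, 20.0))
        with pytest.warns(UserWarning):
            grid = occupancy_map(traj)
        assert grid.occupancy[15:, 15:, 15:].max() == 0.0

    def test_ideal_gas_occupancy_matches_poisson_expectation(self, rng):
        # mean voxel occupancy for n uniform points per frame is
        # 1 - (1 - v_sphere/V)^n ~ n v_sphere / V
        box = np.array([20.0, 20.0, 20.0])
        n, frames = 40, 150
        coords = rng.uniform(0, 20, size=(frames, n, 3))
        traj = Trajectory(coords=coords, box=box, roles=np.full(n, ROLE_WATER_O))
        grid = occupancy_map(traj, radius=1.4)
        v_sphere = 4.0 / 3.0 * np.pi * 1.4**3
        p = 1.0 - (1.0 - v_sphere / box.prod()) ** n
        observed = grid.occupancy.mean()
        sd = np.sqrt(p * (1 - p) / (frames * grid.occupancy.size)) * 10
        assert observed == pytest.approx(p, abs=max(3 * sd, 0.01))

    def test_occupancy_invariant_under_integer_voxel_translation(self, rng):
        box = np.array([16.0, 16.0, 16.0])
        pts = rng.uniform(0, 16, size=(30, 3))
        t1 = static_traj(pts, box, n_frames=3)
        shifted = np.mod(pts + np.array([3.0, 5.0, 0.0]), box)
        t2 = static_traj(shifted, box, n_frames=3)
        with pytest.warns(UserWarning):
            g1 = occupancy_map(t1)
            g2 = occupancy_map(t2)
        assert g1.occupancy.sum() == pytest.approx(g2.occupancy.sum())

    def test_zero_length_window_rejected(self):
        traj = static_traj(np.array([[1.0, 1.0, 1.0]]), (10.0, 10.0, 10.0))
        with pytest.raises(ValueError, match="window"):
            occupancy_map(traj, t_start=5000.0, t_end=6000.0)


class TestExtractFront:
    def test_flat_frozen_slab_recovered_within_a_voxel(self, rng):
        # static waters fill z < 8 on a grid denser than the voxel size
        x = np.arange(0.5, 12.0, 1.0)
        pts = np.array([[xi, yi, zi] for xi in x for yi in x for zi in
                        np.arange(0.5, 8.0, 1.0)])
        traj = static_traj(pts, (12.0, 12.0, 20.0), n_frames=3)
        with pytest.warns(UserWarning):
            grid = occupancy_map(traj)
        surf = extract_front(grid, seed_top_z=0.0)
        assert np.nanmean(surf.heights) == pytest.approx(8.0, abs=1.0)

    def test_threshold_monotonicity(self):
        scn = GrowthScenario(box=(10.0, 22.2, 25.0), n_frames=120, z0=10.0, seed=2)
        traj, _ = generate_growth_trajectory(scn)
        grid = occupancy_map(traj, radius=2.3)
        lo = extract_front(grid, threshold=0.85, seed_top_z=0.0)
        hi = extract_front(grid, threshold=1.0, seed_top_z=0.0)
        assert hi.interpolated.sum() >= lo.interpolated.sum()

    def test_nothing_above_threshold_rejected(self):
        traj = static_traj(np.array([[1.0, 1.0, 1.0]]), (10.0, 10.0, 10.0))
        with pytest.warns(UserWarning):
            grid = occupancy_map(traj)
        with pytest.raises(ValueError, match="occupancy"):
            extract_front(grid, seed_top_z=5.0)

    def test_cylindrical_front_height_field_recovered(self):
        scn = GrowthScenario(
            box=(12.0, 63.3, 45.0), n_frames=200, front_model="pinned",
            z0=20.0, pin_spacing=63.3, radius=46.0, seed=11,
        )
        traj, truth = generate_growth_trajectory(scn)
        grid = occupancy_map(traj, radius=2.3)
        surf = extract_front(grid, seed_top_z=0.0, smooth=2.0)
        true_prof = front_height(scn, surf.y, 0.0)
        rms = np.sqrt(np.nanmean((surf.heights - true_prof[None, :]) ** 2))
        assert rms < 1.5


class TestCylinderFit:
    @staticmethod
    def surface_from_profile(y, z):
        heights = np.tile(z[None, :], (4, 1))
        return FrontSurface(
            heights=heights, x=np.arange(4, dtype=float), y=y,
            threshold=0.85, interpolated=np.zeros_like(heights, bool),
        )

    def test_exact_semicircle_recovered_with_zero_residual(self):
        y = np.linspace(-40.0, 40.0, 81)
        z = 10.0 + np.sqrt(50.0**2 - y**2)
        fit = fit_cylinder(self.surface_from_profile(y, z))
        assert fit.finite
        assert fit.radius == pytest.approx(50.0, abs=1e-6)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-6)
        assert fit.convex

    def test_flat_profile_reports_no_finite_curvature(self):
        y = np.linspace(0.0, 60.0, 61)
        fit = fit_cylinder(self.surface_from_profile(y, np.full_like(y, 25.0)))
        assert not fit.finite
        assert fit.radius == np.inf

    def test_noisy_46A_front_recovered_within_3A(self, rng):
        # cylindrically pinned front of radius 46 A with 1 A positional noise
        s = 63.3
        y = np.linspace(0.0, s, 64, endpoint=False)
        sag = np.sqrt(46.0**2 - (s / 2) ** 2)
        z = 20.0 - sag + np.sqrt(46.0**2 - (y - s / 2) ** 2)
        z_noisy = z + rng.normal(scale=1.0, size=z.shape)
        fit = fit_cylinder(self.surface_from_profile(y, z_noisy))
        assert fit.finite
        assert fit.radius == pytest.approx(46.0, abs=3.0)

    def test_concave_profile_flagged(self):
        y = np.linspace(-30.0, 30.0, 61)
        z = 40.0 - np.sqrt(50.0**2 - y**2)
        fit = fit_cylinder(self.surface_from_profile(y, z))
        assert fit.finite
        assert not fit.convex


class TestGibbsThomson:
    def test_matching_radius_gives_unit_ratio(self):
        theory = 45.949  # TIP4P cylindrical radius at 5 K supercooling
        rep = compare_gibbs_thomson(theory, TIP4P, 5.0)
        assert rep.ratio == pytest.approx(1.0, abs=1e-4)

    def test_double_radius_gives_ratio_two(self):
        rep = compare_gibbs_thomson(2 * 45.949, TIP4P, 5.0)
        assert rep.ratio == pytest.approx(2.0, abs=1e-3)

    def test_ratio_is_scale_free(self):
        # computing both radii in nm and converting back changes nothing
        r_angstrom = 52.0
        rep_a = compare_gibbs_thomson(r_angstrom, TIP4P, 5.0)
        rep_b = compare_gibbs_thomson((r_angstrom / 10.0) * 10.0, TIP4P, 5.0)
        assert rep_a.ratio == pytest.approx(rep_b.ratio, rel=1e-12)

    def test_infinite_fit_rejected(self):
        y = np.linspace(0.0, 60.0, 61)
        flat = fit_cylinder(
            TestCylinderFit.surface_from_profile(y, np.full_like(y, 25.0))
        )
        with pytest.raises(ValueError, match="curvature"):
            compare_gibbs_thomson(flat, TIP4P, 5.0)
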