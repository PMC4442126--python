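"""Mobility-based ice/liquid classification and ice fractions."""

import numpy as np
import pytest

from afpice.mobility import classify_ice, ice_fraction
from afpice.synthetic import GrowthScenario, generate_growth_trajectory
from afpice.traj import ROLE_SEED, ROLE_WATER_O, Trajectory


def make_traj(coords, box=(30.0, 30.0, 30.0), roles=None):
    return Trajectory(coords=np.asarray(coords, float), box=box, roles=roles)


def test_stationary_water_is_ice():
    coords = np.tile(np.array([[5.0, 5.0, 5.0]]), (6, 1, 1))
    labels = classify_ice(make_traj(coords))
    assert (labels.labels == 1).all()


def test_translating_water_is_liquid():
    # 1.0 A per frame exceeds the 0.8 A threshold in every window
    base = np.array([[5.0, 5.0, 5.0]])
    coords = np.stack([base + [0.0, 0.0, f * 1.0] for f in range(6)])
    labels = classify_ice(make_traj(coords))
    assert (labels.labels == 0).all()


def test_periodic_crossing_is_not_misread_as_motion():
    # hops between 0.05 and 29.95 across the x boundary: true motion 0.1 A
    coords = np.stack(
        [np.array([[0.05 if f % 2 else 29.95, 5.0, 5.0]]) for f in range(6)]
    )
    labels = classify_ice(make_traj(coords))
    assert (labels.labels == 1).all()


def test_endpoint_mode_differs_from_mean_mode():
    # 1.3 A oscillation: max deviation from the 3-frame mean is 0.87 A
    # (liquid for mode="mean") but the first-to-last displacement is 0
    # (ice for mode="endpoint")
    z = [5.0, 6.3, 5.0, 6.3, 5.0, 6.3]
    coords = np.array([[[5.0, 5.0, v]] for v in z])
    mean_labels = classify_ice(make_traj(coords), mode="mean")
    end_labels = classify_ice(make_traj(coords), mode="endpoint")
    assert (mean_labels.labels == 0).all()
    assert (end_labels.labels == 1).all()


def test_window_longer_than_trajectory_rejected():
    coords = np.zeros((2, 1, 3))
    with pytest.raises(ValueError, match="window"):
        classify_ice(make_traj(coords), window_frames=3)


def test_classifier_monotone_in_threshold(rng):
    coords = np.cumsum(rng.normal(scale=0.3, size=(10, 50, 3)), axis=0) + 15.0
    traj = make_traj(coords)
    tight = classify_ice(traj, disp_threshold=0.6).labels
    loose = classify_ice(traj, disp_threshold=0.8).labels
    assert ((tight == 1) <= (loose == 1)).all()


def test_time_reversal_mirrors_labels(rng):
    coords = np.cumsum(rng.normal(scale=0.5, size=(8, 30, 3)), axis=0) + 15.0
    traj = make_traj(coords)
    fwd = classify_ice(traj).labels
    rev = classify_ice(traj.reversed()).labels
    assert np.array_equal(rev, fwd[::-1])


def test_agreement_with_generator_ground_truth():
    scn = GrowthScenario(
        box=(30.0, 44.4, 40.0), n_frames=60, front_model="flat", z0=20.0, seed=3
    )
    traj, truth = generate_growth_trajectory(scn)
    labels = classify_ice(traj)
    agreement = (labels.labels.astype(bool) == truth.frozen[: labels.n_windows]).mean()
    assert agreement >= 0.99


def test_advancing_front_fraction_is_monotone_and_matches_truth():
    scn = GrowthScenario(
        box=(25.0, 44.4, 35.0), n_frames=80, front_model="flat", z0=8.0,
        velocity=2.0, seed=4,
    )
    traj, truth = generate_growth_trajectory(scn)
    labels = classify_ice(traj)
    series = ice_fraction(labels, traj)
    # monotone non-decreasing within sampling noise
    assert np.min(np.diff(series.fraction)) > -0.05
    last = labels.n_windows - 1
    z = traj.coords[last, traj.water_oxygens, 2]
    in_region = z > traj.seed_top_z()
    expected = truth.frozen[last, traj.water_oxygens][in_region].mean()
    assert series.fraction[-1] == pytest.approx(expected, abs=0.02)


def test_fully_frozen_region_has_fraction_one():
    coords = np.tile(np.random.default_rng(0).uniform(5, 25, (1, 40, 3)), (5, 1, 1))
    roles = np.array([ROLE_SEED] * 2 + [ROLE_WATER_O] * 38)
    coords[:, :2, 2] = 1.0  # seed below everything
    traj = make_traj(coords, roles=roles)
    labels = classify_ice(traj)
    series = ice_fraction(labels, traj)
    assert series.fraction == pytest.approx(1.0)


def test_constructed_half_and_half_region():
    rng = np.random.default_rng(1)
    frozen = np.tile(rng.uniform(5, 25, (1, 20, 3)), (6, 1, 1))
    mobile = np.cumsum(rng.normal(scale=3.0, size=(6, 20, 3)), axis=0) + 15.0
    seed = np.tile(np.array([[[15.0, 15.0, 1.0]]]), (6, 1, 1))
    coords = np.concatenate([seed, frozen, mobile], axis=1)
    roles = np.array([ROLE_SEED] + [ROLE_WATER_O] * 40)
    traj = make_traj(coords, box=(1000.0, 1000.0, 1000.0), roles=roles)
    labels = classify_ice(traj)
    series = ice_fraction(labels, traj, region=(2.0, 1000.0))
    assert series.fraction[0] == pytest.approx(0.5, abs=0.051)


def test_empty_region_rejected():
    coords = np.zeros((4, 2, 3)) + 5.0
    traj = make_traj(coords)
    labels = classify_ice(traj)
    with pytest.raises(ValueError, match="region"):
        ice_fraction(labels, traj, region=(100.0, 200.0))
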