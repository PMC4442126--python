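"""Synthetic-trajectory generator contracts."""

import numpy as np
import pytest

from afpice.front import extract_front, occupancy_map
from afpice.mobility import classify_ice, ice_fraction
from afpice.synthetic import (
    GrowthScenario,
    generate_binding_track,
    generate_growth_trajectory,
    make_synthetic_afp,
    write_synthetic_afp_pdb,
)


def test_identical_seeds_are_bit_identical():
    scn = GrowthScenario(box=(20.0, 22.2, 25.0), n_frames=15, z0=10.0, seed=42)
    t1, g1 = generate_growth_trajectory(scn)
    t2, g2 = generate_growth_trajectory(scn)
    assert np.array_equal(t1.coords, t2.coords)
    assert np.array_equal(g1.frozen, g2.frozen)


def test_different_seeds_differ():
    scn1 = GrowthScenario(box=(20.0, 22.2, 25.0), n_frames=5, z0=10.0, seed=1)
    scn2 = GrowthScenario(box=(20.0, 22.2, 25.0), n_frames=5, z0=10.0, seed=2)
    assert not np.array_equal(
        generate_growth_trajectory(scn1)[0].coords,
        generate_growth_trajectory(scn2)[0].coords,
    )


def test_zero_velocity_flat_front_fraction_constant():
    scn = GrowthScenario(box=(25.0, 29.6, 30.0), n_frames=40, z0=15.0, seed=6)
    traj, truth = generate_growth_trajectory(scn)
    assert (truth.frozen.sum(axis=1) == truth.frozen[0].sum()).all()
    labels = classify_ice(traj)
    series = ice_fraction(labels, traj)
    assert series.fraction.std() < 0.02


def test_front_velocity_recovered_by_windowed_extraction():
    # median front height from sliding occupancy windows (threshold 1.0
    # keeps only waters static for the whole window, i.e. the region
    # frozen since the window start); the linear fit of height against
    # window start time must recover the prescribed growth velocity
    v = 3.0  # A/ns
    win = 30  # frames per occupancy window
    scn = GrowthScenario(
        box=(15.0, 22.2, 45.0), n_frames=100, z0=8.0, velocity=v, seed=7
    )
    traj, truth = generate_growth_trajectory(scn)
    centres, heights = [], []
    with pytest.warns(UserWarning):
        for f in range(0, traj.n_frames - win, 5):
            grid = occupancy_map(
                traj, t_start=traj.times[f], t_end=traj.times[f + win - 1],
                radius=2.3,
            )
            surf = extract_front(grid, threshold=1.0, seed_top_z=0.0, max_gap=4)
            centres.append(traj.times[f] / 1000.0)
            heights.append(np.nanmedian(surf.heights))
    slope = np.polyfit(centres, heights, 1)[0]
    assert slope == pytest.approx(v, abs=0.6)


def test_ground_truth_front_matches_frozen_labels():
    scn = GrowthScenario(
        box=(15.0, 22.2, 30.0), n_frames=20, z0=9.0, velocity=5.0, seed=8
    )
    traj, truth = generate_growth_trajectory(scn)
    f = 10
    below = truth.sites[:, 2] < np.interp(
        truth.sites[:, 1], truth.front_y, truth.front_heights[f], period=scn.box[1]
    )
    assert np.array_equal(truth.frozen[f], below)


def test_separability_warnings():
    with pytest.warns(UserWarning, match="amplitude"):
        GrowthScenario(box=(10, 11, 12), n_frames=3, amplitude=0.5)
    with pytest.warns(UserWarning, match="diffusion"):
        GrowthScenario(box=(10, 11, 12), n_frames=3, diffusion=0.001)


def test_pinned_scenario_validation():
    with pytest.raises(ValueError, match="pin_spacing"):
        GrowthScenario(box=(10, 60, 40), n_frames=3, front_model="pinned")
    with pytest.raises(ValueError, match="radius"):
        GrowthScenario(
            box=(10, 60, 40), n_frames=3, front_model="pinned",
            pin_spacing=60.0, radius=20.0,
        )


def test_front_truncation_warns_when_exiting_box():
    scn = GrowthScenario(
        box=(15.0, 22.2, 20.0), n_frames=30, z0=15.0, velocity=5.0, seed=9
    )
    with pytest.warns(UserWarning, match="exits"):
        generate_growth_trajectory(scn)


def test_binding_track_determinism_and_truth():
    t1 = generate_binding_track(5.0, pin_z=30.0, n_frames=200, seed=3)
    t2 = generate_binding_track(5.0, pin_z=30.0, n_frames=200, seed=3)
    assert np.array_equal(t1[1], t2[1])
    assert t1[2].bind_time == 5000.0
    after = t1[1][60:]
    assert np.abs(after - 30.0).max() < 2.0  # pinned with small jitter


def test_synthetic_afp_has_full_ibs_and_writes_parseable_pdb(tmp_path):
    from afpice.builder import DEFAULT_IBS_RESIDUES, read_protein_pdb

    prot = make_synthetic_afp()
    og1 = set(prot.resids[prot.names == "OG1"].tolist())
    assert og1 == set(DEFAULT_IBS_RESIDUES)
    path = write_synthetic_afp_pdb(tmp_path / "afp.pdb")
    back = read_protein_pdb(path)
    assert back.n_atoms == prot.n_atoms
    assert np.allclose(back.positions, prot.positions, atol=1.5e-3)
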