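"""Tilted-seed system assembly."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from afpice.builder import (
    DEFAULT_BOX,
    PeriodicConsistencyError,
    SeedSpec,
    SimulationSystem,
    build_barrier,
    number_density,
    periodic_consistency,
    place_afp,
    read_system,
    solvate,
    tilt_seed,
    write_system,
)
from afpice.lattice import LatticeSpec, assign_protons, build_ice_lattice
from afpice.synthetic import make_synthetic_afp


@pytest.fixture(scope="module")
def paper_block():
    block = build_ice_lattice(LatticeSpec(n_a=13, n_b=3, n_c=20))
    return assign_protons(block, seed=0)


@pytest.fixture(scope="module")
def paper_slab(paper_block):
    return tilt_seed(paper_block, SeedSpec(), DEFAULT_BOX)


class TestTiltSeed:
    def test_default_angle_is_single_layer_arctangent(self, paper_slab):
        # one interlayer spacing a*sqrt(3)/2 = 3.897 A across L_y = 126.6 A
        expected = math.degrees(math.atan(4.5 * math.sqrt(3) / 2 / 126.6))
        assert paper_slab.meta["tilt_deg"] == pytest.approx(expected, abs=0.02)
        assert abs(paper_slab.meta["c_strain"]) < 0.01

    def test_periodic_consistency_of_tilted_seed(self, paper_slab):
        report = periodic_consistency(paper_slab, DEFAULT_BOX)
        assert report["closure_error"] < 1e-6
        assert report["rmsd"] < 0.1
        assert report["matched_fraction"] > 0.2

    def test_zero_tilt_zero_step_is_untilted(self, paper_block):
        slab = tilt_seed(paper_block, SeedSpec(tilt_angle=0.0, step_height=0), DEFAULT_BOX)
        assert slab.meta["tilt_deg"] == 0.0
        report = periodic_consistency(slab, DEFAULT_BOX)
        assert report["rmsd"] < 1e-9
        assert report["matched_fraction"] == pytest.approx(1.0)

    def test_incompatible_angle_rejected(self, paper_block):
        with pytest.raises(PeriodicConsistencyError, match="prism"):
            tilt_seed(paper_block, SeedSpec(tilt_angle=4.3), DEFAULT_BOX)

    def test_incompatible_angle_allowed_without_validation(self, paper_block):
        slab = tilt_seed(
            paper_block, SeedSpec(tilt_angle=4.3), DEFAULT_BOX, validate=False
        )
        assert slab.meta["tilt_deg"] == pytest.approx(4.3)

    def test_step_adds_partial_extra_layer(self, paper_block):
        with_step = tilt_seed(paper_block, SeedSpec(step_height=1), DEFAULT_BOX)
        without = tilt_seed(
            paper_block,
            SeedSpec(tilt_angle=with_step.meta["tilt_deg"], step_height=0),
            DEFAULT_BOX,
        )
        assert with_step.n_oxygens > without.n_oxygens

    def test_protons_carried_through(self, paper_slab):
        assert paper_slab.protons is not None
        assert paper_slab.protons.shape == (paper_slab.n_oxygens, 2, 3)
        d = np.linalg.norm(
            paper_slab.protons - paper_slab.oxygens[:, None, :], axis=-1
        )
        # c-strain perturbs O-H lengths by well under a percent
        assert np.allclose(d, 0.9572, atol=0.01)


class TestWaterPlacement:
    def test_barrier_count_near_reference(self):
        barrier = build_barrier(DEFAULT_BOX, thickness=5.0, seed=1)
        assert len(barrier) == pytest.approx(1049, rel=0.15)

    def test_barrier_is_clash_free(self):
        barrier = build_barrier((20.0, 20.0, 30.0), thickness=5.0, seed=2)
        d, _ = cKDTree(barrier).query(barrier, k=2)
        assert d[:, 1].min() >= 2.2 - 1e-9

    def test_zero_thickness_gives_empty_layer(self):
        assert len(build_barrier(DEFAULT_BOX, thickness=0.0)) == 0

    def test_overthick_barrier_rejected(self):
        with pytest.raises(ValueError, match="quarter"):
            build_barrier((20, 20, 30), thickness=10.0)

    def test_solvate_reaches_target_count(self):
        box = (20.0, 20.0, 30.0)
        system = SimulationSystem(
            box=np.array(box),
            seed_o=np.empty((0, 3)),
            barrier_o=build_barrier(box, 5.0, seed=3),
            free_o=np.empty((0, 3)),
        )
        out = solvate(system, target_density=970.0, seed=4)
        target = np.prod(box) * number_density(970.0)
        assert out.n_waters == pytest.approx(target, rel=0.02)

    def test_free_waters_avoid_existing_oxygens(self):
        box = (18.0, 18.0, 24.0)
        system = SimulationSystem(
            box=np.array(box),
            seed_o=np.empty((0, 3)),
            barrier_o=build_barrier(box, 4.0, seed=5),
            free_o=np.empty((0, 3)),
        )
        out = solvate(system, seed=6, barrier_thickness=4.0)
        d, _ = cKDTree(out.barrier_o).query(out.free_o, k=1)
        assert d.min() >= 2.2 - 1e-9

    def test_no_remaining_volume_gives_no_free_waters(self):
        box = (12.0, 12.0, 16.0)
        dense = np.random.default_rng(0).uniform(0, 12, size=(4000, 3))
        system = SimulationSystem(
            box=np.array(box), seed_o=dense, barrier_o=np.empty((0, 3)),
            free_o=np.empty((0, 3)),
        )
        out = solvate(system, target_density=970.0, seed=7)
        assert len(out.free_o) == 0


@pytest.fixture(scope="module")
def small_system():
    box = (40.0, 60.0, 70.0)
    block = assign_protons(build_ice_lattice(LatticeSpec(n_a=10, n_b=3, n_c=10)), 0)
    slab = tilt_seed(block, SeedSpec(step_height=0, tilt_angle=0.0), box)
    system = SimulationSystem(
        box=np.array(box), seed_o=slab.oxygens, seed_h=slab.protons,
        barrier_o=np.empty((0, 3)), free_o=np.empty((0, 3)),
    )
    return solvate(system, seed=8)


class TestPlaceAfp:
    def test_com_height_above_seed(self, small_system):
        out = place_afp(small_system, make_synthetic_afp(), height=20.0)
        com_z = out.afp.positions[:, 2].mean()
        assert com_z - out.seed_top_z == pytest.approx(20.0, abs=0.5)

    def test_orientation_flag_off_preserves_shape_orientation(self, small_system):
        afp = make_synthetic_afp()
        out = place_afp(small_system, afp, orient_ibs_down=False)
        rel_before = afp.positions - afp.positions.mean(axis=0)
        rel_after = out.afp.positions - out.afp.positions.mean(axis=0)
        assert np.allclose(rel_before, rel_after, atol=1e-9)

    def test_ibs_hydroxyls_face_the_seed(self, small_system):
        out = place_afp(small_system, make_synthetic_afp(), orient_ibs_down=True)
        og1 = out.afp.positions[out.ibs_atoms]
        assert og1[:, 2].mean() < out.afp.positions[:, 2].mean()

    def test_deleted_waters_match_brute_force_distance_scan(self, small_system):
        afp = make_synthetic_afp()
        out = place_afp(small_system, afp, clash_cutoff=2.4)
        # O(N^2) oracle: which original free waters sit within the cutoff
        diff = small_system.free_o[:, None, :] - out.afp.positions[None, :, :]
        d = np.linalg.norm(diff, axis=-1).min(axis=1)
        expected_kept = (d >= 2.4).sum()
        assert len(out.free_o) == expected_kept
        assert out.meta["n_waters_deleted"] == len(small_system.free_o) - expected_kept

    def test_missing_ibs_residues_rejected(self, small_system):
        with pytest.raises(ValueError, match="residues"):
            place_afp(small_system, make_synthetic_afp(), ibs_residues=(999,))

    def test_protein_must_fit_in_box(self, small_system):
        with pytest.raises(ValueError, match="fit"):
            place_afp(small_system, make_synthetic_afp(), height=200.0)


@pytest.fixture(scope="module")
def assembled():
    box = (30.0, 44.4, 50.0)
    block = assign_protons(build_ice_lattice(LatticeSpec(n_a=8, n_b=3, n_c=8)), 0)
    slab = tilt_seed(block, SeedSpec(), box)
    system = SimulationSystem(
        box=np.array(box), seed_o=slab.oxygens, seed_h=slab.protons,
        barrier_o=build_barrier(box, 5.0, seed=9), free_o=np.empty((0, 3)),
    )
    from afpice.builder import _random_water_hydrogens

    system.barrier_h = _random_water_hydrogens(
        system.barrier_o, np.random.default_rng(10)
    )
    return solvate(system, seed=11)


class TestSystemIO:
    def test_roundtrip_preserves_counts_and_groups(self, assembled, tmp_path):
        pdb, csv, meta = write_system(assembled, tmp_path / "sys")
        back = read_system(pdb)
        assert len(back.seed_o) == len(assembled.seed_o)
        assert len(back.barrier_o) == len(assembled.barrier_o)
        assert len(back.free_o) == len(assembled.free_o)

    def test_roundtrip_coordinates_to_writer_precision(self, assembled, tmp_path):
        pdb, *_ = write_system(assembled, tmp_path / "sys")
        back = read_system(pdb)
        assert np.allclose(back.seed_o, assembled.seed_o, atol=1.5e-3)
        assert np.allclose(back.free_o, assembled.free_o, atol=1.5e-3)

    def test_constraint_flags_in_bfactor_column(self, assembled, tmp_path):
        import MDAnalysis as mda

        pdb, *_ = write_system(assembled, tmp_path / "sys")
        u = mda.Universe(str(pdb))
        seed_b = u.select_atoms("chainID S").tempfactors
        free_b = u.select_atoms("chainID W").tempfactors
        assert (seed_b == 1.0).all()
        assert (free_b == 0.0).all()

    def test_constraint_csv_lists_constrained_oxygens(self, assembled, tmp_path):
        import pandas as pd

        _, csv, _ = write_system(assembled, tmp_path / "sys")
        df = pd.read_csv(csv)
        assert len(df) == len(assembled.seed_o) + len(assembled.barrier_o)
        assert set(df["group"]) == {"S", "B"}

    def test_oversized_coordinates_rejected(self, tmp_path):
        system = SimulationSystem(
            box=np.array([30.0, 30.0, 30.0]),
            seed_o=np.array([[1e5, 0.0, 0.0]]),
            barrier_o=np.empty((0, 3)),
            free_o=np.empty((0, 3)),
        )
        with pytest.raises(ValueError, match="field width"):
            write_system(system, tmp_path / "bad")
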