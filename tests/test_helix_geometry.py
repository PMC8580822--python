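"""Superposition, membrane frame and helix movement/rotation recovery."""

import numpy as np
import pytest

from gpcrstates.fixture_factory import (
    BundleSpec, MotionSpec, add_coordinate_noise, apply_motion,
    make_ideal_bundle, motion_with_measured_translation,
)
from gpcrstates.helix_geometry import (
    MembraneFrame, RegionSpec, class_consensus_movements,
    estimate_membrane_frame, kabsch, measure_pair, region_rotation,
    region_translation, superpose_pair,
)


def rotation_matrix(axis, deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K


class TestSuperposition:
    def test_identical_structures_identity_transform(self, bundle):
        pair = superpose_pair(bundle, bundle, receptor="X")
        assert pair.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(pair.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(pair.translation, 0.0, atol=1e-9)

    def test_global_rotation_recovered(self, bundle):
        R = rotation_matrix([0.3, -0.5, 1.0], 30.0)
        moved = bundle.transformed(R, np.array([4.0, -2.0, 7.0]))
        pair = superpose_pair(bundle, moved, receptor="X")
        assert pair.rmsd == pytest.approx(0.0, abs=1e-6)
        # recovered transform is the inverse of the applied one
        assert np.allclose(pair.rotation @ R, np.eye(3), atol=1e-6)

    def test_core_excludes_moved_region(self, bundle):
        act = apply_motion(bundle, MotionSpec.single(
            "TM6", "ic_end", (5.0, 0, 0)))
        pair = superpose_pair(bundle, act, receptor="X")
        assert pair.rmsd < 0.1
        heights = [abs(float(pair.frame.height(
            bundle.by_generic()[g].ca)[0])) for g in pair.core_positions]
        assert max(heights) <= 6.0

    def test_too_few_shared_positions_rejected(self, bundle):
        small = BundleSpec(n_helices=1, residues_per_helix=15,
                           structure_id="TINY")
        tiny = make_ideal_bundle(small)
        with pytest.raises(ValueError, match="20"):
            superpose_pair(tiny, tiny, receptor="X",
                           frame=MembraneFrame((0, 0, 0), (0, 0, 1)))


class TestMembraneFrame:
    def test_z_aligned_bundle_gives_z_normal(self, bundle):
        frame = estimate_membrane_frame(bundle)
        assert abs(frame.n[2]) == pytest.approx(1.0, abs=0.05)
        assert frame.n[2] > 0          # extracellular side is +z here
        assert np.linalg.norm(frame.c) < 1.0

    def test_flipping_structure_flips_normal(self, bundle):
        R = rotation_matrix([1.0, 0, 0], 180.0)
        flipped = bundle.transformed(R, np.zeros(3))
        frame = estimate_membrane_frame(flipped)
        assert frame.n[2] < -0.9

    def test_external_frame_returned_unchanged(self, bundle):
        ext = MembraneFrame((1.0, 2.0, 3.0), (0.0, 0.0, 1.0))
        assert estimate_membrane_frame(bundle, mode="external",
                                       external=ext) is ext

    def test_too_few_helices_rejected(self):
        tiny = make_ideal_bundle(BundleSpec(n_helices=3))
        with pytest.raises(ValueError):
            estimate_membrane_frame(tiny)

    def test_normal_must_be_unit(self):
        with pytest.raises(ValueError):
            MembraneFrame((0, 0, 0), (0, 0, 2.0))


class TestTranslationRecovery:
    def test_identical_structures_zero_everywhere(self, bundle):
        pair = superpose_pair(bundle, bundle, receptor="X")
        report = measure_pair(pair)
        for m in report.measurements.values():
            assert m["translation"] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("tm,region,target", [
        ("TM6", "ic_end", 5.0),
        ("TM1", "ec_end", 2.5),
        ("TM3", "mid", 1.5),
    ])
    def test_imposed_translation_recovered(self, bundle, tm, region, target):
        act = apply_motion(bundle, MotionSpec.single(
            tm, region, (target, 0, 0)))
        pair = superpose_pair(bundle, act, receptor="X")
        assert region_translation(pair, tm, region) == pytest.approx(
            target, abs=0.05)

    def test_unmoved_regions_stay_still(self, bundle):
        act = apply_motion(bundle, MotionSpec.single(
            "TM6", "ic_end", (5.0, 0, 0)))
        pair = superpose_pair(bundle, act, receptor="X")
        assert region_translation(pair, "TM6", "ec_end") == pytest.approx(
            0.0, abs=0.05)
        assert region_translation(pair, "TM2", "ic_end") == pytest.approx(
            0.0, abs=0.05)

    def test_short_helix_region_not_measurable(self):
        # 9-residue helices cannot host an axis window; ends unmeasurable
        tiny = make_ideal_bundle(BundleSpec(residues_per_helix=9))
        pair = superpose_pair(tiny, tiny, receptor="X")
        spec = RegionSpec(end_window=4, mid_window=5, axis_window=11)
        assert region_rotation(pair, "TM6", "ic_end", spec) is None


class TestRotationRecovery:
    def test_identical_structures_zero_rotation(self, bundle):
        pair = superpose_pair(bundle, bundle, receptor="X")
        assert region_rotation(pair, "TM6", "ic_end") == pytest.approx(
            0.0, abs=1e-6)

    @pytest.mark.parametrize("deg", [25.0, -30.0, 13.0])
    def test_own_axis_rotation_recovered(self, bundle, deg):
        act = apply_motion(bundle, MotionSpec.single(
            "TM6", "ic_end", (0, 0, 0), deg))
        pair = superpose_pair(bundle, act, receptor="X")
        assert region_rotation(pair, "TM6", "ic_end") == pytest.approx(
            deg, abs=0.5)

    def test_composed_motion_recovered_independently(self, bundle):
        motion = motion_with_measured_translation(
            bundle, "TM6", "ic_end", 4.0, rotation_deg=25.0)
        act = apply_motion(bundle, motion)
        pair = superpose_pair(bundle, act, receptor="X")
        assert region_translation(pair, "TM6", "ic_end") == pytest.approx(
            4.0, abs=0.05)
        assert region_rotation(pair, "TM6", "ic_end") == pytest.approx(
            25.0, abs=0.5)

    def test_noise_robustness(self, bundle):
        """0.3 A coordinate noise keeps recovery within 0.5 A / 5 deg."""
        act = apply_motion(bundle, MotionSpec.single(
            "TM6", "ic_end", (5.0, 0, 0), 25.0))
        for seed in range(3):
            noisy_i = add_coordinate_noise(bundle, 0.3, seed=10 + seed)
            noisy_a = add_coordinate_noise(act, 0.3, seed=20 + seed)
            pair = superpose_pair(noisy_i, noisy_a, receptor="X")
            assert region_translation(pair, "TM6", "ic_end") == \
                pytest.approx(5.0, abs=0.5)
            assert region_rotation(pair, "TM6", "ic_end") == \
                pytest.approx(25.0, abs=5.0)


class TestFrameAndLabelInvariance:
    def test_common_rigid_transform_changes_nothing(self, bundle):
        act = apply_motion(bundle, MotionSpec.single(
            "TM6", "ic_end", (5.0, 0, 0), 25.0))
        pair0 = superpose_pair(bundle, act, receptor="X")
        R = rotation_matrix([0.2, 1.0, -0.4], 55.0)
        t = np.array([12.0, -4.0, 9.0])
        pair1 = superpose_pair(bundle.transformed(R, t),
                               act.transformed(R, t), receptor="X")
        for tm in ("TM5", "TM6"):
            for region in ("ec_end", "mid", "ic_end"):
                assert region_translation(pair1, tm, region) == \
                    pytest.approx(region_translation(pair0, tm, region),
                                  abs=1e-6)
                assert region_rotation(pair1, tm, region) == \
                    pytest.approx(region_rotation(pair0, tm, region),
                                  abs=1e-5)

    def test_state_swap_negates_rotation_keeps_translation(self, bundle):
        act = apply_motion(bundle, MotionSpec.single(
            "TM6", "ic_end", (3.0, 0, 0), 20.0))
        fwd = superpose_pair(bundle, act, receptor="X")
        rev = superpose_pair(act, bundle, receptor="X")
        assert region_translation(rev, "TM6", "ic_end") == pytest.approx(
            region_translation(fwd, "TM6", "ic_end"), abs=0.05)
        assert region_rotation(rev, "TM6", "ic_end") == pytest.approx(
            -region_rotation(fwd, "TM6", "ic_end"), abs=0.5)


class TestConsensus:
    def _report(self, gpcr_class, translation):
        b = make_ideal_bundle()
        act = apply_motion(b, MotionSpec.single(
            "TM6", "ic_end", (translation, 0, 0)))
        pair = superpose_pair(b, act, receptor=f"R{translation}")
        return measure_pair(pair, gpcr_class=gpcr_class)

    def test_single_receptor_consensus(self):
        out = class_consensus_movements([self._report("F", 7.0)])
        cell = out["F"][("TM6", "ic_end")]
        assert cell["n_moving"] == 1
        assert cell["consensus"] is True

    def test_exactly_threshold_not_counted(self):
        out = class_consensus_movements([self._report("A", 1.0)])
        cell = out["A"][("TM6", "ic_end")]
        assert cell["n_measured"] == 1
        assert cell["n_moving"] == 0
        assert cell["consensus"] is False

    def test_majority_rule(self):
        reports = [self._report("A", 5.0), self._report("A", 4.0),
                   self._report("A", 0.2)]
        out = class_consensus_movements(reports)
        cell = out["A"][("TM6", "ic_end")]
        assert cell["n_moving"] == 2 and cell["consensus"] is True

    def test_kabsch_recovers_random_rigid_transform(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3)) * 5
        R = rotation_matrix(rng.normal(size=3), 40.0)
        t = np.array([1.0, -2.0, 3.0])
        Y = X @ R.T + t
        R_fit, t_fit, rmsd = kabsch(X, Y)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R_fit, R, atol=1e-9)
        assert np.allclose(t_fit, t, atol=1e-8)
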