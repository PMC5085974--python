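import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from atelect.transfer import (AlignmentError, Beam, DoseEngineError,
                              PlanGeometry, RigidTransform,
                              align_bone, align_carina, compute_toy_dose,
                              normalize_plan_to_prescription,
                              resample_to_reference, square_aperture)
from atelect.volume_io import LabelMaskSet, VolumeGrid


def _points(rng, n=8):
    return rng.uniform(0, 100, size=(n, 3))


class TestRigidTransform:
    def test_inverse_composes_to_identity(self, rng):
        R = Rotation.from_euler("xyz", [10, -5, 30], degrees=True).as_matrix()
        x = RigidTransform(R, rng.uniform(-10, 10, 3))
        ident = x.compose(x.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(ident.translation_mm, 0.0, atol=1e-9)

    def test_improper_rotation_rejected(self):
        flip = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(AlignmentError):
            RigidTransform(flip, np.zeros(3))

    def test_json_round_trip(self, rng):
        x = RigidTransform.from_translation(rng.uniform(-5, 5, 3))
        y = RigidTransform.from_dict(x.to_dict())
        assert np.allclose(x.translation_mm, y.translation_mm)


class TestAlignBone:
    def test_identity_for_identical_landmarks(self, rng):
        pts = _points(rng)
        x, rms = align_bone(pts, pts)
        assert np.allclose(x.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(x.translation_mm, 0.0, atol=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_recovered_with_opposite_sign(self, rng):
        pts = _points(rng)
        x, _ = align_bone(pts, pts + np.array([5.0, 0.0, 0.0]))
        assert np.allclose(x.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(x.translation_mm, [-5.0, 0.0, 0.0], atol=1e-9)

    def test_noiseless_rigid_motion_recovered_exactly(self, rng):
        pts = _points(rng)
        R = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        t = np.array([3.0, -4.0, 2.0])
        moved = pts @ R.T + t
        x, rms = align_bone(pts, moved)
        truth = RigidTransform(R, t).inverse()
        assert np.allclose(x.rotation, truth.rotation, atol=1e-9)
        assert np.allclose(x.translation_mm, truth.translation_mm, atol=1e-6)
        assert rms < 1e-9

    def test_noisy_rotation_recovered_within_tolerance(self, rng):
        pts = _points(rng, n=40)
        R = Rotation.from_euler("z", 10, degrees=True)
        moved = pts @ R.as_matrix().T + rng.normal(0, 0.1, size=pts.shape)
        x, rms = align_bone(pts, moved)
        angle = np.degrees(
            np.arccos(np.clip((np.trace(x.rotation) - 1) / 2, -1, 1))
        )
        assert angle == pytest.approx(10.0, abs=0.1)
        assert rms == pytest.approx(0.1, abs=0.08)

    def test_box_region_filters_landmarks(self, rng):
        pts = _points(rng)
        shifted = pts + np.array([2.0, 0.0, 0.0])
        # corrupt landmarks outside the box; fit must ignore them
        outside = pts[:, 0] > 50
        shifted[outside] += 100.0
        box = ((0, 0, 0), (50, 100, 100))
        if np.count_nonzero(~outside) >= 3:
            x, _ = align_bone(pts, shifted, box)
            assert np.allclose(x.translation_mm, [-2.0, 0.0, 0.0], atol=1e-9)

    def test_collinear_landmarks_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(AlignmentError, match="collinear"):
            align_bone(pts, pts)

    def test_too_few_landmarks_rejected(self, rng):
        pts = _points(rng, n=2)
        with pytest.raises(AlignmentError):
            align_bone(pts, pts)


class TestAlignCarina:
    def _masks(self, idx, shape=(12, 12, 12), spacing=(2.0, 2.0, 2.0)):
        m = np.zeros(shape, dtype=bool)
        m[idx] = True
        return LabelMaskSet(spacing, masks={"carina": m})

    def test_identical_masks_zero_translation(self):
        a = self._masks((slice(4, 7), slice(4, 7), slice(4, 7)))
        x = align_carina(a, a)
        assert np.allclose(x.translation_mm, 0.0)
        assert np.allclose(x.rotation, np.eye(3))

    def test_centroid_offset_recovered(self):
        a = self._masks((slice(4, 7), slice(4, 7), slice(4, 7)))
        b = self._masks((slice(4, 7), slice(5, 8), slice(3, 6)))
        x = align_carina(a, b)
        assert np.allclose(x.translation_mm, [0.0, -2.0, 2.0])

    def test_irregular_mask_centroid_matches_brute_force(self, rng):
        m = rng.uniform(size=(10, 10, 10)) > 0.7
        a = LabelMaskSet((1.5, 1.5, 2.0), masks={"carina": m})
        manual = np.mean([idx * np.array([1.5, 1.5, 2.0]) for idx in np.argwhere(m)], axis=0)
        assert np.allclose(a.centroid_world("carina"), manual)

    def test_empty_mask_rejected(self):
        a = self._masks((slice(4, 7),) * 3)
        b = LabelMaskSet((2, 2, 2), masks={"carina": np.zeros((12, 12, 12), dtype=bool)})
        with pytest.raises(AlignmentError):
            align_carina(a, b)


class TestResample:
    def test_identity_transform_is_bitwise_for_labels(self, rng):
        labels = (rng.uniform(size=(10, 10, 10)) > 0.5).astype(float)
        grid = VolumeGrid(labels, (2.0, 2.0, 2.0))
        out = resample_to_reference(grid, RigidTransform.identity(), grid, mode="nearest")
        assert np.array_equal(out.data, labels)

    def test_one_voxel_translation_is_index_shift(self, rng):
        data = rng.normal(size=(10, 10, 10))
        grid = VolumeGrid(data, (2.0, 2.0, 2.0))
        x = RigidTransform.from_translation([2.0, 0.0, 0.0])  # one voxel in +x
        out = resample_to_reference(grid, x, grid, fill_value=-1.0)
        assert np.allclose(out.data[1:, :, :], data[:-1, :, :])
        assert np.allclose(out.data[0, :, :], -1.0)

    def test_rigid_round_trip_dice_on_smooth_shape(self):
        shape = (32, 32, 32)
        ax = [np.arange(n) * 2.0 for n in shape]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        ball = ((X - 32) ** 2 + (Y - 30) ** 2 + (Z - 34) ** 2) <= 18**2
        grid = VolumeGrid(ball.astype(float), (2.0, 2.0, 2.0))
        R = Rotation.from_euler("z", 7, degrees=True).as_matrix()
        x = RigidTransform(R, np.array([1.3, -2.1, 0.7]))
        fwd = resample_to_reference(grid, x, grid, mode="nearest")
        back = resample_to_reference(fwd, x.inverse(), grid, mode="nearest")
        a, b = ball, back.data > 0.5
        dice = 2 * np.count_nonzero(a & b) / (np.count_nonzero(a) + np.count_nonzero(b))
        assert dice >= 0.98


class TestToyDoseEngine:
    def _plan(self, iso=(40.0, 40.0, 40.0), angles=(0.0,), half=20.0):
        return PlanGeometry(iso, tuple(Beam(a, square_aperture(half)) for a in angles), 60.0)

    def test_air_phantom_constant_dose_along_ray(self):
        dens = VolumeGrid(np.zeros((40, 40, 40)), (2.0, 2.0, 2.0))
        dose = compute_toy_dose(dens, self._plan())
        prof = dose.data[20, :, 20]
        inside = prof > 0
        assert inside.any()
        assert np.allclose(prof[inside], prof[inside][0])

    @pytest.mark.parametrize("angle, axis", [(0.0, 1), (90.0, 0)])
    def test_water_slab_exponential_falloff(self, angle, axis):
        """Uniform 1000 mg/cc: radiological depth equals geometric depth, so
        the central-axis log-dose slope is exactly -mu_eff per mm."""
        dens = VolumeGrid(np.full((40, 40, 40), 1000.0), (2.0, 2.0, 2.0))
        dose = compute_toy_dose(dens, self._plan(angles=(angle,)))
        sl = [20, 20, 20]
        sl[axis] = slice(None)
        prof = dose.data[tuple(sl)]
        pos = np.arange(40) * 2.0
        keep = prof > 0
        slope = np.polyfit(pos[keep], np.log(prof[keep]), 1)[0]
        assert slope == pytest.approx(-0.005, rel=1e-3)

    def test_linearity_in_beam_weight(self, rng):
        dens = VolumeGrid(rng.uniform(0, 1200, size=(24, 24, 24)), (3.0, 3.0, 3.0))
        plan = self._plan(iso=(36.0, 36.0, 36.0), angles=(0.0, 120.0, 240.0))
        d1 = compute_toy_dose(dens, plan)
        d2 = compute_toy_dose(dens, plan.scaled(2.0))
        assert np.allclose(d2.data, 2.0 * d1.data)

    def test_reaeration_raises_distal_dose(self):
        """Dose beyond a collapsed region increases once the region re-aerates
        (smaller path integral -> less attenuation)."""
        base = np.full((40, 40, 40), 260.0)
        collapsed = base.copy()
        collapsed[15:25, 10:20, 15:25] = 1050.0
        plan = self._plan()
        d_coll = compute_toy_dose(VolumeGrid(collapsed, (2.0, 2.0, 2.0)), plan)
        d_open = compute_toy_dose(VolumeGrid(base, (2.0, 2.0, 2.0)), plan)
        distal = (slice(17, 23), slice(28, 36), slice(17, 23))
        assert np.all(d_open.data[distal] >= d_coll.data[distal])
        assert d_open.data[20, 32, 20] > d_coll.data[20, 32, 20]

    def test_isocenter_outside_grid_rejected(self):
        dens = VolumeGrid(np.zeros((10, 10, 10)), (2.0, 2.0, 2.0))
        with pytest.raises(DoseEngineError, match="isocenter"):
            compute_toy_dose(dens, self._plan(iso=(500.0, 0.0, 0.0)))

    def test_normalization_hits_prescription_at_isocenter(self):
        dens = VolumeGrid(np.full((30, 30, 30), 800.0), (3.0, 3.0, 3.0))
        plan = self._plan(iso=(45.0, 45.0, 45.0), angles=(0.0, 180.0))
        plan = normalize_plan_to_prescription(plan, dens)
        dose = compute_toy_dose(dens, plan)
        idx = tuple(np.rint(dens.world_to_index(np.array([45.0, 45.0, 45.0]))).astype(int))
        assert dose.data[idx] == pytest.approx(60.0, rel=1e-9)

    def test_alignment_schemes_agree_for_pure_translation(self, small_pair):
        """The phantom's followup motion is a pure translation, so bone and
        carina alignment recover (nearly) the same transform."""
        from atelect.volume_io import landmark_array

        b = landmark_array(small_pair.baseline.landmarks)
        f = landmark_array(small_pair.followup.landmarks)
        xb, _ = align_bone(b, f)
        xc = align_carina(small_pair.baseline.masks, small_pair.followup.masks)
        assert np.allclose(xb.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(xb.translation_mm, xc.translation_mm, atol=2.0)
        assert np.allclose(
            xb.translation_mm, small_pair.truth.misalignment.translation_mm, atol=1e-9
        )
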