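import math

import numpy as np
import pytest

from atelect import synthetic as syn
from atelect.volume_io import StructureOverlapError


def _spec(**kw):
    defaults = dict(grid_shape=(48, 48, 48), spacing_mm=(5.0, 5.0, 5.0), seed=3)
    defaults.update(kw)
    return syn.PhantomSpec(**defaults)


def _ellipsoid_area_mm2(semi):
    """Thomsen approximation of ellipsoid surface area."""
    p = 1.6075
    a, b, c = semi
    return 4 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)


class TestAnalyticTruth:
    def test_no_resolution_keeps_atelectasis_volume(self):
        truth = syn.analytic_truth(_spec(
            atelectasis=syn.AtelectasisSpec(followup_resolution_fraction=0.0)))
        assert truth.atelectasis_volume_followup_ml == pytest.approx(
            truth.atelectasis_volume_baseline_ml)

    def test_pure_reaeration_conserves_mass(self):
        """Full resolution with no edema: lobe mass unchanged, density down,
        volume up (mass conservation by construction)."""
        truth = syn.analytic_truth(_spec(
            atelectasis=syn.AtelectasisSpec(
                followup_resolution_fraction=1.0, edema_excess_mass_fraction=0.0)))
        rec = truth.lobes["RLL"].change
        assert rec.pct_mass_change == pytest.approx(0.0, abs=1e-9)
        assert rec.pct_density_change < 0
        assert rec.pct_volume_change > 0

    def test_edema_mass_leaves_on_resolution(self):
        """With edema fraction e, resolving tissue sheds e/(1+e) of its mass."""
        e = 0.5
        base = _spec(atelectasis=syn.AtelectasisSpec(
            followup_resolution_fraction=1.0, edema_excess_mass_fraction=e,
            baseline_fraction_of_lobe=1.0))
        truth = syn.analytic_truth(base)
        b = truth.lobes["RLL"].baseline
        f = truth.lobes["RLL"].followup
        lost = b.mass_mg - f.mass_mg
        resolved_mass = 1050.0 * truth.atelectasis_volume_baseline_ml
        assert lost == pytest.approx(resolved_mass * e / (1 + e), rel=1e-9)

    def test_large_baseline_reduction_and_label(self):
        """200 ml baseline atelectasis at 90% resolution: 180 ml reduction,
        labelled full."""
        scale = ((200.0 + syn.TumorSpec().baseline_volume_ml) / 0.85
                 / syn.default_lobe_geometry()["RLL"].volume_ml) ** (1 / 3)
        geom = dict(syn.default_lobe_geometry())
        rll = geom["RLL"]
        geom["RLL"] = syn.LobeGeometry(rll.center_mm,
                                       tuple(s * scale for s in rll.semi_axes_mm))
        truth = syn.analytic_truth(_spec(
            lobe_geometry=geom,
            atelectasis=syn.AtelectasisSpec(followup_resolution_fraction=0.9)))
        assert truth.atelectasis_volume_baseline_ml == pytest.approx(200.0, rel=1e-9)
        reduction = (truth.atelectasis_volume_baseline_ml
                     - truth.atelectasis_volume_followup_ml)
        assert reduction == pytest.approx(180.0, rel=1e-9)
        assert truth.resolution_label == "full"

    def test_target_density_change_is_hit_exactly(self):
        truth = syn.analytic_truth(_spec(
            atelectasis=syn.AtelectasisSpec(
                followup_resolution_fraction=0.5, target_density_change=-0.30)))
        assert truth.lobes["RLL"].change.pct_density_change == pytest.approx(-30.0)

    def test_tumor_regression_alone_leaves_lobe_minus_tumor_unchanged(self):
        truth = syn.analytic_truth(_spec(
            atelectasis=syn.AtelectasisSpec(followup_resolution_fraction=0.0),
            tumor=syn.TumorSpec(regression_fraction=0.6)))
        rec = truth.lobes["RLL"].change
        assert rec.pct_mass_change == pytest.approx(0.0, abs=1e-9)
        assert rec.pct_volume_change == pytest.approx(0.0, abs=1e-9)


class TestGeneratePair:
    def test_regeneration_is_bit_identical(self):
        a = syn.generate_pair(_spec(seed=42))
        b = syn.generate_pair(_spec(seed=42))
        assert np.array_equal(a.baseline.raw.data, b.baseline.raw.data)
        assert np.array_equal(a.followup.raw.data, b.followup.raw.data)

    def test_different_seeds_differ(self):
        a = syn.generate_pair(_spec(seed=1))
        b = syn.generate_pair(_spec(seed=2))
        assert not np.array_equal(a.baseline.raw.data, b.baseline.raw.data)

    def test_voxel_volumes_match_analytic_within_surface_shell(self, default_pair):
        """Voxel count x voxel volume agrees with the analytic volume within
        one voxel shell of the shape's surface area, at both time points."""
        spec = default_pair.spec
        h = max(spec.spacing_mm)
        for tp, key in ((default_pair.baseline, "baseline"), (default_pair.followup, "followup")):
            for name, lt in default_pair.truth.lobes.items():
                analytic = getattr(lt, key).volume_ml
                if name == spec.atelectasis.lobe:
                    analytic += (spec.tumor.baseline_volume_ml if key == "baseline"
                                 else default_pair.truth.followup_geometry["v_tumor_f"])
                measured = tp.masks.volume_ml(name)
                semis = syn._semis_for_volume(
                    np.asarray(spec.lobe_geometry[name].semi_axes_mm), analytic)
                shell_ml = _ellipsoid_area_mm2(semis) * h / 1000.0
                assert abs(measured - analytic) < shell_ml, (name, key)

    def test_atelectasis_mask_volumes_track_truth(self, default_pair):
        tr = default_pair.truth
        vv = default_pair.baseline.masks.voxel_volume_ml
        assert default_pair.baseline.masks.volume_ml("atelectasis") == pytest.approx(
            tr.atelectasis_volume_baseline_ml, abs=60 * vv)
        assert default_pair.followup.masks.volume_ml("atelectasis") == pytest.approx(
            tr.atelectasis_volume_followup_ml, abs=60 * vv)

    def test_structures_present_and_disjoint(self, small_pair):
        masks = small_pair.baseline.masks
        for name in ["LUL", "LLL", "RUL", "RML", "RLL", "tumor_gtv", "ctv",
                     "atelectasis", "spinal_cord", "esophagus", "heart",
                     "air_ref", "blood_ref", "carina", "bone"]:
            assert name in masks and np.any(masks[name]), name
        masks.validate_lobes_disjoint()
        assert not np.any(masks["tumor_gtv"] & ~masks["RLL"])
        assert not np.any(masks["atelectasis"] & ~masks["RLL"])

    def test_followup_is_translated_by_the_misalignment(self, small_pair):
        t = -small_pair.truth.misalignment.translation_mm  # baseline -> followup
        lm_b = small_pair.baseline.landmarks[["x_mm", "y_mm", "z_mm"]].to_numpy()
        lm_f = small_pair.followup.landmarks[["x_mm", "y_mm", "z_mm"]].to_numpy()
        assert np.allclose(lm_f, lm_b + t)

    def test_overlapping_geometry_request_rejected(self):
        geom = dict(syn.default_lobe_geometry())
        geom["RML"] = geom["RUL"]  # two lobes on the same ellipsoid
        with pytest.raises(StructureOverlapError):
            syn.generate_pair(_spec(lobe_geometry=geom))

    def test_tumor_larger_than_core_rejected(self):
        with pytest.raises(ValueError, match="core"):
            _spec(tumor=syn.TumorSpec(baseline_radius_mm=40.0)).validate()


class TestCohort:
    def test_eighteen_patients_split_four_nine_five(self):
        counts = syn.class_counts(18, syn.DEFAULT_EFFECT_PROFILE)
        assert counts == {"full": 4, "partial": 9, "none": 5}

    def test_single_patient_assignment_deterministic(self):
        a = [lbl for lbl, _ in syn.cohort_specs(1, seed=5)]
        b = [lbl for lbl, _ in syn.cohort_specs(1, seed=5)]
        assert a == b and len(a) == 1

    def test_programmed_class_mean_recovered_in_truth(self):
        """Single-class cohort of 50 with -66% +/- 5% programmed density
        change: the mean of the generator's own truth records lands within
        2 points of the programmed mean."""
        profile = {"full": syn.ClassEffect(1.0, -66.0, 5.0, (0.85, 0.98), 0.10)}
        specs = syn.cohort_specs(50, profile, seed=9)
        changes = [
            syn.analytic_truth(spec).lobes["RLL"].change.pct_density_change
            for _, spec in specs
        ]
        assert np.mean(changes) == pytest.approx(-66.0, abs=2.0)

    def test_cohort_reproducible_by_seed(self):
        a = syn.cohort_specs(6, seed=4)
        b = syn.cohort_specs(6, seed=4)
        assert [l for l, _ in a] == [l for l, _ in b]
        assert all(sa == sb for (_, sa), (_, sb) in zip(a, b))

    def test_truth_labels_match_programmed_classes(self):
        for label, spec in syn.cohort_specs(18, seed=2):
            assert syn.analytic_truth(spec).resolution_label == label
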