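import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zeonco.quantification import (
    QuantificationError,
    aggregate_cohort,
    call_metastasis,
    growth_ratio,
    quantify_larva,
    x_variance,
)
from zeonco.segmentation import LarvaSegmentation, SegmentedMass, segment_larva
from zeonco.synthetic import SyntheticLarvaSpec, render_larva


def _mass(count, cx, primary=False, cz=0.0, cy=0.0):
    return SegmentedMass(
        1, count, float(count), (cz, cy, cx), ((0, 1),) * 3, is_primary=primary
    )


def _seg(masses, larva_id="L001", eye=(0.0, 0.0, 0.0), tp="tp2"):
    return LarvaSegmentation(
        larva_id=larva_id,
        timepoint_tag=tp,
        threshold_used=50.0,
        background=10.0,
        masses=masses,
        eye_um=eye,
    )


class TestGrowthRatio:
    def test_arithmetic(self):
        assert growth_ratio(100.0, 370.0) == pytest.approx(3.7)

    def test_identity(self):
        assert growth_ratio(123.4, 123.4) == 1.0

    def test_zero_tp1_flagged(self):
        with pytest.raises(QuantificationError):
            growth_ratio(0.0, 50.0)


class TestXVariance:
    def test_single_focus_is_zero(self):
        assert x_variance([42.0]) == 0.0
        assert x_variance([]) == 0.0

    def test_hand_computed_n_minus_1(self):
        assert x_variance([-1.0, 1.0]) == pytest.approx(2.0)

    def test_normal_draws_recover_sigma_squared(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 100.0, size=10_000)
        assert abs(x_variance(x) - 1e4) / 1e4 < 0.05

    @given(
        st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=50)
    )
    def test_matches_two_pass_formula(self, xs):
        """Sample variance equals the brute-force two-pass computation."""
        mean = sum(xs) / len(xs)
        brute = sum((v - mean) ** 2 for v in xs) / (len(xs) - 1)
        assert x_variance(xs) == pytest.approx(brute, rel=1e-9, abs=1e-9)


class TestCallMetastasis:
    def test_primary_only_false(self):
        assert call_metastasis(_seg([_mass(100, 150.0, primary=True)])) is False

    def test_caudal_focus_true(self):
        seg = _seg([_mass(100, 150.0, primary=True), _mass(40, 650.0)])
        assert call_metastasis(seg) is True

    def test_focus_within_min_distance_not_called(self):
        seg = _seg([_mass(100, 150.0, primary=True), _mass(40, 200.0)])
        assert call_metastasis(seg, min_distance_um=100.0) is False
        assert call_metastasis(seg, min_distance_um=30.0) is True

    def test_no_masses_false(self):
        assert call_metastasis(_seg([])) is False


class TestQuantifyLarva:
    def _segment(self, spec, tp):
        return segment_larva(render_larva(spec, tp), eye_annotation_um=spec.eye_center)

    def test_ground_truth_recovery(self, small_spec):
        seg1 = self._segment(small_spec, "tp1")
        seg2 = self._segment(small_spec, "tp2")
        q = quantify_larva(seg1, seg2)
        assert abs(q.growth_ratio - small_spec.growth_factor) / small_spec.growth_factor < 0.10
        assert q.metastasis is False
        assert q.n_secondary_tp2 == 0

    def test_identical_timepoints_give_unit_ratio(self, small_spec):
        seg1 = self._segment(small_spec, "tp1")
        seg1b = self._segment(small_spec, "tp1")
        seg1b.timepoint_tag = "tp2"
        q = quantify_larva(seg1, seg1b)
        assert q.growth_ratio == 1.0

    def test_disseminating_larva_recovers_foci(self):
        spec = SyntheticLarvaSpec(
            larva_id="L002",
            grid_shape=(30, 80, 200),
            voxel_size=(2.0, 1.0, 1.0),
            primary_center=(30.0, 40.0, 70.0),
            primary_semi_axes=(10.0, 12.0, 12.0),
            eye_center=(30.0, 40.0, 20.0),
            eye_radius=8.0,
            growth_factor=2.0,
            disseminate=True,
            n_foci=2,
            foci_radius=6.0,
            foci_centers=((30.0, 30.0, 175.0), (30.0, 55.0, 190.0)),
            noise_sd=2.0,
            seed=21,
        )
        q = quantify_larva(self._segment(spec, "tp1"), self._segment(spec, "tp2"))
        assert q.n_secondary_tp2 == 2
        assert q.metastasis is True
        # segmented focus positions agree with generator truth to a few µm
        assert np.allclose(
            sorted(q.foci_rel_x_tp2), sorted(spec.foci_rel_x), atol=5.0
        )

    def test_mismatched_larva_ids_rejected(self):
        a = _seg([_mass(10, 0.0, primary=True)], larva_id="A")
        b = _seg([_mass(10, 0.0, primary=True)], larva_id="B")
        with pytest.raises(QuantificationError, match="different larvae"):
            quantify_larva(a, b)

    def test_missing_tp1_primary_rejected(self):
        a = _seg([], larva_id="A")
        b = _seg([_mass(10, 0.0, primary=True)], larva_id="A")
        with pytest.raises(QuantificationError, match="no primary"):
            quantify_larva(a, b)


class TestAggregateCohort:
    def _quant(self, ratio, metastasis=False, foci=()):
        from zeonco.quantification import LarvaQuant

        return LarvaQuant(
            larva_id="L",
            v_tp1_um3=100.0,
            v_tp2_um3=100.0 * ratio,
            growth_ratio=ratio,
            foci_rel_x_tp2=tuple(foci),
            x_variance_um2=x_variance(foci),
            n_secondary_tp2=len(foci),
            metastasis=metastasis,
        )

    def test_constant_group(self):
        out = aggregate_cohort([self._quant(2.0)] * 3, ["g"] * 3)
        assert out.loc[0, "mean_ratio"] == 2.0
        assert out.loc[0, "sd_ratio"] == 0.0

    def test_incidence_percentage(self):
        quants = [self._quant(1.0, metastasis=(i < 3)) for i in range(4)]
        out = aggregate_cohort(quants, ["g"] * 4)
        assert out.loc[0, "incidence_pct"] == 75.0

    def test_pooled_variance_over_all_foci(self):
        quants = [
            self._quant(1.0, foci=(100.0, 200.0)),
            self._quant(1.0, foci=(300.0,)),
        ]
        out = aggregate_cohort(quants, ["g"] * 2)
        assert out.loc[0, "pooled_x_variance_um2"] == pytest.approx(
            x_variance([100.0, 200.0, 300.0])
        )

    def test_groups_kept_separate(self):
        quants = [self._quant(1.0), self._quant(3.0)]
        out = aggregate_cohort(quants, ["a", "b"])
        assert set(out["group"]) == {"a", "b"}

    def test_mean_recovery_16_larvae(self):
        rng = np.random.default_rng(1)
        ratios = rng.normal(3.7, 0.5, size=16)
        quants = [self._quant(r) for r in ratios]
        out = aggregate_cohort(quants, ["g"] * 16)
        se = out.loc[0, "sd_ratio"] / np.sqrt(out.loc[0, "n"])
        assert abs(out.loc[0, "mean_ratio"] - 3.7) < 2 * se + 1e-9


class TestScaleInvariance:
    def test_ratio_invariant_under_intensity_scaling(self, small_spec):
        s1 = render_larva(small_spec, "tp1")
        s2 = render_larva(small_spec, "tp2")
        kwargs = dict(
            eye_annotation_um=small_spec.eye_center,
            method="fixed",
            min_voxels=30,
        )
        r_base = (
            segment_larva(s2, fixed_threshold=55.0, **kwargs).primary.volume_um3
            / segment_larva(s1, fixed_threshold=55.0, **kwargs).primary.volume_um3
        )
        s1x = s1.with_intensities(s1.intensities * 3.0)
        s2x = s2.with_intensities(s2.intensities * 3.0)
        r_scaled = (
            segment_larva(s2x, fixed_threshold=165.0, **kwargs).primary.volume_um3
            / segment_larva(s1x, fixed_threshold=165.0, **kwargs).primary.volume_um3
        )
        assert r_scaled == pytest.approx(r_base, rel=1e-12)


def test_recovered_ratio_monotone_in_growth_factor():
    """For fixed noise/geometry the recovered mean ratio increases with g."""
    means = []
    for g in (0.5, 1.0, 2.0, 4.0):
        ratios = []
        for seed in range(4):
            spec = SyntheticLarvaSpec(
                grid_shape=(30, 80, 160),
                voxel_size=(2.0, 1.0, 1.0),
                primary_center=(30.0, 40.0, 80.0),
                primary_semi_axes=(10.0, 12.0, 12.0),
                eye_center=(30.0, 40.0, 20.0),
                eye_radius=8.0,
                growth_factor=g,
                noise_sd=5.0,
                seed=seed,
            )
            seg1 = segment_larva(
                render_larva(spec, "tp1"), eye_annotation_um=spec.eye_center
            )
            seg2 = segment_larva(
                render_larva(spec, "tp2"), eye_annotation_um=spec.eye_center
            )
            ratios.append(quantify_larva(seg1, seg2).growth_ratio)
        means.append(np.mean(ratios))
    assert all(a < b for a, b in zip(means, means[1:]))
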