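"""SNR/CNR estimators, aggregation, Wilcoxon signed-rank, score tables."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from angioqa.phantom import make_pair
from angioqa.quality_metrics import (
    CnrResult,
    DegenerateInputError,
    NoVariabilityError,
    ScoreTable,
    SnrResult,
    aggregate_metric,
    cnr,
    detection_rate,
    load_reference_scores,
    paired_wilcoxon,
    score_mean,
    score_total,
    snr_difference,
)
from angioqa.volume import Volume3D


def constant_pair(value=100.0, sigma=10.0, shape=(47, 47, 47), seeds=(1, 2)):
    vol = Volume3D(np.full(shape, value), (1, 1, 1))
    return make_pair(vol, sigma, seed_a=seeds[0], seed_b=seeds[1])


class TestSnrDifference:
    def test_noiseless_pair_is_degenerate(self):
        pair = constant_pair(sigma=0.0)
        with pytest.raises(DegenerateInputError):
            snr_difference(pair, np.ones(pair.volume_a.shape, dtype=bool))

    def test_closed_form_recovery(self):
        """Constant signal S with noise sigma: the halved-convention estimator
        converges to S / (2 sigma) = 5.0 (half the conventional value)."""
        pair = constant_pair(value=100.0, sigma=10.0)  # 47^3 > 1e5 voxels
        res = snr_difference(pair, np.ones(pair.volume_a.shape, dtype=bool))
        assert res.snr == pytest.approx(5.0, rel=0.02)

    def test_nema_convention_is_twice_halved_form(self):
        pair = constant_pair()
        roi = np.ones(pair.volume_a.shape, dtype=bool)
        halved = snr_difference(pair, roi, convention="halved")
        nema = snr_difference(pair, roi, convention="nema")
        assert nema.snr == pytest.approx(2.0 * halved.snr, rel=1e-12)

    def test_scale_invariance(self):
        pair = constant_pair()
        roi = np.ones(pair.volume_a.shape, dtype=bool)
        scaled = make_pair(Volume3D(np.full((47, 47, 47), 300.0), (1, 1, 1)), 30.0, 1, 2)
        base = snr_difference(pair, roi).snr
        tripled = snr_difference(scaled, roi).snr
        assert tripled == pytest.approx(base, rel=1e-9)  # identical seeds, scaled by 3

    def test_invariant_identity_holds(self):
        pair = constant_pair()
        res = snr_difference(pair, np.ones(pair.volume_a.shape, dtype=bool))
        assert res.snr == pytest.approx(res.mean_signal / (np.sqrt(2) * res.sigma_diff), rel=1e-14)


class TestCnr:
    @staticmethod
    def two_region_volume(sv=300.0, sb=60.0, sigma=10.0, n_side=22, seed=3):
        rng = np.random.default_rng(seed)
        data = np.full((2 * n_side, n_side, n_side), sb)
        data[:n_side] = sv
        data = data + rng.normal(0, sigma, data.shape)
        vol = Volume3D(data, (1, 1, 1))
        vessel = np.zeros(data.shape, dtype=bool)
        vessel[:n_side] = True
        return vol, vessel, ~vessel

    def test_closed_form_recovery(self):
        vol, vessel, paren = self.two_region_volume()  # 10648 voxels per ROI
        res = cnr(vol, vessel, paren)
        assert res.cnr == pytest.approx(240.0 / (10.0 * np.sqrt(2)), rel=0.02)

    def test_null_contrast_near_zero(self):
        vol, vessel, paren = self.two_region_volume(sv=60.0, sb=60.0)
        assert abs(cnr(vol, vessel, paren).cnr) < 0.05

    def test_antisymmetry_exact(self):
        vol, vessel, paren = self.two_region_volume()
        assert cnr(vol, vessel, paren).cnr == -cnr(vol, paren, vessel).cnr

    def test_unequal_roi_sizes_rejected(self):
        vol, vessel, paren = self.two_region_volume()
        paren = paren.copy()
        paren[np.argwhere(paren)[0][0], 0, 0] = False
        with pytest.raises(ValueError):
            cnr(vol, vessel, paren)

    def test_zero_variance_everywhere_is_degenerate(self):
        vol = Volume3D(np.full((10, 10, 10), 7.0), (1, 1, 1))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask_a, mask_b = mask.copy(), mask.copy()
        mask_a[:5] = True
        mask_b[5:] = True
        with pytest.raises(DegenerateInputError):
            cnr(vol, mask_a, mask_b)


class TestAggregateMetric:
    @staticmethod
    def as_results(values, acq="a"):
        return [SnrResult(acq, f"roi{i}", v, 0, 1) for i, v in enumerate(values)]

    def test_small_group_statistics(self):
        out = aggregate_metric(self.as_results([1.0, 2.0, 3.0]))
        row = out.iloc[0]
        assert (row["mean"], row["median"], row["sd"]) == (2.0, 2.0, 1.0)

    def test_percentile_convention_linear_interpolation(self):
        out = aggregate_metric(self.as_results(list(range(1, 101))))
        assert out.iloc[0]["q25"] == pytest.approx(25.75)
        assert out.iloc[0]["q75"] == pytest.approx(75.25)

    def test_order_invariance(self, rng):
        vals = list(rng.normal(size=30))
        a = aggregate_metric(self.as_results(vals))
        b = aggregate_metric(self.as_results(list(reversed(vals))))
        pd.testing.assert_frame_equal(a, b)

    def test_single_entry_group_sd_undefined(self):
        out = aggregate_metric(self.as_results([4.2]))
        assert np.isnan(out.iloc[0]["sd"])

    def test_caliber_grouping_uses_cnr_results(self):
        res = [CnrResult("a", f"r{i}", float(i), 0, 0, 1, 1, c)
               for i, c in enumerate(["large", "large", "small"])]
        out = aggregate_metric(res, "caliber_class")
        assert set(out["group"]) == {"large", "small"}


class TestPairedWilcoxon:
    def test_identical_samples_raise(self):
        with pytest.raises(NoVariabilityError):
            paired_wilcoxon([1.0, 2, 3, 4, 5, 6], [1.0, 2, 3, 4, 5, 6])

    def test_all_positive_differences_exact_p(self):
        """n=6, all differences positive: statistic 0 and two-sided
        p = 2/2^6, checked against full enumeration of sign assignments."""
        a = [2.0, 3, 4, 5, 6, 7]
        b = [1.0, 1, 1, 1, 1, 1]
        stat, p = paired_wilcoxon(a, b)
        assert stat == 0.0
        # brute force: all 2^6 sign assignments of ranks 1..6
        ranks = np.arange(1, 7)
        null = [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=6)]
        p_enum = 2 * sum(1 for w in null if w <= 0) / len(null)
        assert p == pytest.approx(p_enum) == pytest.approx(0.03125)

    def test_swap_mirrors_statistic_same_p(self, rng):
        a = list(rng.normal(size=12))
        b = list(rng.normal(size=12))
        stat_ab, p_ab = paired_wilcoxon(a, b)
        stat_ba, p_ba = paired_wilcoxon(b, a)
        assert p_ab == pytest.approx(p_ba, rel=1e-12)
        assert stat_ab + stat_ba == pytest.approx(12 * 13 / 2)

    def test_matches_scipy_exact_without_ties(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        a = rng.normal(size=15)
        b = rng.normal(size=15)
        _, p = paired_wilcoxon(a, b)
        ref = scipy_wilcoxon(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_matches_scipy_normal_approximation_above_threshold(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        a = rng.normal(size=40)
        b = rng.normal(size=40)
        _, p = paired_wilcoxon(a, b)
        ref = scipy_wilcoxon(a, b, alternative="two-sided", method="approx", correction=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1.0, 2.0], [0.0, 1.0])


class TestScoreTables:
    def test_grand_means_are_exact_rationals(self):
        table = load_reference_scores()
        assert Fraction(score_mean(table, "7T")).limit_denominator(100) == Fraction(81, 28)
        assert Fraction(score_mean(table, "3T")).limit_denominator(100) == Fraction(64, 28)

    def test_small_vessel_and_pontine_subset_means(self):
        table = load_reference_scores()
        small = ("lenticulostriate", "thalamic_perforating")
        assert score_mean(table, "7T", small) == pytest.approx(3.50)
        assert score_mean(table, "3T", small) == pytest.approx(1.625)
        assert score_mean(table, "7T", ("pontine_perforating",)) == pytest.approx(1.0)
        assert score_mean(table, "3T", ("pontine_perforating",)) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "volunteer,fs,total",
        [(1, "7T", 21), (2, "7T", 23), (3, "7T", 18), (4, "7T", 19),
         (1, "3T", 20), (2, "3T", 15), (3, "3T", 14), (4, "3T", 15)],
    )
    def test_per_volunteer_totals(self, volunteer, fs, total):
        assert score_total(load_reference_scores(), volunteer, fs) == total

    def test_all_zero_synthetic_table(self):
        rows = [{"vessel_category": c, "volunteer_id": 1, "field_strength": "7T", "score": 0}
                for c in ("a", "b", "c")]
        table = ScoreTable(pd.DataFrame(rows))
        assert score_total(table, 1, "7T") == 0

    def test_empty_selection_and_missing_category_raise(self):
        table = load_reference_scores()
        with pytest.raises(ValueError):
            score_mean(table, "7T", ("no_such_vessel",))
        with pytest.raises(ValueError):
            score_total(table, 99, "7T")

    def test_invalid_scores_rejected(self):
        df = pd.DataFrame([{"vessel_category": "a", "volunteer_id": 1,
                            "field_strength": "7T", "score": 5}])
        with pytest.raises(ValueError):
            ScoreTable(df)


class TestDetectionRate:
    def test_study_detection_rates(self):
        assert round(detection_rate(16, 19), 1) == 84.2
        assert round(detection_rate(27, 32)) == 84
        assert detection_rate(0, 7) == 0.0

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            detection_rate(5, 4)
        with pytest.raises(ValueError):
            detection_rate(-1, 4)
        with pytest.raises(ValueError):
            detection_rate(0, 0)
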