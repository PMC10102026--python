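import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nct import freqmatch as fm
from nct.synthetic import CohortSpec, gen_expression_cohort


class TestBinomialBand:
    def test_study_band_matches_published_intervals(self):
        band = fm.binomial_band(20, 0.35)
        assert band.expected == pytest.approx(7.0)
        assert band.iqr == (6, 8)
        assert band.ci90 == (4, 11)

    def test_degenerate_probability(self):
        band = fm.binomial_band(12, 0.0)
        assert band.expected == 0
        assert band.iqr == (0, 0)
        assert band.ci90 == (0, 0)

    def test_symmetric_case_against_enumeration(self):
        band = fm.binomial_band(10, 0.5)
        assert band.iqr == (4, 6)
        assert band.ci90 == (2, 8)

    @settings(max_examples=60, deadline=None)
    @given(n=st.integers(1, 50), p=st.sampled_from(np.arange(0.05, 1.0, 0.05).round(2).tolist()))
    def test_endpoints_match_exact_cdf_enumeration(self, n, p):
        # brute-force oracle: cumulative sums of the exact pmf
        band = fm.binomial_band(n, p)
        from scipy.special import comb
        k = np.arange(n + 1)
        pmf = comb(n, k) * p ** k * (1 - p) ** (n - k)
        cdf = np.cumsum(pmf)
        invert = lambda level: int(np.searchsorted(cdf, level - 1e-12))
        assert band.iqr == (invert(0.25), invert(0.75))
        assert band.ci90 == (invert(0.05), invert(0.95))
        lo5, lo25, hi75, hi95 = band.ci90[0], band.iqr[0], band.iqr[1], band.ci90[1]
        assert 0 <= lo5 <= lo25 <= hi75 <= hi95 <= n


class TestThresholdsAndCounts:
    def test_interpolated_percentiles_of_1_to_20(self):
        p10, p90 = fm.control_thresholds(np.arange(1, 21))
        assert p10 == pytest.approx(2.9)
        assert p90 == pytest.approx(18.1)

    def test_constant_vector(self):
        assert fm.control_thresholds(np.full(10, 3.5)) == (3.5, 3.5)

    def test_outlier_keeps_p90_finite_and_bounded(self):
        v = np.concatenate([np.random.default_rng(0).normal(size=19), [1e6]])
        p10, p90 = fm.control_thresholds(v)
        assert np.isfinite(p90) and p90 <= v.max()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fm.control_thresholds([1.0, 2.0, 3.0, np.nan, np.nan])

    def test_counts_use_strict_inequalities(self):
        above, below = fm.count_events([1, 2, 3, 9, 9, 10], (1.0, 9.0))
        # 1.0 and 9.0 are exactly at the thresholds: not events
        assert (above, below) == (1, 0)

    def test_all_inside_gives_zero(self):
        assert fm.count_events([5, 6, 7], (1.0, 9.0)) == (0, 0)

    def test_empty_vector(self):
        assert fm.count_events([], (0.0, 1.0)) == (0, 0)


class TestClassification:
    BAND = fm.binomial_band(20, 0.35)

    @pytest.mark.parametrize("count,tier", [
        (7, "high_priority"), (6, "high_priority"), (8, "high_priority"),
        (11, "candidate"), (4, "candidate"),
        (12, "unmatched"), (3, "unmatched"), (0, "unmatched"),
    ])
    def test_tiers(self, count, tier):
        assert self.BAND.classify(count) == tier

    def test_classify_count_requires_matching_n(self):
        with pytest.raises(ValueError, match="samples"):
            fm.classify_count(5, 1, self.BAND, n_samples=16)

    def test_direction_tie_flagged_up(self):
        matched, direction, tied, _ = fm.classify_count(5, 5, self.BAND, 20)
        assert (matched, direction, tied) == (5, "up", True)

    def test_sum_mode_pools_directions(self):
        matched, _, _, tier = fm.classify_count(4, 3, self.BAND, 20, mode="sum")
        assert matched == 7 and tier == "high_priority"

    def test_invariant_under_joint_monotone_transform(self):
        rng = np.random.default_rng(1)
        minus = rng.normal(8, 1, 20)
        plus = rng.normal(8, 2, 20)
        f = lambda x: np.exp(0.3 * np.asarray(x)) + 5
        t_raw = fm.control_thresholds(minus)
        t_tr = fm.control_thresholds(f(minus))
        assert fm.count_events(plus, t_raw) == fm.count_events(f(plus), t_tr)


class TestHeterogeneityScreen:
    @staticmethod
    def _cohort(n_genes=300, n_planted=0, seed=0, var_factor=10.0):
        rng = np.random.default_rng(seed)
        cols = [f"b{i}" for i in range(20)] + [f"p{i}" for i in range(16)]
        samples = pd.DataFrame({
            "condition": "plusAP",
            "sample_type": ["biological"] * 20 + ["poolsplit"] * 16,
        }, index=cols)
        sd = 0.3
        vals = rng.normal(8.0, sd, (n_genes, 36))
        vals[:n_planted, :20] = rng.normal(
            8.0, sd * np.sqrt(var_factor), (n_planted, 20))
        return fm.ExpressionMatrix(pd.DataFrame(vals, columns=cols), samples)

    def test_null_flag_rate_within_fdr(self):
        em = self._cohort(n_genes=1000, seed=2)
        out = fm.heterogeneity_screen(em, "plusAP")
        assert out["flagged"].mean() <= 0.1

    def test_planted_variance_is_detected(self):
        em = self._cohort(n_genes=1000, n_planted=50, seed=3)
        out = fm.heterogeneity_screen(em, "plusAP")
        assert out["flagged"][:50].mean() >= 0.9

    def test_undetected_gene_excluded(self):
        em = self._cohort(n_genes=10, seed=4)
        det = pd.DataFrame(True, index=em.values.index, columns=em.values.columns)
        det.iloc[0, :12] = False  # undetected in 12 of 20 biological samples
        em = fm.ExpressionMatrix(em.values, em.samples, det)
        out = fm.heterogeneity_screen(em, "plusAP")
        assert not out["tested"].iloc[0]
        assert not out["flagged"].iloc[0]

    def test_missing_poolsplit_is_an_error(self):
        cols = [f"b{i}" for i in range(20)]
        samples = pd.DataFrame({"condition": "plusAP",
                                "sample_type": "biological"}, index=cols)
        em = fm.ExpressionMatrix(
            pd.DataFrame(np.zeros((5, 20)), columns=cols), samples)
        with pytest.raises(ValueError, match="pool-and-split"):
            fm.heterogeneity_screen(em, "plusAP")


class TestEndToEndRecovery:
    def test_planted_genes_recovered_null_genes_quiet(self):
        em, truth = gen_expression_cohort(CohortSpec(seed=11))
        calls = fm.frequency_matching(em)
        labels = truth["labels"]
        planted = [g for g, l in labels.items() if l == "frequency_matched"]
        nulls = [g for g, l in labels.items() if l == "null"]
        scored = set(calls.index)
        tiers = calls.loc[[g for g in planted if g in scored], "tier"]
        assert (tiers != "unmatched").mean() >= 0.6
        null_called = [g for g in nulls
                       if g in scored and calls.loc[g, "tier"] != "unmatched"]
        assert len(null_called) / len(nulls) <= 0.10


class TestPenetranceStats:
    def test_extreme_proportions(self):
        assert fm.penetrance_stats([0, 0], [10, 10])["transformed_mean"] == 0.0
        out = fm.penetrance_stats([10, 10], [10, 10])
        assert out["transformed_mean"] == pytest.approx(np.pi / 2)
        assert out["proportion"] == pytest.approx(1.0)

    def test_zero_total_replicate_excluded_with_note(self):
        out = fm.penetrance_stats([3, 0], [10, 0])
        assert out["n"] == 1 and out["notes"]

    def test_type_i_error_calibration(self):
        rng = np.random.default_rng(9)
        n_sims, alpha_hits = 600, 0
        for _ in range(n_sims):
            a = rng.binomial(200, 0.35, 8)
            b = rng.binomial(200, 0.35, 8)
            out = fm.penetrance_stats(a, np.full(8, 200), other=(b, np.full(8, 200)))
            alpha_hits += out["p_two_sided"] < 0.05
        rate = alpha_hits / n_sims
        assert 0.02 < rate < 0.09
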