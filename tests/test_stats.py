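import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from rsibreast import (
    levene,
    pairwise_wilcoxon_bonferroni,
    ranked_rm_anova,
    shapiro_wilk,
    wilcoxon_signed_rank,
)
from rsibreast.stats import StatsError, bonferroni


def brute_force_signed_rank_p(diffs):
    """Oracle: exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    eps = 1e-9
    cdf = np.mean(ws <= w_obs + eps)
    sf = np.mean(ws >= w_obs - eps)
    return min(1.0, 2.0 * min(cdf, sf))


class TestShapiroWilk:
    def test_constant_sample_rejected(self):
        with pytest.raises(StatsError):
            shapiro_wilk([1.0] * 10)

    def test_too_few_values_rejected(self):
        with pytest.raises(StatsError):
            shapiro_wilk([1.0, 2.0])

    def test_exponential_sample_fails_normality(self):
        rng = np.random.default_rng(0)
        report = shapiro_wilk(rng.exponential(size=50))
        assert report.p_raw < 0.05

    def test_gaussian_sample_passes_normality(self):
        rng = np.random.default_rng(1)
        report = shapiro_wilk(rng.normal(size=50))
        assert report.p_raw > 0.05


class TestLevene:
    def test_location_shift_preserves_variance_equality(self):
        rng = np.random.default_rng(2)
        g = rng.normal(size=50)
        report = levene([g, g + 5.0])
        assert report.statistic == pytest.approx(0.0, abs=1e-10)
        assert report.p_raw > 0.99

    def test_scaled_group_detected(self):
        rng = np.random.default_rng(3)
        report = levene([rng.normal(size=50), 10.0 * rng.normal(size=50)])
        assert report.p_raw < 0.05

    def test_single_group_rejected(self):
        with pytest.raises(StatsError):
            levene([[1.0, 2.0, 3.0]])


class TestWilcoxonSignedRank:
    def test_five_concordant_pairs_exact_p(self):
        w, p = wilcoxon_signed_rank([1.0, 2.0, 0.5, 3.0, 1.5])
        assert w == 15.0
        assert p == pytest.approx(0.0625)
        assert bonferroni(p, 3) == pytest.approx(0.1875)

    def test_bonferroni_caps_at_one(self):
        assert bonferroni(0.5, 3) == 1.0

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(size=12)
        _, p_ab = wilcoxon_signed_rank(x, y)
        _, p_ba = wilcoxon_signed_rank(y, x)
        assert p_ab == pytest.approx(p_ba, abs=1e-14)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(StatsError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_scipy_exact_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, size=12)
        d = d[d != 0]
        _, p = wilcoxon_signed_rank(d)
        p_scipy = sps.wilcoxon(d, method="exact").pvalue
        assert p == pytest.approx(p_scipy, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration_with_ties(self, seed):
        # integer differences force tied |d| ranks; oracle enumerates 2^n
        rng = np.random.default_rng(100 + seed)
        d = rng.integers(-4, 5, size=10).astype(float)
        d = d[d != 0]
        if d.size == 0:
            return
        _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    def test_normal_approximation_above_cutoff(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.5, 1.0, size=60)
        _, p_approx = wilcoxon_signed_rank(d, exact_cutoff=25)
        p_scipy = sps.wilcoxon(d, correction=True, method="approx").pvalue
        assert p_approx == pytest.approx(p_scipy, rel=1e-6)

    @settings(derandomize=True, max_examples=40)
    @given(
        p=st.floats(0.0, 1.0),
        q=st.floats(0.0, 1.0),
        m=st.integers(1, 10),
    )
    def test_bonferroni_monotone_and_dominates_raw(self, p, q, m):
        assert bonferroni(p, m) >= p
        if p <= q:
            assert bonferroni(p, m) <= bonferroni(q, m)


def _cohort_table(rng, effect=0.0, n_patients=12, metrics=("C1", "C2")):
    rows = []
    for i in range(n_patients):
        for t, shift in (("malignant", effect), ("benign", 0.0), ("healthy", 0.0)):
            for m in metrics:
                rows.append(
                    {
                        "patient_id": f"p{i:02d}",
                        "tissue": t,
                        "metric": m,
                        "median": rng.lognormal(shift if m == "C1" else 0.0, 0.5),
                    }
                )
    return pd.DataFrame(rows)


class TestRankedRmAnova:
    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        table = _cohort_table(rng, effect=1.0)
        r1 = ranked_rm_anova(table)
        table2 = table.assign(median=np.exp(table["median"]))
        r2 = ranked_rm_anova(table2)
        for a, b in zip(r1, r2):
            assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
            assert a.p_raw == pytest.approx(b.p_raw, rel=1e-12)

    def test_large_tissue_effect_detected_and_matches_permutation_oracle(self):
        rng = np.random.default_rng(9)
        table = _cohort_table(rng, effect=2.0, metrics=("C1",))
        report = ranked_rm_anova(table, within=("tissue",))[0]
        assert report.p_raw < 0.05

        # permutation oracle: permute tissue labels within each patient
        def stat(tbl):
            return ranked_rm_anova(tbl, within=("tissue",))[0].statistic

        obs = stat(table)
        perm_rng = np.random.default_rng(10)
        count = 0
        n_perm = 200
        for _ in range(n_perm):
            shuffled = table.copy()
            shuffled["tissue"] = (
                shuffled.groupby("patient_id")["tissue"]
                .transform(lambda s: perm_rng.permutation(s.to_numpy()))
            )
            count += stat(shuffled) >= obs
        p_perm = (count + 1) / (n_perm + 1)
        assert p_perm < 0.05

    def test_all_equal_values_degenerate_result(self):
        rng = np.random.default_rng(11)
        table = _cohort_table(rng)
        table["median"] = 1.0
        reports = ranked_rm_anova(table)
        assert all(r.p_raw == 1.0 and r.statistic == 0.0 for r in reports)

    def test_unbalanced_table_names_missing_cells(self):
        rng = np.random.default_rng(12)
        table = _cohort_table(rng).iloc[:-1]
        with pytest.raises(StatsError, match="cells"):
            ranked_rm_anova(table)

    def test_reports_main_effects_and_interaction(self):
        rng = np.random.default_rng(13)
        reports = ranked_rm_anova(_cohort_table(rng))
        assert [r.comparison for r in reports] == [
            "tissue",
            "metric",
            "tissue * metric",
        ]


class TestPairwiseWilcoxon:
    def test_three_pairs_with_adjustment(self):
        rng = np.random.default_rng(14)
        table = _cohort_table(rng, effect=2.0, metrics=("C1",))
        reports = pairwise_wilcoxon_bonferroni(table, "C1")
        assert len(reports) == 3
        for r in reports:
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p_raw))
            assert r.p_adjusted >= r.p_raw
        strong = [r for r in reports if "malignant" in r.comparison]
        assert all(r.p_adjusted < 0.05 for r in strong)

    def test_missing_metric_rejected(self):
        rng = np.random.default_rng(15)
        with pytest.raises(StatsError):
            pairwise_wilcoxon_bonferroni(_cohort_table(rng), "ADC")
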