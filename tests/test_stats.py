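"""Cohort statistics: effect sizes, tests, ROC/Youden, screened logistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from brainage.stats import (
    GroupSummary,
    SeparationError,
    ancova_age_adjusted,
    anova_oneway,
    chi_square_2x2,
    cohens_d_pooled,
    correlate,
    mann_whitney,
    pairwise_posthoc,
    roc_youden,
    screen_and_fit_logistic,
    two_sample_t,
)

G = GroupSummary


class TestCohensD:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (G(70, 0.6, 1.1), G(24, 0.0, 1.0), 0.56),     # BrainAGE z
            (G(70, 51.19, 2.43), G(24, 52.31, 2.64), -0.45),  # GM % ICV
            (G(70, 36.85, 1.99), G(24, 36.89, 1.45), -0.02),  # WM % ICV
            (G(70, 11.96, 2.50), G(24, 10.80, 2.13), 0.48),   # CSF % ICV
            (G(70, 0.179, 0.339), G(24, 0.061, 0.156), 0.39),  # WMH mL
        ],
    )
    def test_published_group_summaries(self, a, b, expected):
        assert round(cohens_d_pooled(a, b), 2) == expected

    def test_identical_summaries_zero(self):
        assert cohens_d_pooled(G(10, 5.0, 2.0), G(10, 5.0, 2.0)) == 0.0

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = G(int(rng.integers(2, 50)), float(rng.normal()), float(rng.uniform(0.1, 3)))
        b = G(int(rng.integers(2, 50)), float(rng.normal()), float(rng.uniform(0.1, 3)))
        assert cohens_d_pooled(a, b) == pytest.approx(-cohens_d_pooled(b, a))

    def test_zero_pooled_sd_unequal_means(self):
        with pytest.raises(ZeroDivisionError):
            cohens_d_pooled(G(5, 1.0, 0.0), G(5, 2.0, 0.0))


class TestTwoSampleT:
    def test_published_brainage_p(self):
        res = two_sample_t(G(70, 0.6, 1.1), G(24, 0.0, 1.0), variant="student")
        assert round(res.p_value, 2) == 0.02
        assert res.df == 92

    def test_identical_groups(self):
        res = two_sample_t(G(10, 3.0, 1.0), G(12, 3.0, 1.0))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_scipy_on_raw_vectors(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=18), rng.normal(0.8, size=14)
        mine = two_sample_t(x, y)
        ref = sps.ttest_ind(x, y)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-10)
        welch = two_sample_t(x, y, variant="welch")
        refw = sps.ttest_ind(x, y, equal_var=False)
        assert welch.p_value == pytest.approx(refw.pvalue, rel=1e-10)

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 1.0, size=15)
        y = rng.normal(0.7, 1.0, size=12)
        obs = two_sample_t(x, y).statistic
        pooled = np.concatenate([x, y])
        n_perm = 100_000
        ranks = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
        perm = pooled[ranks]
        px, py = perm[:, : len(x)], perm[:, len(x):]
        vx, vy = px.var(axis=1, ddof=1), py.var(axis=1, ddof=1)
        sp2 = ((len(x) - 1) * vx + (len(y) - 1) * vy) / (len(pooled) - 2)
        t_perm = (px.mean(axis=1) - py.mean(axis=1)) / np.sqrt(
            sp2 * (1 / len(x) + 1 / len(y)))
        p_perm = np.mean(np.abs(t_perm) >= abs(obs))
        assert two_sample_t(x, y).p_value == pytest.approx(p_perm, abs=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            two_sample_t(G(5, 1.0, 0.0), G(5, 1.0, 0.0))


class TestMannWhitney:
    def test_exact_small_sample(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert "exact" in res.method

    def test_identical_groups_nonsignificant(self):
        x = np.arange(10.0)
        res = mann_whitney(x, x)
        assert res.p_value > 0.9

    def test_large_shift_significant(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = rng.normal(2.0, size=60)
        res = mann_whitney(y, x)
        assert res.p_value < 0.001
        assert "asymptotic" in res.method


class TestAnova:
    def test_all_identical_groups(self):
        res = anova_oneway([[1.0, 1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(0.5, size=15)
        f = anova_oneway([x, y]).statistic
        t = two_sample_t(x, y).statistic
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1.0, size=12) for m in (0.0, 0.5, 1.0)]
        obs = anova_oneway(groups).statistic
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        n_perm = 20_000
        count = 0
        for i in range(n_perm):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            count += sps.f_oneway(*parts).statistic >= obs
        assert anova_oneway(groups).p_value == pytest.approx(count / n_perm, abs=0.01)

    def test_kruskal_variant(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1.0, size=20) for m in (0.0, 0.0, 1.5)]
        res = anova_oneway(groups, variant="kruskal")
        ref = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value < 0.01

    def test_pairwise_bonferroni(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 0.5, size=20) for m in (0.0, 0.0, 3.0)]
        table = pairwise_posthoc(groups, ["a", "b", "c"])
        assert len(table) == 3
        sig = table[table.significant]
        assert set(map(tuple, sig[["a", "b"]].to_numpy())) == {("a", "c"), ("b", "c")}
        assert (table.p_bonferroni >= table.p_raw - 1e-12).all()


class TestAncova:
    def test_zero_age_slope_gives_raw_means(self):
        rng = np.random.default_rng(7)
        values = np.r_[rng.normal(0, 0.1, 20), rng.normal(1, 0.1, 20)]
        labels = np.array(["a"] * 20 + ["b"] * 20)
        ages = rng.uniform(20, 60, 40)  # independent of values
        adjusted, _ = ancova_age_adjusted(values, labels, ages)
        assert adjusted["a"] == pytest.approx(values[:20].mean(), abs=0.15)
        assert adjusted["b"] == pytest.approx(values[20:].mean(), abs=0.15)

    def test_recovers_constructed_offsets_exactly(self):
        ages = np.tile(np.linspace(20, 60, 10), 3)
        labels = np.repeat(["a", "b", "c"], 10)
        offsets = {"a": 0.0, "b": 0.7, "c": 1.5}
        values = 0.01 * ages + np.array([offsets[g] for g in labels])
        adjusted, res = ancova_age_adjusted(values, labels, ages)
        grand = 0.01 * ages.mean()
        for g, off in offsets.items():
            assert adjusted[g] == pytest.approx(grand + off, abs=1e-10)
        assert res.p_value < 1e-10

    def test_constant_age_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            ancova_age_adjusted([1, 2, 3, 4], ["a", "a", "b", "b"], [40, 40, 40, 40])


class TestCorrelate:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert correlate(x, x).estimate == pytest.approx(1.0)

    def test_spearman_monotone_transform(self):
        x = np.arange(1.0, 11.0)
        y = -np.exp(x)  # monotone decreasing transform
        assert correlate(x, y, method="spearman").estimate == pytest.approx(-1.0)

    def test_sampling_distribution(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            cov = [[1, 0.5], [0.5, 1]]
            xy = rng.multivariate_normal([0, 0], cov, size=200)
            r = correlate(xy[:, 0], xy[:, 1]).estimate
            hits += 0.35 <= r <= 0.62
        assert hits >= 9

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            correlate([1, 1, 1], [1, 2, 3])


class TestChiSquare:
    def test_published_dmard_table(self):
        res, odds = chi_square_2x2([[19, 5], [22, 24]])
        assert round(res.p_value, 2) == 0.01
        assert odds.odds_ratio == pytest.approx((19 * 24) / (5 * 22), rel=1e-12)
        assert round(odds.odds_ratio, 2) == 4.15
        assert odds.ci_low < odds.odds_ratio < odds.ci_high

    def test_independent_table(self):
        res, _ = chi_square_2x2([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestRocYouden:
    def test_perfect_separation_midpoint(self):
        res = roc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.threshold == pytest.approx(6.5)
        assert res.j_statistic == pytest.approx(1.0)
        assert res.auc == pytest.approx(1.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(8, 40))
            scores = rng.normal(size=n)
            outcome = (scores + rng.normal(size=n) > 0).astype(int)
            if outcome.min() == outcome.max():
                continue
            res = roc_youden(scores, outcome)
            uniq = np.sort(np.unique(scores))
            grid = np.concatenate(
                [[uniq[0] - 1, uniq[-1] + 1], (uniq[:-1] + uniq[1:]) / 2])
            j_grid = max(
                (scores[outcome == 1] >= c).mean() + (scores[outcome == 0] < c).mean() - 1
                for c in grid
            )
            assert res.j_statistic == pytest.approx(j_grid, abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=30)
        outcome = (scores + rng.normal(scale=0.5, size=30) > 0).astype(int)
        base = roc_youden(scores, outcome)
        trans = roc_youden(np.exp(scores), outcome)
        assert trans.j_statistic == pytest.approx(base.j_statistic)
        # the chosen threshold separates the same subjects
        assert np.array_equal(np.exp(scores) >= trans.threshold, scores >= base.threshold)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden([1.0, 2.0, 3.0], [1, 1, 1])


class TestScreening:
    @staticmethod
    def _data(seed, n=200, true_or=None):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            {f"x{i}": rng.normal(size=n) for i in range(10)}
        )
        if true_or is None:
            logits = np.zeros(n)
        else:
            logits = np.log(true_or) * table["x0"]
        p = 1 / (1 + np.exp(-logits))
        outcome = (rng.random(n) < p).astype(int)
        return table, outcome

    def test_duplicated_covariate_excluded(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=100)
        y = (x + rng.normal(size=100) > 0).astype(int)
        table = pd.DataFrame({"a": x, "a_copy": x})
        report = screen_and_fit_logistic(table, y)
        assert report.excluded_collinear == ["a_copy"]
        assert report.entered == ["a"]

    def test_null_covariates_rarely_enter(self):
        counts = []
        for seed in range(10):
            table, outcome = self._data(seed)
            report = screen_and_fit_logistic(table, outcome)
            counts.append(len(report.entered))
        assert np.mean(counts) <= 4  # expected 2 of 10 at p < 0.2

    def test_recovers_strong_odds_ratio(self):
        hits = 0
        for seed in range(10):
            table, outcome = self._data(200 + seed, true_or=6.0)
            report = screen_and_fit_logistic(table, outcome)
            row = report.final_model.set_index("variable").loc["x0"]
            hits += row.ci_low <= 6.0 <= row.ci_high
        assert hits >= 9

    def test_binary_covariates_use_chi_square(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame({"flag": rng.integers(0, 2, 120).astype(float)})
        outcome = rng.integers(0, 2, 120)
        report = screen_and_fit_logistic(table, outcome)
        assert report.univariate.iloc[0].method == "chi-square"

    def test_separation_raises(self):
        table = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
        outcome = np.r_[np.zeros(20), np.ones(20)].astype(int)
        with pytest.raises(SeparationError):
            screen_and_fit_logistic(table, outcome, p_enter=1.1)
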