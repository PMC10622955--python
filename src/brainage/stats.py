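"""The cohort statistical plan.

Group contrasts use Cohen's d with the pooled SD and Student (or Welch)
t-tests; skewed outcomes (WMH volumes) use Mann-Whitney U; three-group
comparisons use one-way ANOVA or Kruskal-Wallis with Bonferroni pairwise
follow-up; biomarker contrasts are age-adjusted with an ANCOVA; the
high/low BrainAGE cutoff comes from a ROC analysis maximizing the Youden
index against low reaction-time performance; and risk-factor modelling is
a univariate screen (p < 0.2 to enter), a pairwise-correlation collinearity
exclusion (|r| > 0.6), and a multivariate logistic regression.

No multiplicity adjustment is applied across table rows (only the pairwise
post-hoc comparisons are Bonferroni-adjusted), mirroring common clinical
reporting practice; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


@dataclass(frozen=True)
class GroupSummary:
    """n / mean / sample SD of one variable in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        v = np.asarray(values, dtype=np.float64)
        return cls(n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)))


@dataclass(frozen=True)
class TestResult:
    """A statistical test outcome: statistic, degrees of freedom, p, method."""

    statistic: float
    df: float | tuple[float, ...] | None
    p_value: float
    method: str
    estimate: float | None = None  # e.g. correlation coefficient, odds ratio

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class StratificationConfig:
    """High/low BrainAGE stratification rule."""

    outcome_score: str = "reaction_time"
    outcome_cutoff: float = 80.0   # standardized score defining low performance
    brainage_cutoff: float = 0.9   # z; re-derived per cohort by roc_youden

    def __post_init__(self) -> None:
        if not (np.isfinite(self.outcome_cutoff) and np.isfinite(self.brainage_cutoff)):
            raise ValueError("cutoffs must be finite")


# ---------------------------------------------------------------------------
# Effect sizes and two-group tests


def cohens_d_pooled(a: GroupSummary, b: GroupSummary) -> float:
    """Standardized mean difference (a - b) over the pooled SD."""
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    if sp2 == 0:
        if a.mean == b.mean:
            return 0.0
        raise ZeroDivisionError("zero pooled SD with unequal means: effect size undefined")
    return (a.mean - b.mean) / float(np.sqrt(sp2))


def _as_summary(x) -> GroupSummary:
    return x if isinstance(x, GroupSummary) else GroupSummary.from_values(x)


def two_sample_t(a, b, variant: Literal["student", "welch"] = "student") -> TestResult:
    """Two-sided two-sample t-test from raw vectors or group summaries."""
    a, b = _as_summary(a), _as_summary(b)
    va, vb = a.sd**2, b.sd**2
    if va == 0 and vb == 0:
        raise ZeroDivisionError("zero variance in both groups")
    if variant == "student":
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / (a.n + b.n - 2)
        se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = a.n + b.n - 2
    elif variant == "welch":
        se = np.sqrt(va / a.n + vb / b.n)
        df = (va / a.n + vb / b.n) ** 2 / (
            (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
        )
    else:
        raise ValueError("variant must be 'student' or 'welch'")
    t = (a.mean - b.mean) / se
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), f"{variant}-t")


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, otherwise
    the tie-corrected normal approximation."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per group")
    small = max(len(x), len(y)) <= 20
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (small and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), None, float(res.pvalue), f"mann-whitney-{method}")


# ---------------------------------------------------------------------------
# Multi-group comparisons


def anova_oneway(
    groups: Sequence[Sequence[float]],
    variant: Literal["anova", "kruskal"] = "anova",
) -> TestResult:
    """One-way ANOVA F (or Kruskal-Wallis H) across >= 2 groups."""
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence against equal locations
        return TestResult(0.0, None, 1.0, variant)
    if variant == "anova":
        stat, p = sps.f_oneway(*arrays)
        df = (len(arrays) - 1, len(pooled) - len(arrays))
    elif variant == "kruskal":
        stat, p = sps.kruskal(*arrays)
        df = float(len(arrays) - 1)
    else:
        raise ValueError("variant must be 'anova' or 'kruskal'")
    return TestResult(float(stat), df, float(p), variant)


def pairwise_posthoc(
    groups: Sequence[Sequence[float]],
    names: Sequence[str],
    variant: Literal["anova", "kruskal"] = "anova",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise follow-up to a significant omnibus test."""
    m = len(list(combinations(range(len(groups)), 2)))
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        if variant == "anova":
            res = two_sample_t(groups[i], groups[j])
        else:
            res = mann_whitney(groups[i], groups[j])
        p_adj = min(1.0, res.p_value * m)
        rows.append(
            {
                "a": names[i],
                "b": names[j],
                "p_raw": res.p_value,
                "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def ancova_age_adjusted(
    values: Sequence[float],
    group_labels: Sequence[str],
    ages: Sequence[float],
) -> tuple[dict[str, float], TestResult]:
    """Group comparison adjusted for age: linear model value ~ group + age.

    Returns adjusted group means evaluated at the grand-mean age, and the
    group-effect F test from the common-slope model.
    """
    y = np.asarray(values, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    labels = np.asarray(group_labels)
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    # age must vary within groups, else it is collinear with the group dummies
    if all(np.ptp(ages[labels == g]) == 0 for g in names):
        raise np.linalg.LinAlgError(
            "age is constant within every group: age adjustment is not estimable"
        )
    dummies = np.column_stack([(labels == g).astype(float) for g in names[1:]])
    X_full = sm.add_constant(np.column_stack([dummies, ages]))
    fit_full = sm.OLS(y, X_full).fit()
    X_null = sm.add_constant(ages)
    fit_null = sm.OLS(y, X_null).fit()
    df_num = len(names) - 1
    df_den = fit_full.df_resid
    f = (fit_null.ssr - fit_full.ssr) / df_num / (fit_full.ssr / df_den)
    p = sps.f.sf(f, df_num, df_den)
    grand = ages.mean()
    params = fit_full.params
    base = params[0] + params[-1] * grand
    adjusted = {names[0]: float(base)}
    for k, g in enumerate(names[1:]):
        adjusted[g] = float(base + params[1 + k])
    return adjusted, TestResult(float(f), (float(df_num), float(df_den)), float(p), "ancova")


# ---------------------------------------------------------------------------
# Correlation and categorical association


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> TestResult:
    """Correlation coefficient with a two-sided p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroDivisionError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return TestResult(float(r), float(len(x) - 2), float(p), method, estimate=float(r))


@dataclass(frozen=True)
class OddsRatioCI:
    odds_ratio: float
    ci_low: float
    ci_high: float


def chi_square_2x2(table: Sequence[Sequence[float]]) -> tuple[TestResult, OddsRatioCI]:
    """Pearson chi-square (no continuity correction) and the Woolf-CI odds ratio."""
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    a, b = t[0]
    c, d = t[1]
    if min(a, b, c, d) == 0:
        orr, ci = np.inf if b * c == 0 else 0.0, (np.nan, np.nan)
        odds = OddsRatioCI(orr, *ci)
    else:
        orr = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = sps.norm.ppf(0.975)
        odds = OddsRatioCI(float(orr), float(orr * np.exp(-z * se)), float(orr * np.exp(z * se)))
    return TestResult(float(chi2), float(dof), float(p), "chi-square"), odds


# ---------------------------------------------------------------------------
# ROC / Youden stratification


@dataclass(frozen=True)
class YoudenResult:
    threshold: float
    j_statistic: float
    curve: pd.DataFrame  # threshold, sens, spec, J
    auc: float


def roc_youden(scores: Sequence[float], binary_outcome: Sequence[int]) -> YoudenResult:
    """Optimal score threshold by the Youden index J = sens + spec - 1.

    Candidate thresholds are the midpoints between consecutive sorted unique
    scores; a subject is called positive when score >= threshold (higher
    scores are assumed to indicate the outcome).  Ties in J are broken
    toward higher specificity, i.e. the largest tied threshold.
    """
    s = np.asarray(scores, dtype=np.float64)
    o = np.asarray(binary_outcome, dtype=int)
    if set(np.unique(o)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    n_pos, n_neg = int(o.sum()), int((1 - o).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValueError("scores are constant")
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    sens = np.array([(s[o == 1] >= c).mean() for c in cands])
    spec = np.array([(s[o == 0] < c).mean() for c in cands])
    j = sens + spec - 1
    best_j = j.max()
    # ties toward higher specificity = largest threshold among the tied set
    best = np.flatnonzero(np.isclose(j, best_j))[-1]
    curve = pd.DataFrame({"threshold": cands, "sens": sens, "spec": spec, "J": j})
    # trapezoidal AUC over the ROC points (1-spec, sens) plus the corners
    fpr = np.concatenate([[1.0], 1 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return YoudenResult(float(cands[best]), float(best_j), curve, auc)


def bootstrap_threshold_spread(
    scores: Sequence[float],
    binary_outcome: Sequence[int],
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """SD of the Youden threshold across bootstrap resamples (instability flag)."""
    s = np.asarray(scores, dtype=np.float64)
    o = np.asarray(binary_outcome, dtype=int)
    rng = np.random.default_rng(seed)
    thresholds = []
    for _ in range(n_boot):
        idx = rng.integers(len(s), size=len(s))
        if len(set(o[idx])) < 2 or len(np.unique(s[idx])) < 2:
            continue
        thresholds.append(roc_youden(s[idx], o[idx]).threshold)
    return float(np.std(thresholds)) if thresholds else np.inf


# ---------------------------------------------------------------------------
# Screened multivariate logistic regression


class SeparationError(RuntimeError):
    """Maximum-likelihood logistic fit failed to converge (e.g. separation)."""


@dataclass
class ScreeningReport:
    """Univariate screen -> collinearity exclusion -> logistic model."""

    univariate: pd.DataFrame          # variable, p
    entered: list[str]
    excluded_collinear: list[str]
    final_model: pd.DataFrame | None  # variable, coef, odds_ratio, ci_low, ci_high, p


def screen_and_fit_logistic(
    table: pd.DataFrame,
    outcome: Sequence[int],
    p_enter: float = 0.2,
    r_exclude: float = 0.6,
) -> ScreeningReport:
    """The risk-factor modelling plan for a binary outcome.

    Continuous covariates are screened with a Student t-test between outcome
    groups, binary (0/1) covariates with a Pearson chi-square.  Covariates
    with univariate p < ``p_enter`` are candidates; among candidate pairs
    with |Pearson r| > ``r_exclude`` the later-listed variable is dropped
    (column order is the declared priority).  The remaining covariates enter
    a maximum-likelihood logistic regression (Newton/IRLS); Wald CIs.
    """
    y = np.asarray(outcome, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")

    uni_rows = []
    for col in table.columns:
        v = table[col].to_numpy(dtype=np.float64)
        is_binary = set(np.unique(v)) <= {0.0, 1.0}
        if is_binary:
            ct = np.array(
                [
                    [np.sum((v == 1) & (y == 1)), np.sum((v == 1) & (y == 0))],
                    [np.sum((v == 0) & (y == 1)), np.sum((v == 0) & (y == 0))],
                ]
            )
            if (ct.sum(axis=0) == 0).any() or (ct.sum(axis=1) == 0).any():
                p = 1.0
            else:
                p = chi_square_2x2(ct)[0].p_value
            method = "chi-square"
        else:
            p = two_sample_t(v[y == 1], v[y == 0]).p_value
            method = "student-t"
        uni_rows.append({"variable": col, "p": p, "method": method})
    univariate = pd.DataFrame(uni_rows)

    candidates = [r["variable"] for r in uni_rows if r["p"] < p_enter]
    excluded: list[str] = []
    kept: list[str] = []
    for var in candidates:  # column order = priority; drop the later-listed
        collinear = any(
            abs(correlate(table[var], table[prev]).estimate) > r_exclude for prev in kept
        )
        (excluded if collinear else kept).append(var)

    final = None
    if kept:
        X = sm.add_constant(table[kept].to_numpy(dtype=np.float64))
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise SeparationError(f"logistic fit failed: {exc}") from exc
        if not fit.mle_retvals.get("converged", False):
            raise SeparationError("logistic MLE did not converge (possible separation)")
        ci = fit.conf_int()
        rows = []
        for i, var in enumerate(kept, start=1):
            rows.append(
                {
                    "variable": var,
                    "coef": float(fit.params[i]),
                    "odds_ratio": float(np.exp(fit.params[i])),
                    "ci_low": float(np.exp(ci[i][0])),
                    "ci_high": float(np.exp(ci[i][1])),
                    "p": float(fit.pvalues[i]),
                }
            )
        final = pd.DataFrame(rows)
    return ScreeningReport(univariate, kept, excluded, final)
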