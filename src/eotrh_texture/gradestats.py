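"""Grade-wise statistics: normality-gated group comparison (ANOVA + Tukey HSD
or Kruskal-Wallis + Dunn), compact letter display, and slope/intercept
similarity testing between measure series by sequential linear regression.

The branch rule is conservative: the parametric branch is taken only when
every grade group passes Shapiro-Wilk at the configured alpha. Dunn's
pairwise p-values are Bonferroni-adjusted over all pairs; Tukey HSD carries
its own family-wise control.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ParameterError, ValidationError

_PERFECT_FIT_SSR = 1e-10
_ZERO_COEF = 1e-8


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    normality_rule: str = "all_groups_pass"  # or "pooled_residuals"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if self.normality_rule not in ("all_groups_pass", "pooled_residuals"):
            raise ParameterError("unknown normality rule")


@dataclass
class GroupComparison:
    measure: str
    group_n: dict[int, int]
    group_mean: dict[int, float]
    group_sd: dict[int, float]
    branch: str  # "anova_tukey" | "kw_dunn" | "degenerate"
    omnibus_p: float | None
    pairwise_p: dict[tuple[int, int], float]
    letters: dict[int, str]
    monotone_increase_flag: bool
    shapiro_p: dict[int, float] = field(default_factory=dict)


@dataclass
class RegressionComparison:
    label_a: str
    label_b: str
    slope_a: float
    slope_b: float
    intercept_a: float
    intercept_b: float
    slope_equality_p: float
    common_slope: float | None = None
    intercept_equality_p: float | None = None
    common_intercept: float | None = None


def normality_check(
    groups: dict[int, np.ndarray], cfg: StatsConfig = StatsConfig()
) -> tuple[dict[int, float], str]:
    """Shapiro-Wilk p-value per group; branch is ``anova_tukey`` iff every
    group passes at ``cfg.alpha``, else ``kw_dunn``."""
    pvals: dict[int, float] = {}
    for g, vals in groups.items():
        vals = np.asarray(vals, dtype=np.float64)
        if len(vals) < 3:
            raise ValidationError(f"group {g} has n={len(vals)} < 3; cannot test normality")
        if np.ptp(vals) == 0:
            pvals[g] = 0.0  # constant sample: not normal in any useful sense
        else:
            pvals[g] = float(stats.shapiro(vals).pvalue)
    branch = "anova_tukey" if all(p >= cfg.alpha for p in pvals.values()) else "kw_dunn"
    return pvals, branch


def _dunn_pairwise(groups: list[np.ndarray], alpha_pairs: int) -> np.ndarray:
    """Dunn's z-test on mean ranks with tie correction, Bonferroni-adjusted.

    Returns the symmetric matrix of adjusted p-values.
    """
    k = len(groups)
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    splits = np.cumsum([len(g) for g in groups])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]
    sizes = [len(g) for g in groups]
    P = np.ones((k, k))
    var_base = n * (n + 1) / 12.0 - tie_term
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * alpha_pairs)
        P[i, j] = P[j, i] = p
    return P


def letter_display(
    labels: list[int], pairwise_p: dict[tuple[int, int], float], alpha: float
) -> dict[int, str]:
    """Compact letter display via insert-and-absorb: two groups share a
    letter iff their pairwise p >= alpha."""
    columns: list[set[int]] = [set(labels)]
    for (i, j), p in sorted(pairwise_p.items()):
        if p >= alpha:
            continue
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            columns.extend([col - {i}, col - {j}])
        # absorb: drop empty columns, duplicates, and columns contained in another
        kept: list[set[int]] = []
        for c in columns:
            if c and not any(c < d for d in columns) and c not in kept:
                kept.append(c)
        columns = kept
    # stable ordering: by smallest member then size
    columns.sort(key=lambda c: (min(c), -len(c)))
    letters: dict[int, list[str]] = {g: [] for g in labels}
    for letter, col in zip(string.ascii_lowercase, columns):
        for g in col:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


def compare_groups(
    groups: dict[int, np.ndarray], cfg: StatsConfig = StatsConfig(), measure: str = ""
) -> GroupComparison:
    """Omnibus + pairwise comparison of grade groups with letter display and
    the monotone-increase flag (non-decreasing means AND significant
    lowest-vs-highest difference)."""
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    labels = sorted(groups)
    arrays = [np.asarray(groups[g], dtype=np.float64) for g in labels]
    group_n = {g: len(a) for g, a in zip(labels, arrays)}
    group_mean = {g: float(a.mean()) for g, a in zip(labels, arrays)}
    group_sd = {g: float(a.std(ddof=1)) if len(a) > 1 else 0.0 for g, a in zip(labels, arrays)}

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return GroupComparison(
            measure=measure,
            group_n=group_n,
            group_mean=group_mean,
            group_sd=group_sd,
            branch="degenerate",
            omnibus_p=None,
            pairwise_p={},
            letters={g: "a" for g in labels},
            monotone_increase_flag=False,
        )

    shapiro_p, branch = normality_check(groups, cfg)
    pairwise: dict[tuple[int, int], float] = {}
    if branch == "anova_tukey":
        omnibus_p = float(stats.f_oneway(*arrays).pvalue)
        hsd = stats.tukey_hsd(*arrays)
        for i, j in itertools.combinations(range(len(labels)), 2):
            pairwise[(labels[i], labels[j])] = float(hsd.pvalue[i, j])
    else:
        omnibus_p = float(stats.kruskal(*arrays).pvalue)
        n_pairs = len(labels) * (len(labels) - 1) // 2
        P = _dunn_pairwise(arrays, n_pairs)
        for i, j in itertools.combinations(range(len(labels)), 2):
            pairwise[(labels[i], labels[j])] = float(P[i, j])

    letters = letter_display(labels, pairwise, cfg.alpha)
    means = [group_mean[g] for g in labels]
    extremes_p = pairwise[(labels[0], labels[-1])]
    # "significantly increases with grade": no significant decrease between
    # consecutive grades (a non-significant dip of the sample means does not
    # break the trend), and the lowest vs highest grades differ significantly
    # with the higher grade larger
    no_significant_drop = all(
        m2 >= m1 or pairwise[(g1, g2)] >= cfg.alpha
        for (g1, m1), (g2, m2) in zip(
            zip(labels, means), zip(labels[1:], means[1:])
        )
    )
    monotone = (
        no_significant_drop and extremes_p < cfg.alpha and means[-1] > means[0]
    )
    return GroupComparison(
        measure=measure,
        group_n=group_n,
        group_mean=group_mean,
        group_sd=group_sd,
        branch=branch,
        omnibus_p=omnibus_p,
        pairwise_p=pairwise,
        letters=letters,
        monotone_increase_flag=monotone,
        shapiro_p=shapiro_p,
    )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Least squares with coefficient t-test p-values; returns
    (coefs, pvalues, ssr, dof)."""
    n, k = X.shape
    coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    ssr = float(resid @ resid)
    dof = n - k
    if dof <= 0 or ssr < _PERFECT_FIT_SSR:
        # perfect fit (or saturated): inference degenerates; a coefficient is
        # "significant" iff it is materially non-zero
        pvals = np.where(np.abs(coefs) < _ZERO_COEF, 1.0, 0.0)
        return coefs, pvals, ssr, dof
    sigma2 = ssr / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coefs / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return coefs, pvals, ssr, dof


def compare_slopes(
    series_a: list[tuple[float, float]],
    series_b: list[tuple[float, float]],
    cfg: StatsConfig = StatsConfig(),
    label_a: str = "A",
    label_b: str = "B",
) -> RegressionComparison:
    """Sequential similarity test of two (grade, value) series.

    Per-series OLS of value on grade; slope equality is tested by the
    grade-by-series interaction term of the pooled model. On non-significant
    slope difference the model is refit with a common slope and the
    intercepts are compared; on a further non-significant difference a
    common intercept is reported.
    """
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    for name, s in (("A", a), ("B", b)):
        if s.ndim != 2 or s.shape[0] < 2 or len(np.unique(s[:, 0])) < 2:
            raise ValidationError(f"series {name} must span >= 2 distinct grades")

    def fit_simple(s: np.ndarray) -> tuple[float, float]:
        X = np.column_stack([np.ones(len(s)), s[:, 0]])
        coefs, *_ = np.linalg.lstsq(X, s[:, 1], rcond=None)
        return float(coefs[1]), float(coefs[0])

    slope_a, intercept_a = fit_simple(a)
    slope_b, intercept_b = fit_simple(b)

    x = np.concatenate([a[:, 0], b[:, 0]])
    y = np.concatenate([a[:, 1], b[:, 1]])
    g = np.concatenate([np.zeros(len(a)), np.ones(len(b))])

    X_full = np.column_stack([np.ones_like(x), x, g, x * g])
    _, pvals, _, _ = _ols(X_full, y)
    slope_p = float(pvals[3])

    result = RegressionComparison(
        label_a=label_a,
        label_b=label_b,
        slope_a=slope_a,
        slope_b=slope_b,
        intercept_a=intercept_a,
        intercept_b=intercept_b,
        slope_equality_p=slope_p,
    )
    if slope_p <= cfg.alpha:
        return result

    X_red = np.column_stack([np.ones_like(x), x, g])
    coefs, pvals, _, _ = _ols(X_red, y)
    result.common_slope = float(coefs[1])
    result.intercept_equality_p = float(pvals[2])
    if result.intercept_equality_p > cfg.alpha:
        X_min = np.column_stack([np.ones_like(x), x])
        coefs, _, _, _ = _ols(X_min, y)
        result.common_intercept = float(coefs[0])
    return result
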