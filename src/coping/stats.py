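"""Group-comparison statistics for classified cohorts.

The menu mirrors a standard behavioral-phenotyping analysis: one-way
ANOVA across stress groups (control / passive / active) with Tukey HSD
post hoc comparisons, two-way stress-by-drug ANOVA for endpoints
measured under vehicle/CNO treatment, two-sample t tests, and Pearson
correlation (reported as R² with the sign of r) for the
latency-expression relationship.

One-way ANOVA and the t test are computed from the classical
sums-of-squares formulas with p-values from scipy distributions, so the
degenerate all-constant case yields F = 0, p = 1 rather than nan.  The
two-way ANOVA uses statsmodels OLS with Type III sums of squares under
sum-to-zero factor coding (robust to the unequal cell sizes that the
exclusion rule produces); Tukey comparisons use the Tukey–Kramer
extension for unequal group sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "StatsDataError",
    "EffectResult",
    "PairwiseComparison",
    "StatsReport",
    "one_way_anova",
    "two_way_anova",
    "tukey_hsd",
    "two_sample_t",
    "pearson_r2",
]


class StatsDataError(ValueError):
    """Input data cannot support the requested test."""


@dataclass(frozen=True)
class EffectResult:
    """One tested effect: an F (df = (num, den)) or t (df = (df, None))."""

    name: str
    statistic: float
    df: tuple[float, float | None]
    p_value: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    ci_low: float
    ci_high: float
    p_adj: float | None = None


@dataclass(frozen=True)
class StatsReport:
    """Structured result of one test: effects plus pairwise 95% CIs."""

    test_name: str
    effects: tuple[EffectResult, ...]
    comparisons: tuple[PairwiseComparison, ...] = ()
    extras: Mapping[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per effect and per pairwise comparison (CSV-friendly)."""
        rows = []
        for e in self.effects:
            rows.append(
                {
                    "test": self.test_name,
                    "row_type": "effect",
                    "term": e.name,
                    "statistic": e.statistic,
                    "df1": e.df[0],
                    "df2": e.df[1],
                    "p_value": round(e.p_value, 4),
                    "comparison": "",
                    "mean_diff": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
        for c in self.comparisons:
            rows.append(
                {
                    "test": self.test_name,
                    "row_type": "comparison",
                    "term": "",
                    "statistic": np.nan,
                    "df1": np.nan,
                    "df2": np.nan,
                    "p_value": round(c.p_adj, 4) if c.p_adj is not None else np.nan,
                    "comparison": f"{c.group_a} vs {c.group_b}",
                    "mean_diff": c.mean_diff,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                }
            )
        return pd.DataFrame(rows)


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(out) < 2:
        raise StatsDataError("need at least 2 groups")
    for name, v in out.items():
        if v.size < 2:
            raise StatsDataError(f"group {name!r} has fewer than 2 observations")
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> StatsReport:
    """Classical one-way ANOVA: between/within F with (g-1, N-g) df.

    ``groups`` maps level name to observations. If all observations are
    identical the F statistic is 0 with p = 1.
    """
    g = _as_groups(groups)
    all_vals = np.concatenate(list(g.values()))
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(g)
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in g.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in g.values())
    df1, df2 = k - 1, n_total - k
    if ss_between == 0.0:
        f_stat, p = 0.0, 1.0
    elif ss_within == 0.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(f_stat, df1, df2))
    return StatsReport(
        test_name="one_way_anova",
        effects=(EffectResult("group", float(f_stat), (float(df1), float(df2)), p),),
    )


def two_way_anova(
    data: pd.DataFrame,
    value: str,
    stress: str = "stress",
    drug: str = "drug",
) -> StatsReport:
    """Two-way stress-by-drug ANOVA with Type III sums of squares.

    All stress-by-drug cells must be non-empty. Factors use sum-to-zero
    coding so the Type III decomposition is meaningful for the
    unbalanced designs the exclusion rule produces.
    """
    for col in (value, stress, drug):
        if col not in data.columns:
            raise StatsDataError(f"column {col!r} missing from data")
    counts = data.groupby([stress, drug], observed=True)[value].count()
    for s in data[stress].unique():
        for d in data[drug].unique():
            if counts.get((s, d), 0) == 0:
                raise StatsDataError(f"empty cell: {stress}={s}, {drug}={d}")

    df = data.rename(columns={value: "_y", stress: "_stress", drug: "_drug"})
    with warnings.catch_warnings():
        # zero-residual degenerate designs emit harmless divide warnings
        warnings.simplefilter("ignore")
        fit = ols("_y ~ C(_stress, Sum) * C(_drug, Sum)", data=df).fit()
        table = anova_lm(fit, typ=3)

    # a zero-noise design leaves residual SS at floating-point dust; rebuild
    # the degenerate F values from the sums of squares in that case
    ss = table["sum_sq"]
    ss_resid = float(ss["Residual"])
    tol = 1e-9 * max(float(ss.drop("Intercept", errors="ignore").abs().max()), 1.0)

    def row(term: str) -> EffectResult:
        r = table.loc[term]
        df_den = float(table.loc["Residual", "df"])
        if ss_resid <= tol:
            if float(r["sum_sq"]) <= tol:
                f_stat, p = 0.0, 1.0
            else:
                f_stat, p = np.inf, 0.0
        else:
            f_stat = float(r["F"])
            p = float(r["PR(>F)"])
            if np.isnan(f_stat):
                f_stat, p = 0.0, 1.0
        return EffectResult(term, f_stat, (float(r["df"]), df_den), p)

    effects = (
        row("C(_stress, Sum)"),
        row("C(_drug, Sum)"),
        row("C(_stress, Sum):C(_drug, Sum)"),
    )
    named = tuple(
        EffectResult(n, e.statistic, e.df, e.p_value)
        for n, e in zip((stress, drug, f"{stress}:{drug}"), effects)
    )
    return StatsReport(test_name="two_way_anova", effects=named)


def tukey_hsd(
    values: Sequence[float], labels: Sequence[str], alpha: float = 0.05
) -> StatsReport:
    """All-pairs Tukey HSD comparisons with studentized-range 95% CIs.

    Uses the Tukey–Kramer extension when group sizes are unequal. A CI
    excluding 0 corresponds to adjusted p below ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise StatsDataError("need at least 2 groups")
    if (counts < 2).any():
        raise StatsDataError("every group needs at least 2 observations")
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    groups = [str(g) for g in res.groupsunique]
    pairs = [(groups[i], groups[j]) for i, j in zip(*np.triu_indices(len(groups), 1))]
    comparisons = tuple(
        PairwiseComparison(
            group_a=a,
            group_b=b,
            mean_diff=float(diff),
            ci_low=float(lo),
            ci_high=float(hi),
            p_adj=float(p),
        )
        for (a, b), diff, (lo, hi), p in zip(
            pairs, res.meandiffs, res.confint, res.pvalues
        )
    )
    return StatsReport(test_name="tukey_hsd", effects=(), comparisons=comparisons)


def two_sample_t(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = True,
) -> StatsReport:
    """Two-tailed two-sample t test with a 95% CI on the mean difference.

    ``equal_var=True`` gives the classical pooled-variance test;
    ``False`` gives Welch's unequal-variance test. Two identical
    samples yield t = 0, p = 1 with a zero-width CI.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsDataError("each sample needs at least 2 observations")
    diff = a.mean() - b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if equal_var:
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * va + (b.size - 1) * vb) / df
        se = np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    else:
        se2a, se2b = va / a.size, vb / b.size
        se = np.sqrt(se2a + se2b)
        if se > 0:
            df = (se2a + se2b) ** 2 / (
                se2a**2 / (a.size - 1) + se2b**2 / (b.size - 1)
            )
        else:
            df = a.size + b.size - 2
    if se == 0.0:
        if diff == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = np.sign(diff) * np.inf, 0.0
        ci = (diff, diff)
    else:
        t_stat = diff / se
        p = float(2 * sps.t.sf(abs(t_stat), df))
        half = float(sps.t.ppf(0.975, df)) * se
        ci = (diff - half, diff + half)
    return StatsReport(
        test_name="t_test" if equal_var else "welch_t_test",
        effects=(EffectResult("mean_difference", float(t_stat), (float(df), None), p),),
        comparisons=(
            PairwiseComparison("a", "b", float(diff), float(ci[0]), float(ci[1])),
        ),
    )


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> StatsReport:
    """Squared Pearson correlation with two-tailed p and the sign of r.

    ``extras`` carries ``r`` (signed) and ``r2``. Raises on fewer than
    3 pairs or zero variance in either vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsDataError("x and y must have the same length")
    if x.size < 3:
        raise StatsDataError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsDataError("correlation undefined: zero variance")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return StatsReport(
        test_name="pearson_correlation",
        effects=(
            EffectResult("r", r, (float(x.size - 2), None), float(res.pvalue)),
        ),
        extras={"r": r, "r2": r * r, "n": float(x.size)},
    )
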