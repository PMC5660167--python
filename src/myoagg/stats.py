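"""Group-comparison machinery of the study.

Two-way between-subject ANOVA (Type-II sums of squares, interaction
included) with Bonferroni-corrected post-hoc comparisons, Student's t-test,
iterative two-sided Grubbs outlier screening, Kaplan-Meier estimation with
the Mantel-Cox log-rank test, the RNA-seq gene-retention filter ("count of
2 or more in at least 10 samples"), and geometric-mean qPCR normalization
to three housekeeping genes.

ANOVA model fitting is delegated to statsmodels and survival estimation to
lifelines; this module owns the study-specific conventions (Type-II SS,
degenerate-data handling, per-cell outlier screening, the retention rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "two_way_anova",
    "bonferroni_posthoc",
    "grubbs_test",
    "km_logrank",
    "gene_filter",
    "qpcr_fold_change",
]


def two_way_anova(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "treatment",
) -> pd.DataFrame:
    """Two-way between-subject ANOVA with interaction, Type-II SS.

    Returns one row per effect (``factor_a``, ``factor_b``, interaction)
    with columns ``F``, ``df1``, ``df2`` and ``p``.  Type-II sums of
    squares are the convention for unbalanced factorial designs without an
    interaction focus; in the balanced case they coincide with Type-I and
    the effect and residual SS partition the total exactly.

    Raises if either factor has fewer than two levels, if a factor-level
    cell is empty (named in the error), or if any cell has fewer than two
    observations (no residual degrees of freedom for the full model).
    """
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    counts = data.groupby([factor_a, factor_b], observed=True)[value].count()
    levels_a = data[factor_a].unique()
    levels_b = data[factor_b].unique()
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least two levels")
    for a in levels_a:
        for b in levels_b:
            n = counts.get((a, b), 0)
            if n == 0:
                raise ValueError(f"empty design cell: {factor_a}={a!r}, {factor_b}={b!r}")
            if n < 2:
                raise ValueError(
                    f"cell {factor_a}={a!r}, {factor_b}={b!r} has {n} observation(s); "
                    "need >= 2 per cell"
                )
    df = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    resid_df = float(table.loc["Residual", "df"])
    resid_ss = float(table.loc["Residual", "sum_sq"])
    rows = []
    name_map = {
        "C(_a)": factor_a,
        "C(_b)": factor_b,
        "C(_a):C(_b)": f"{factor_a}:{factor_b}",
    }
    for key, name in name_map.items():
        ss = float(table.loc[key, "sum_sq"])
        df1 = float(table.loc[key, "df"])
        if resid_ss <= 1e-12 * max(1.0, abs(float(df["_y"].abs().max())) ** 2):
            # degenerate data (e.g. all values equal): no variance to test
            F, p = (0.0, 1.0)
        else:
            F = (ss / df1) / (resid_ss / resid_df)
            p = float(sps.f.sf(F, df1, resid_df))
        rows.append({"effect": name, "F": float(F), "df1": df1, "df2": resid_df, "p": p})
    return pd.DataFrame(rows).set_index("effect")


def bonferroni_posthoc(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: ``min(1, m * p)`` for each of m tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return np.minimum(1.0, m * p)


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G_crit for sample size n."""
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_test(values, alpha: float = 0.05) -> list[int]:
    """Iterative two-sided Grubbs outlier screen.

    At each pass the single most extreme value is tested with
    ``G = max|x - mean| / sd`` against the two-sided critical value; if it
    exceeds it, that value is removed and the test repeats on the rest.
    Returns the indices (into the original array) of all flagged outliers,
    in removal order.  Deterministic; requires n >= 3; an all-equal sample
    has no outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1-D")
    if len(x) < 3:
        raise ValueError("Grubbs test requires at least 3 values")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    active = list(range(len(x)))
    flagged: list[int] = []
    while len(active) >= 3:
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        i_max = int(np.argmax(dev))
        G = dev[i_max] / sd
        if G > grubbs_critical(len(sub), alpha):
            flagged.append(active.pop(i_max))
        else:
            break
    return flagged


@dataclass
class LogrankResult:
    chi_square: float
    p: float
    curves: dict[str, pd.DataFrame]  # group -> columns time, survival


def km_logrank(
    data: pd.DataFrame,
    time: str = "time",
    event: str = "event",
    group: str = "group",
) -> LogrankResult:
    """Kaplan-Meier curves and the Mantel-Cox log-rank test for two groups.

    The log-rank statistic uses the hypergeometric variance of the pooled
    event-time table without continuity correction (the Mantel-Cox
    convention).  KM curves are right-continuous step functions starting at
    1.  Raises with fewer or more than two groups or if no events occurred.
    """
    groups = list(pd.unique(data[group]))
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {groups}")
    if (data[time] < 0).any():
        raise ValueError("negative survival times")
    if int(data[event].sum()) == 0:
        raise ValueError("no events in either group; log-rank undefined")
    sub = {g: data[data[group] == g] for g in groups}
    res = logrank_test(
        sub[groups[0]][time],
        sub[groups[1]][time],
        event_observed_A=sub[groups[0]][event],
        event_observed_B=sub[groups[1]][event],
    )
    curves = {}
    for g in groups:
        kmf = KaplanMeierFitter()
        kmf.fit(sub[g][time], sub[g][event])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return LogrankResult(
        chi_square=float(res.test_statistic), p=float(res.p_value), curves=curves
    )


def gene_filter(
    counts: pd.DataFrame, min_count: int = 2, min_samples: int = 10
) -> pd.Index:
    """RNA-seq gene-retention filter.

    A gene (row) is retained iff its count is at least ``min_count`` in at
    least ``min_samples`` samples (columns).  Order-preserving and
    idempotent; the retained count is monotone non-increasing in both
    parameters.
    """
    if min_count < 0 or min_samples < 0:
        raise ValueError("filter parameters must be non-negative")
    keep = (counts >= min_count).sum(axis=1) >= min_samples
    return counts.index[keep]


def qpcr_fold_change(
    target: pd.Series,
    housekeeping: pd.DataFrame,
    groups: pd.Series,
    reference: str,
) -> pd.Series:
    """Fold change of a qPCR target vs a reference group.

    Each sample's target copy number is normalized to the geometric mean of
    its three housekeeping-gene copy numbers; the fold change of a group is
    its mean normalized value over the reference group's.  All copy numbers
    must be positive.
    """
    if housekeeping.shape[1] != 3:
        raise ValueError("expected exactly 3 housekeeping genes")
    if (target <= 0).any() or (housekeeping <= 0).to_numpy().any():
        raise ValueError("copy numbers must be positive")
    if reference not in set(groups):
        raise ValueError(f"reference group {reference!r} not present")
    norm = target / sps.gmean(housekeeping, axis=1)
    group_means = norm.groupby(groups.to_numpy()).mean()
    return group_means / group_means[reference]
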