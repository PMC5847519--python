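"""Group-level statistics for quantified sodium metrics.

Two factorial analyses per metric — tissue type (GM vs WM) and sub-cortical
region (8 levels), each with sex and age as nuisance terms — followed by
nonparametric Steel-Dwass all-pairs comparisons within the significant
factor, and an explicit Bonferroni correction across the six dependent
metrics (alpha = 0.05/6).

The Steel-Dwass statistic for a pair of groups is the Mann-Whitney rank sum
computed on the two groups' joint mid-ranks, standardized with the
tie-corrected variance and a 0.5 continuity correction, and referred to the
studentized-range distribution with k = number of groups (comparing
sqrt(2)*|z|), which builds the all-pairs multiplicity adjustment into each
p-value. For two fully separated samples of 13 the statistic saturates at
|z| = (260 - 175.5 - 0.5)/sqrt(13*13*27/12) = 4.31.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, studentized_range
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "METRICS",
    "AnovaResult",
    "PosthocResult",
    "run_anova",
    "pairwise_rank_z",
    "steel_dwass",
    "steel_dwass_zmatrix",
    "steel_dwass_critical_z",
    "bonferroni_alpha",
    "BonferroniAlpha",
    "metrics_long_table",
]

#: The six dependent variables analysed per ROI grouping.
METRICS: tuple[str, ...] = ("t2s", "t2l", "na_sf", "na_lf", "tsc", "ecf")

_METRIC_COLUMNS = {
    "t2s": "t2s_ms",
    "t2l": "t2l_ms",
    "na_sf": "na_sf_mM",
    "na_lf": "na_lf_mM",
    "tsc": "tsc_mM",
    "ecf": "ecf",
}


@dataclass(frozen=True)
class AnovaResult:
    """Whole-model and per-factor F tests for one metric."""

    metric_name: str
    f_whole_model: float
    p_whole_model: float
    df_whole_model: int
    f_per_factor: dict[str, float]
    df_per_factor: dict[str, int]
    p_values: dict[str, float]

    def to_row(self) -> dict:
        row = {
            "metric": self.metric_name,
            "f_whole_model": self.f_whole_model,
            "df_whole_model": self.df_whole_model,
            "p_whole_model": self.p_whole_model,
        }
        for factor in self.f_per_factor:
            row[f"f_{factor}"] = self.f_per_factor[factor]
            row[f"df_{factor}"] = self.df_per_factor[factor]
            row[f"p_{factor}"] = self.p_values[factor]
        return row


@dataclass(frozen=True)
class PosthocResult:
    """All-pairs Steel-Dwass comparisons for one metric."""

    metric_name: str
    pairs: tuple[tuple[str, str, float, float], ...]  # (a, b, z, p_adjusted)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.pairs), columns=["group_a", "group_b", "z", "p_adjusted"]
        ).assign(metric=self.metric_name)


def metrics_long_table(
    quant_frame: pd.DataFrame, subjects: pd.DataFrame
) -> pd.DataFrame:
    """Reshape the per-subject quantification table to long metric form.

    Returns rows (subject_id, sex, age, group_label, metric_name, value)
    with one row per subject x ROI x metric.
    """
    df = quant_frame.merge(subjects, on="subject_id", validate="many_to_one")
    long = df.melt(
        id_vars=["subject_id", "sex", "age", "roi"],
        value_vars=list(_METRIC_COLUMNS.values()),
        var_name="column",
        value_name="value",
    )
    colmap = {v: k for k, v in _METRIC_COLUMNS.items()}
    long["metric_name"] = long["column"].map(colmap)
    return long.rename(columns={"roi": "group_label"})[
        ["subject_id", "sex", "age", "group_label", "metric_name", "value"]
    ]


def run_anova(
    table: pd.DataFrame, metric: str, group_factor: str = "group_label"
) -> AnovaResult:
    """Fixed-effects ANOVA of one metric on (group, sex, age).

    Type II sums of squares, no interactions; age enters as a continuous
    covariate. ``table`` is the long form from :func:`metrics_long_table`.
    """
    sub = table[table["metric_name"] == metric].copy()
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    counts = sub.groupby(["subject_id", group_factor]).size()
    if (counts != 1).any():
        raise ValueError("expected exactly one value per subject x group")
    sub = sub.rename(columns={group_factor: "group"})
    if sub["group"].nunique() < 2:
        raise ValueError("group factor needs at least two levels")
    # constant nuisance factors (e.g. a single-sex cohort) carry no df
    terms = ["C(group)"]
    names = {"C(group)": "group"}
    if sub["sex"].nunique() > 1:
        terms.append("C(sex)")
        names["C(sex)"] = "sex"
    if sub["age"].nunique() > 1:
        terms.append("age")
        names["age"] = "age"
    model = smf.ols("value ~ " + " + ".join(terms), data=sub).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design")
    table2 = sm.stats.anova_lm(model, typ=2)
    f_per, df_per, p_per = {}, {}, {}
    for src, label in names.items():
        f_per[label] = float(table2.loc[src, "F"])
        df_per[label] = int(table2.loc[src, "df"])
        p_per[label] = float(table2.loc[src, "PR(>F)"])
    return AnovaResult(
        metric_name=metric,
        f_whole_model=float(model.fvalue),
        p_whole_model=float(model.f_pvalue),
        df_whole_model=int(model.df_model),
        f_per_factor=f_per,
        df_per_factor=df_per,
        p_values=p_per,
    )


def pairwise_rank_z(a, b) -> float:
    """Standardized Mann-Whitney rank statistic for one pair of groups.

    Joint mid-ranks over the two samples; z > 0 when ``b`` tends to exceed
    ``a``. Variance uses the general tie-corrected form
    ``n_a n_b / (N(N-1)) * sum (r_k - (N+1)/2)^2`` (equal to
    ``n_a n_b (N+1)/12`` without ties); a 0.5 continuity correction shrinks
    the deviation toward zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    n = na + nb
    ranks = rankdata(np.concatenate([a, b]))
    w_b = float(ranks[na:].sum())
    expect = nb * (n + 1) / 2.0
    var = na * nb / (n * (n - 1.0)) * float(np.sum((ranks - (n + 1) / 2.0) ** 2))
    if var == 0.0:
        return 0.0
    d = w_b - expect
    d = np.sign(d) * max(abs(d) - 0.5, 0.0)
    return float(d / np.sqrt(var))


def steel_dwass_critical_z(k: int, alpha: float = 0.05) -> float:
    """|z| threshold for familywise significance at level ``alpha``."""
    return float(studentized_range.ppf(1.0 - alpha, k, np.inf) / np.sqrt(2.0))


def steel_dwass_zmatrix(groups: list[np.ndarray]) -> np.ndarray:
    """Antisymmetric matrix of pairwise standardized rank statistics."""
    k = len(groups)
    z = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            z[i, j] = pairwise_rank_z(groups[i], groups[j])
            z[j, i] = -z[i, j]
    return z


def steel_dwass(
    groups, labels=None, metric_name: str = ""
) -> PosthocResult:
    """Steel-Dwass all-pairs comparison.

    Each pair's p-value refers sqrt(2)*|z| to the studentized-range
    distribution with k groups (infinite df), so the p is already adjusted
    for all k(k-1)/2 comparisons. Requires >= 2 groups of >= 3 observations.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 3 for g in groups):
        raise ValueError("every group needs at least 3 observations")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels must match number of groups")
    z = steel_dwass_zmatrix(groups)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            p = float(studentized_range.sf(np.sqrt(2.0) * abs(z[i, j]), k, np.inf))
            pairs.append((labels[i], labels[j], float(z[i, j]), min(p, 1.0)))
    return PosthocResult(metric_name=metric_name, pairs=tuple(pairs))


@dataclass(frozen=True)
class BonferroniAlpha:
    """Corrected per-test alpha, exact and at the conventional 3-decimal print."""

    exact: float
    rounded: float
    n_tests: int
    family_alpha: float


def bonferroni_alpha(n_tests: int, family_alpha: float = 0.05) -> BonferroniAlpha:
    """Per-test alpha controlling the family of ``n_tests`` comparisons."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must lie in (0, 1)")
    exact = family_alpha / n_tests
    return BonferroniAlpha(
        exact=exact,
        rounded=round(exact, 3),
        n_tests=n_tests,
        family_alpha=family_alpha,
    )
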