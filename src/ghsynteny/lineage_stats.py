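"""Cohort-level statistics across genomes.

Relates the GH-gene repertoire to genome size (Pearson correlation and
ordinary-least-squares slope of GH count on PEG count) and partitions the
variance of GH-gene clustering between genome size, GH-gene count, and
their interaction, using sequential (type-I) sums of squares in that fixed
order so the term percentages and the residual sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "COHORT_COLUMNS",
    "RegressionSummary",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
    "correlation_and_slope",
    "variance_partition",
    "group_summary",
]

#: Canonical per-genome columns of a cohort table.  ``f_gh`` is a percentage
#: (100 * n_gh / n_pegs); the remaining fractions live in [0, 1].
COHORT_COLUMNS = [
    "genome_id",
    "n_pegs",
    "n_gh",
    "f_gh",
    "n_clustered",
    "f_clustered",
    "f_codir_all",
    "f_codir_clustered",
    "colocalized_fraction",
    "n_tr_mfs",
    "n_tr_abc",
    "n_tr_pts",
    "n_tr_sus",
    "phylum",
    "genus",
    "environment",
]


@dataclass(frozen=True)
class RegressionSummary:
    """Correlation/slope results and/or a sequential variance decomposition."""

    n: int
    pearson_r: Optional[float] = None
    pearson_p: Optional[float] = None
    slope: Optional[float] = None
    slope_p: Optional[float] = None
    intercept: Optional[float] = None
    variance_percent: dict[str, float] = field(default_factory=dict)
    term_p: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False


def validate_cohort(cohort: pd.DataFrame, required: Sequence[str] = ("genome_id", "n_pegs", "n_gh")) -> None:
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    if cohort["genome_id"].duplicated().any():
        dupes = cohort.loc[cohort["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValueError(f"duplicate genome_id(s): {dupes[:3]}")


def read_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t", na_values=["NA"])
    validate_cohort(cohort)
    return cohort


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def correlation_and_slope(
    cohort: pd.DataFrame, x: str = "n_pegs", y: str = "n_gh"
) -> RegressionSummary:
    """Pearson r and OLS slope of y on x across genomes.

    A response with zero variance yields a degenerate-flagged zero rather
    than an error, so one uniform genus does not abort a cohort run.
    """
    validate_cohort(cohort, required=("genome_id", x, y))
    xv = cohort[x].to_numpy(dtype=float)
    yv = cohort[y].to_numpy(dtype=float)
    n = len(xv)
    if n < 3:
        raise ValueError(f"need >= 3 genomes, got {n}")
    if np.ptp(xv) == 0:
        raise ValueError(f"predictor {x!r} has zero variance")
    if np.ptp(yv) == 0:
        return RegressionSummary(
            n=n, pearson_r=0.0, pearson_p=1.0, slope=0.0, slope_p=1.0,
            intercept=float(yv[0]), degenerate=True,
        )
    r, r_p = stats.pearsonr(xv, yv)
    fit = stats.linregress(xv, yv)
    return RegressionSummary(
        n=n,
        pearson_r=float(r),
        pearson_p=float(r_p),
        slope=float(fit.slope),
        slope_p=float(fit.pvalue),
        intercept=float(fit.intercept),
    )


def variance_partition(
    cohort: pd.DataFrame,
    response: str = "n_clustered",
    predictors: Sequence[str] = ("n_pegs", "n_gh"),
    interaction: bool = True,
) -> RegressionSummary:
    """Sequential (type-I) variance decomposition of GH-gene clustering.

    Fits ``response ~ p1 + p2 [+ p1:p2]`` with predictors entered in the
    given order and reports each term's percentage of the total sum of
    squares plus the residual; the percentages sum to 100.  The response may
    be the clustered-gene count (default) or a frequency column.
    """
    validate_cohort(cohort, required=("genome_id", response, *predictors))
    if len(predictors) != 2:
        raise ValueError("exactly two predictors expected")
    n = len(cohort)
    if n < 5:
        raise ValueError(f"need >= 5 genomes, got {n}")
    p1, p2 = predictors
    data = cohort[[response, p1, p2]].astype(float)
    design = [data[p1], data[p2]]
    if interaction:
        design.append(data[p1] * data[p2])
    X = np.column_stack([np.ones(n)] + design)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"collinear predictors among ({p1}, {p2}, {p1}:{p2})")
    formula = f"Q('{response}') ~ Q('{p1}') + Q('{p2}')"
    if interaction:
        formula += f" + Q('{p1}'):Q('{p2}')"
    fit = smf.ols(formula, data=data).fit()
    table = anova_lm(fit, typ=1)
    total_ss = float(table["sum_sq"].sum())
    labels = [p1, p2] + (["interaction"] if interaction else []) + ["residual"]
    variance_percent: dict[str, float] = {}
    term_p: dict[str, float] = {}
    if total_ss == 0:
        raise ValueError(f"response {response!r} has zero variance")
    for label, (idx, row) in zip(labels, table.iterrows()):
        variance_percent[label] = 100.0 * float(row["sum_sq"]) / total_ss
        if np.isfinite(row["PR(>F)"]):
            term_p[label] = float(row["PR(>F)"])
    return RegressionSummary(n=n, variance_percent=variance_percent, term_p=term_p)


def group_summary(
    cohort: pd.DataFrame,
    by: str = "genus",
    metrics: Sequence[str] = (
        "f_gh",
        "f_clustered",
        "f_codir_clustered",
        "colocalized_fraction",
    ),
) -> pd.DataFrame:
    """Per-group n, mean and sd of the per-genome metrics (sd is NA for n = 1)."""
    if by not in cohort.columns:
        raise ValueError(f"unknown grouping column {by!r}")
    present = [m for m in metrics if m in cohort.columns]
    rows = []
    for group, sub in cohort.groupby(by, sort=True, dropna=False):
        row: dict = {by: group, "n": len(sub)}
        for metric in present:
            values = sub[metric].dropna().to_numpy(dtype=float)
            row[f"{metric}_mean"] = values.mean() if values.size else np.nan
            row[f"{metric}_sd"] = values.std(ddof=1) if values.size > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
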