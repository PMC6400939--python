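"""Cohort-level statistics linking fluorescence to pathology.

Mirrors the study-style questions: does mean biopsy fluorescence track tumor
cellularity (it should not), receptor subtype (Her2+ > TNBC > ER+), and
lymphocyte infiltration (inverse)?  Two-group contrasts use a two-sided
t-test (Welch by default), multi-group contrasts a one-way ANOVA with
Tukey-Kramer post-hoc pairwise comparisons (valid for unequal group sizes),
and associations Pearson's linear correlation.  Significance is declared at
alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .synthetic import SiteAnnotation, til_density

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Per-biopsy mean fluorescence values for one labelled group."""

    group_label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.size < 1:
            raise ValueError("group must contain at least one value")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def correlate(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson r with a two-sided p from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=x.size)


def two_sample_t(
    x: np.ndarray, y: np.ndarray, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        raise ValueError("both samples degenerate with different means")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    groups: list[GroupSummary], alpha: float = ALPHA
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus a Tukey-Kramer pairwise table.

    Returns (F, p, table); the table has one row per group pair with the
    mean difference, adjusted p-value and a reject flag at ``alpha``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.group_label!r} has n < 2")
    f_stat, p = sps.f_oneway(*[g.values for g in groups])
    values = np.concatenate([g.values for g in groups])
    labels = np.concatenate([[g.group_label] * g.n for g in groups])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return float(f_stat), float(p), table


def biopsy_til_density(annotations: list[SiteAnnotation]) -> float:
    """Biopsy-level TIL density: mean of site densities over annotated sites."""
    densities = [til_density(a) for a in annotations if a.stromal_percent > 0]
    if not densities:
        raise ValueError("no sites with nonzero stromal percent")
    return float(np.mean(densities))


def fig3_analysis(
    features_df: pd.DataFrame, annotations_df: pd.DataFrame
) -> dict:
    """Cohort analysis of fluorescence vs. pathology.

    Inputs: a per-biopsy features table (biopsy_id, tissue_class, subtype,
    mean_all, ...) and a per-site annotation table (biopsy_id, cellularity,
    stromal_pct, til_pct).  Computes

    a. correlation of tumor-biopsy mean fluorescence with mean tumor
       cellularity;
    b. group comparison of mean fluorescence across ER+/Her2+/TNBC/benign/
       mammoplasty (ANOVA + Tukey-Kramer where >= 2 groups have n >= 2);
    c. correlation with TIL density, over all tumors and within the pooled
       Her2+/TNBC subset (the aggressive subtypes where TILs are prognostic).
    """
    tumors = features_df[features_df["tissue_class"] == "tumor"]
    if tumors.empty:
        raise ValueError("no tumor biopsies in features table")
    missing = set(tumors["biopsy_id"]) - set(annotations_df["biopsy_id"])
    if missing:
        raise ValueError(f"missing annotations for biopsies: {sorted(missing)}")

    per_biopsy = (
        annotations_df.assign(
            til_density=lambda d: d["til_pct"] / d["stromal_pct"]
        )
        .groupby("biopsy_id")
        .agg(cellularity=("cellularity", "mean"), til_density=("til_density", "mean"))
        .reset_index()
    )
    tm = tumors.merge(per_biopsy, on="biopsy_id")

    report: dict = {}
    report["cellularity_corr"] = correlate(
        tm["mean_all"].to_numpy(), tm["cellularity"].to_numpy()
    )

    group_labels = features_df.apply(
        lambda r: r["subtype"] if r["tissue_class"] == "tumor" else r["tissue_class"],
        axis=1,
    )
    groups = [
        GroupSummary(lbl, features_df.loc[group_labels == lbl, "mean_all"].to_numpy())
        for lbl in group_labels.unique()
        if (group_labels == lbl).sum() >= 2
    ]
    if len(groups) >= 2:
        f_stat, p, tukey = compare_groups(groups)
        report["group_comparison"] = {"F": f_stat, "p": p, "tukey": tukey}
        report["group_means"] = {g.group_label: float(g.values.mean()) for g in groups}

    report["til_corr_all_tumors"] = correlate(
        tm["mean_all"].to_numpy(), tm["til_density"].to_numpy()
    )
    aggressive = tm[tm["subtype"].isin(["Her2+", "TNBC"])]
    if len(aggressive) >= 3:
        report["til_corr_her2_tnbc"] = correlate(
            aggressive["mean_all"].to_numpy(), aggressive["til_density"].to_numpy()
        )
    return report
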