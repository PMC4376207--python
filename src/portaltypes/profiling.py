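"""Cluster summaries: per-type usage means, demographic profiles, flags.

Clusters are described mechanically: per-cluster arithmetic means of every
usage variable (a function-count mean is the cluster's total clicks on that
function divided by the cluster size), with highest/lowest flags across
clusters and no narrative naming.  Percentages are reported at 2 dp and
means at 1 dp in the rounded views; machine-readable output keeps full
precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSummary",
    "DemographicSummary",
    "cluster_summary",
    "demographic_summary",
    "describe_types",
    "proportion_table",
    "round_ratio",
]


def proportion_table(sizes: "pd.Series | dict[int, int]", dp: int = 2) -> pd.DataFrame:
    """Counts and percent shares of a partition, percents rounded to ``dp``.

    The raw percents sum to exactly 100; the rounded column is the reported
    view (half-up at ``dp`` decimals, as printed tables round).
    """
    s = pd.Series(sizes).astype(int)
    total = int(s.sum())
    if total <= 0:
        raise ValueError("sizes must sum to a positive total")
    pct = 100.0 * s / total
    rounded = np.floor(pct * 10**dp + 0.5) / 10**dp
    return pd.DataFrame({"n": s, "percent": pct, "percent_rounded": rounded})


def round_ratio(numerator: float, denominator: float, dp: int = 1) -> float:
    """A reported ratio (e.g. administrative:care), half-up rounded."""
    if denominator == 0:
        raise ValueError("denominator is zero")
    value = numerator / denominator
    return float(np.floor(value * 10**dp + 0.5) / 10**dp)


@dataclass
class ClusterSummary:
    sizes: pd.Series  # cluster -> n
    percents: pd.Series  # cluster -> percent of clustered cohort (full precision)
    means: pd.DataFrame  # clusters x variables
    is_max: pd.DataFrame  # clusters x variables, bool
    is_min: pd.DataFrame
    ties: list[tuple[str, str]]  # (variable, "max"|"min") with tied clusters

    def rounded_means(self, dp: int = 1) -> pd.DataFrame:
        return self.means.round(dp)


def cluster_summary(labels: pd.Series, matrix: pd.DataFrame) -> ClusterSummary:
    """Per-cluster means of every usage variable with max/min flags.

    ``labels`` maps patient_id -> cluster; every labelled patient must have
    a row in ``matrix``.  Ties flag all tied clusters and are listed in
    ``ties``.
    """
    missing = labels.index.difference(matrix.index)
    if len(missing):
        raise ValueError(f"labels without profiles: {sorted(missing)[:5]}")
    sub = matrix.loc[labels.index]
    grouped = sub.groupby(labels)
    means = grouped.mean()
    sizes = grouped.size()
    sizes.name = "n"
    percents = 100.0 * sizes / sizes.sum()
    col_max = means.max(axis=0)
    col_min = means.min(axis=0)
    is_max = means.eq(col_max, axis=1)
    is_min = means.eq(col_min, axis=1)
    ties = [
        (var, kind)
        for frame, kind in ((is_max, "max"), (is_min, "min"))
        for var in frame.columns
        if frame[var].sum() > 1
    ]
    return ClusterSummary(sizes, percents, means, is_max, is_min, ties)


@dataclass
class DemographicSummary:
    table: pd.DataFrame  # clusters x demographic summary columns
    n_missing: int  # labelled patients lacking demographics


def demographic_summary(labels: pd.Series, demographics: pd.DataFrame) -> DemographicSummary:
    """Per-cluster demographic profile (age, sex, BMI, chronic conditions).

    Patients without a demographics row are counted and excluded from the
    affected means with a warning; they never error.
    """
    demo = demographics.set_index("patient_id") if "patient_id" in demographics else demographics
    have = labels.index.intersection(demo.index)
    n_missing = len(labels) - len(have)
    if n_missing:
        logger.warning("%d labelled patients lack demographics; excluded from means", n_missing)
    rows = []
    for cluster in sorted(labels.unique()):
        ids = labels.index[labels == cluster].intersection(have)
        size = int((labels == cluster).sum())
        sub = demo.loc[ids]
        row: dict[str, float] = {"cluster": cluster, "n": size, "n_with_demographics": len(ids)}
        if len(ids):
            row["mean_age"] = float(sub["age_years"].mean())
            row["percent_female"] = 100.0 * float((sub["sex"] == "F").mean())
            row["mean_bmi"] = float(sub["bmi"].mean())
            for cond in ("diabetes", "cardiovascular", "heart_failure"):
                n_cond = int(sub[cond].sum())
                row[f"{cond}_n"] = n_cond
                row[f"{cond}_percent"] = 100.0 * n_cond / len(ids)
        else:
            for col in ("mean_age", "percent_female", "mean_bmi"):
                row[col] = np.nan
            for cond in ("diabetes", "cardiovascular", "heart_failure"):
                row[f"{cond}_n"] = 0
                row[f"{cond}_percent"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("cluster")
    return DemographicSummary(table=table, n_missing=n_missing)


def describe_types(summary: ClusterSummary) -> dict[int, dict[str, list[str]]]:
    """Mechanical per-cluster descriptors: variables on which the cluster
    holds the highest / lowest mean.  No narrative labels."""
    out: dict[int, dict[str, list[str]]] = {}
    for cluster in summary.means.index:
        out[int(cluster)] = {
            "max": [v for v in summary.means.columns if summary.is_max.loc[cluster, v]],
            "min": [v for v in summary.means.columns if summary.is_min.loc[cluster, v]],
        }
    return out
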