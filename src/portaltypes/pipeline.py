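"""Chained typology run: outlier filter -> factors -> Ward -> k -> labels."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from portaltypes.typology import (
    ClusterTree,
    FactorModel,
    KSelection,
    OutlierReport,
    cut_clusters,
    filter_outliers,
    fit_factors,
    select_k,
    ward_cluster,
)

__all__ = ["TypologyRun", "run_typology"]


@dataclass
class TypologyRun:
    outliers: OutlierReport
    factors: FactorModel
    tree: ClusterTree
    selection: KSelection
    labels: pd.Series  # patient_id -> cluster, size-ordered numbering

    @property
    def chosen_k(self) -> int:
        return self.selection.chosen_k


def run_typology(
    matrix: pd.DataFrame,
    n_factors: int = 10,
    k_range: range | list[int] = range(2, 16),
    outlier_percentile: float = 99.0,
    k: int | None = None,
    standardize: bool = True,
) -> TypologyRun:
    """Run the full analytic chain on a cohort feature matrix.

    Constant columns (possible in small subsamples) are dropped before the
    factor analysis rather than erroring, since they carry no information
    for the reduction.  ``k`` overrides the automatic CCC / pseudo-t²
    choice when given.
    """
    report = filter_outliers(matrix, percentile=outlier_percentile)
    retained = report.retained_matrix
    sd = retained.std(axis=0, ddof=1)
    usable = retained.loc[:, sd > 0]
    nf = min(n_factors, usable.shape[1])
    factors = fit_factors(usable, n_factors=nf, standardize=standardize)
    tree = ward_cluster(factors.scores)
    selection = select_k(tree, factors.scores, k_range)
    labels = cut_clusters(tree, k if k is not None else selection.chosen_k)
    return TypologyRun(report, factors, tree, selection, labels)
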