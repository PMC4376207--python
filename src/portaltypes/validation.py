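"""Stability checks: subsample re-analysis and k-means replication.

Two complementary checks of whether the hierarchical typology reflects real
structure rather than sampling noise:

* rerun the whole analytic chain on random subsamples and compare the
  resulting labels, restricted to the shared patients, with the full-cohort
  labels (adjusted Rand index);
* re-cluster the same factor scores with k-means at the chosen k, which
  should broadly replicate the hierarchical partition if the structure is
  real.

All reports are deterministic under a fixed seed and serialise to stable
JSON so reruns are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from portaltypes.pipeline import run_typology

__all__ = [
    "StabilityReport",
    "ReplicationReport",
    "adjusted_rand",
    "subsample_stability",
    "kmeans_replicate",
]


def adjusted_rand(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Permutation-adjusted Rand index between two labelings of the same
    patients (1 identical, ~0 chance level).  Mismatched id sets error."""
    if set(labels_a.index) != set(labels_b.index):
        raise ValueError("labelings cover different patient sets")
    b = labels_b.loc[labels_a.index]
    return float(adjusted_rand_score(labels_a.to_numpy(), b.to_numpy()))


@dataclass
class StabilityReport:
    per_subsample: list[dict] = field(default_factory=list)  # {index, n, chosen_k, ari}
    modal_k: int = 0
    mean_ari: float = 0.0
    min_ari: float = 0.0

    def to_json(self) -> str:
        payload = {
            "per_subsample": self.per_subsample,
            "modal_k": self.modal_k,
            "mean_ari": round(self.mean_ari, 10),
            "min_ari": round(self.min_ari, 10),
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def subsample_stability(
    matrix: pd.DataFrame,
    n_subsamples: int = 10,
    fraction: float = 0.5,
    seed: int = 0,
    n_factors: int = 10,
    k_range: range | list[int] = range(2, 16),
    outlier_percentile: float = 99.0,
) -> StabilityReport:
    """Re-run filter -> factors -> Ward -> select_k -> cut on random
    subsamples (without replacement) and compare to the full-cohort labels
    on the shared retained patients."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_take = int(round(fraction * len(matrix)))
    if n_take <= matrix.shape[1]:
        raise ValueError(
            f"subsample of {n_take} is not larger than the variable count "
            f"({matrix.shape[1]})"
        )
    full = run_typology(
        matrix, n_factors=n_factors, k_range=k_range, outlier_percentile=outlier_percentile
    )
    rng = np.random.default_rng(seed)
    rows = []
    aris = []
    for i in range(n_subsamples):
        take = rng.choice(len(matrix), size=n_take, replace=False)
        sub = matrix.iloc[np.sort(take)]
        run = run_typology(
            sub, n_factors=n_factors, k_range=k_range, outlier_percentile=outlier_percentile
        )
        shared = run.labels.index.intersection(full.labels.index)
        ari = adjusted_rand(run.labels.loc[shared], full.labels.loc[shared])
        aris.append(ari)
        rows.append(
            {"index": i, "n": int(len(sub)), "chosen_k": int(run.chosen_k),
             "ari": round(float(ari), 10)}
        )
    ks = pd.Series([r["chosen_k"] for r in rows])
    modal_k = int(ks.mode().iloc[0])
    return StabilityReport(
        per_subsample=rows,
        modal_k=modal_k,
        mean_ari=float(np.mean(aris)),
        min_ari=float(np.min(aris)),
    )


@dataclass
class ReplicationReport:
    kmeans_labels: pd.Series
    ari: float
    confusion: pd.DataFrame  # hierarchical clusters x best-matched k-means clusters
    inertia: float

    def to_json(self) -> str:
        payload = {
            "ari": round(float(self.ari), 10),
            "inertia": round(float(self.inertia), 6),
            "confusion": {
                str(r): {str(c): int(v) for c, v in row.items()}
                for r, row in self.confusion.to_dict(orient="index").items()
            },
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def kmeans_replicate(
    scores: pd.DataFrame,
    hier_labels: pd.Series,
    k: int,
    n_starts: int = 50,
    seed: int = 0,
) -> ReplicationReport:
    """k-means on the same factor scores (best of ``n_starts`` by within-
    cluster sum of squares), compared to the hierarchical labels by ARI and
    a best-match confusion matrix (columns permuted by linear assignment so
    matched clusters sit on the diagonal)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(scores):
        raise ValueError("k exceeds the number of patients")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    raw = km.fit_predict(scores.to_numpy(dtype=float))
    km_labels = pd.Series(raw + 1, index=scores.index, name="kmeans_cluster")
    hier = hier_labels.loc[scores.index]
    ari = adjusted_rand(hier, km_labels)
    confusion = pd.crosstab(hier, km_labels)
    # best matching of k-means clusters onto hierarchical clusters
    cost = -confusion.reindex(
        index=sorted(hier.unique()), columns=sorted(km_labels.unique()), fill_value=0
    ).to_numpy()
    rows_idx, cols_idx = linear_sum_assignment(cost)
    col_order = [confusion.columns[j] for j in cols_idx if j < len(confusion.columns)]
    remaining = [c for c in confusion.columns if c not in col_order]
    confusion = confusion[col_order + remaining]
    return ReplicationReport(
        kmeans_labels=km_labels,
        ari=ari,
        confusion=confusion,
        inertia=float(km.inertia_),
    )
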