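"""Patient clustering: gap-statistic model selection and k-means.

Participants are clustered on the differential genes only, with each
gene z-scored so that high-variance transcripts do not dominate the
Euclidean metric.  The number of clusters is chosen with the gap
statistic: the within-cluster dispersion of the data is compared to
that of reference datasets drawn uniformly over each feature's
observed range, and the smallest k satisfying the one-standard-error
rule Gap(k) >= Gap(k+1) - se(k+1) is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .io import ExpressionMatrix


@dataclass
class ClusterAssignment:
    labels: dict[str, int]  # sample -> 1..k
    k: int
    inertia: float
    gap_curve: pd.DataFrame | None = None  # columns k, gap, se, log_wk
    seed: int | None = None

    def __post_init__(self) -> None:
        vals = set(self.labels.values())
        if not vals <= set(range(1, self.k + 1)):
            raise ValueError(f"labels {sorted(vals)} outside 1..{self.k}")
        if self.inertia < 0:
            raise ValueError("inertia must be >= 0")

    def labels_array(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = sample_ids if sample_ids is not None else list(self.labels)
        return np.array([self.labels[s] for s in ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": [self.labels[s] for s in self.labels]},
            index=pd.Index(list(self.labels), name="sample_id"),
        )


def _zscore_features(x: np.ndarray) -> np.ndarray:
    """Z-score columns (features); constant features become zero."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def _sample_matrix(expr: ExpressionMatrix, zscore: bool = True) -> np.ndarray:
    """Samples as observations, genes as (optionally z-scored) features."""
    x = expr.values.T
    return _zscore_features(x) if zscore else x


def _dispersion(x: np.ndarray, k: int, seed: int, n_starts: int, max_iter: int = 300) -> float:
    """Total within-cluster sum of squares W_k from the best k-means run."""
    if k == 1:
        return float(((x - x.mean(axis=0)) ** 2).sum())
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_starts,
        max_iter=max_iter,
        tol=1e-6,
        random_state=seed % (2**32),
    ).fit(x)
    return float(km.inertia_)


def select_k_gap(
    expr: ExpressionMatrix,
    k_range: Sequence[int] = range(1, 9),
    n_refs: int = 50,
    seed: int = 0,
    n_starts: int = 10,
    zscore: bool = True,
) -> tuple[int, pd.DataFrame]:
    """Gap-statistic selection of the number of clusters.

    Gap(k) = E*[log W_k] - log W_k, where the expectation is over
    ``n_refs`` reference datasets drawn uniformly over each feature's
    observed range.  Returns (k*, gap curve) with k* the smallest k
    whose gap is within one standard error of the next one.
    """
    x = _sample_matrix(expr, zscore=zscore)
    n = x.shape[0]
    ks = sorted(int(k) for k in k_range)
    if ks[0] < 1 or ks[-1] > n - 1:
        raise ValueError(f"k_range {ks[0]}..{ks[-1]} outside [1, {n - 1}]")
    if n_refs < 10:
        raise ValueError("n_refs must be >= 10")

    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    refs = rng.uniform(lo, hi, size=(n_refs, n, x.shape[1]))
    ref_seeds = rng.integers(0, 2**31 - 1, size=(n_refs, len(ks)))
    data_seeds = rng.integers(0, 2**31 - 1, size=len(ks))

    rows = []
    for i, k in enumerate(ks):
        log_wk = np.log(_dispersion(x, k, int(data_seeds[i]), n_starts))
        log_ref = np.array(
            [
                np.log(_dispersion(refs[b], k, int(ref_seeds[b, i]), n_starts))
                for b in range(n_refs)
            ]
        )
        gap = log_ref.mean() - log_wk
        se = log_ref.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_refs)
        rows.append({"k": k, "gap": gap, "se": se, "log_wk": log_wk})
    curve = pd.DataFrame(rows)

    k_star = ks[-1]
    for i in range(len(ks) - 1):
        if curve.loc[i, "gap"] >= curve.loc[i + 1, "gap"] - curve.loc[i + 1, "se"]:
            k_star = ks[i]
            break
    return int(k_star), curve


def kmeans_cluster(
    expr: ExpressionMatrix,
    k: int,
    seed: int = 0,
    n_starts: int = 25,
    zscore: bool = True,
    gap_curve: pd.DataFrame | None = None,
) -> ClusterAssignment:
    """K-means on samples (k-means++ init, best of ``n_starts``)."""
    x = _sample_matrix(expr, zscore=zscore)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of samples {x.shape[0]}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_starts,
        max_iter=300,
        tol=1e-6,
        random_state=seed % (2**32),
    ).fit(x)
    labels = {s: int(l) + 1 for s, l in zip(expr.sample_ids, km.labels_)}
    return ClusterAssignment(
        labels=labels,
        k=k,
        inertia=float(km.inertia_),
        gap_curve=gap_curve,
        seed=seed,
    )


def compare_partitions(
    a: Mapping[str, int] | Sequence[int],
    b: Mapping[str, int] | Sequence[int],
    sample_ids: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Concordance (optimal label matching) and adjusted Rand index.

    Concordance maximizes the fraction of agreeing samples over label
    bijections via the Hungarian algorithm on the contingency table;
    with unequal label cardinalities the smaller side is matched and
    unmatched labels count as disagreement.
    """
    if isinstance(a, Mapping) or isinstance(b, Mapping):
        if sample_ids is None:
            keys_a = set(a) if isinstance(a, Mapping) else None
            keys_b = set(b) if isinstance(b, Mapping) else None
            if keys_a is not None and keys_b is not None and keys_a != keys_b:
                raise ValueError("partitions cover different sample sets")
            sample_ids = sorted(keys_a or keys_b)
        va = np.array([a[s] for s in sample_ids]) if isinstance(a, Mapping) else np.asarray(list(a))
        vb = np.array([b[s] for s in sample_ids]) if isinstance(b, Mapping) else np.asarray(list(b))
    else:
        va, vb = np.asarray(list(a)), np.asarray(list(b))
    if va.shape != vb.shape:
        raise ValueError("partitions have different lengths")

    ct = pd.crosstab(pd.Series(va), pd.Series(vb)).to_numpy()
    rows, cols = linear_sum_assignment(-ct)
    agree = ct[rows, cols].sum()
    concordance = float(agree) / va.size
    ari = float(adjusted_rand_score(va, vb))
    return concordance, ari
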