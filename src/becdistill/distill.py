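"""Supervised distillation of a minimal cluster-classifying gene set.

The stage mirrors a PCA-guided feature-selection loop: candidate gene
lists are taken as unions of the top-loading genes of the leading
principal components, each list is scored by repeated stratified
cross-validation of a sparse PLS discriminant classifier using the
balanced error rate (BER, the mean over classes of each class's error
rate), and the final list is chosen at the elbow of the LOESS-smoothed
BER-versus-gene-count curve: the inflection of the fitted curve is
located via its second differences and the smallest list whose BER is
within tolerance of the post-inflection minimum is accepted.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import RepeatedStratifiedKFold
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cluster import ClusterAssignment
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA candidate lists
# ---------------------------------------------------------------------------


def pca_loadings(expr: ExpressionMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the gene-standardized matrix (samples as observations).

    Returns (loadings, explained_variance) with loadings indexed by
    gene and columns PC1..PCm ordered by explained variance.  The sign
    of each component is fixed so its largest-|loading| entry is
    positive.
    """
    if expr.n_samples < 2 or expr.n_genes < 2:
        raise ValueError("PCA needs at least 2 samples and 2 genes")
    x = expr.values.T  # samples x genes
    sd = x.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("matrix has zero variance")
    x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(svd_solver="full")
    pca.fit(x)
    comps = pca.components_  # m x genes
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    cols = [f"PC{i + 1}" for i in range(comps.shape[0])]
    loadings = pd.DataFrame(comps.T, index=expr.data.index, columns=cols)
    return loadings, pca.explained_variance_


def eigenvector_gene_lists(
    loadings: pd.DataFrame,
    n_per_pc_grid: Sequence[int],
    n_pcs: int,
) -> list[tuple[int, list[str]]]:
    """Candidate lists: union of top-|loading| genes of the first PCs.

    For each grid value n, the n genes with largest absolute loading
    on each of the first ``n_pcs`` components are pooled (duplicates
    collapsed).  Returns [(n, sorted gene list), ...].
    """
    if n_pcs > loadings.shape[1]:
        raise ValueError(f"n_pcs={n_pcs} exceeds available components {loadings.shape[1]}")
    n_genes = loadings.shape[0]
    out = []
    for n in n_per_pc_grid:
        if n > n_genes:
            logger.warning("grid value %d exceeds %d genes; capped", n, n_genes)
            n = n_genes
        union: set[str] = set()
        for pc in loadings.columns[:n_pcs]:
            top = loadings[pc].abs().sort_values(ascending=False, kind="mergesort")
            union.update(top.index[:n])
        out.append((int(n), sorted(union)))
    return out


def n_pcs_for_variance(
    explained_variance: np.ndarray, fraction: float = 0.8, cap: int = 10
) -> int:
    """Smallest component count whose cumulative share reaches ``fraction``."""
    share = np.cumsum(explained_variance) / explained_variance.sum()
    n = int(np.searchsorted(share, fraction) + 1)
    return max(1, min(n, cap, explained_variance.size))


# ---------------------------------------------------------------------------
# sparse PLS-DA
# ---------------------------------------------------------------------------


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold a weight vector so only the ``keep`` largest
    |entries| survive (threshold = largest discarded magnitude)."""
    if keep >= w.size:
        return w
    mags = np.sort(np.abs(w))[::-1]
    lam = mags[keep]
    out = np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)
    return out


@dataclass
class SparseDAModel:
    """Fitted sparse PLS discriminant model.

    Holds the selected genes, per-component (sparse, unit-norm) weight
    vectors, the x-loadings and class-score loadings needed for
    prediction, the training standardization statistics, and class
    centroids in latent space.
    """

    genes: list[str]
    classes: list[int]
    weights: np.ndarray  # genes x H
    x_loadings: np.ndarray  # genes x H
    y_loadings: np.ndarray  # classes x H
    train_means: np.ndarray
    train_sds: np.ndarray
    y_mean: np.ndarray
    centroids: np.ndarray  # classes x H
    n_components: int
    prediction_rule: str = "max_dist"

    def rotation(self) -> np.ndarray:
        """Projection matrix mapping standardized X to latent scores."""
        return self.weights @ np.linalg.inv(self.x_loadings.T @ self.weights)

    def _standardize(self, x: np.ndarray, mode: str) -> np.ndarray:
        if mode == "train":
            mu, sd = self.train_means, self.train_sds
        else:  # the new cohort's own statistics (cross-platform contract)
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
        return (x - mu) / np.where(sd > 0, sd, 1.0)

    def latent_scores(self, x: np.ndarray, standardize: str = "train") -> np.ndarray:
        return self._standardize(x, standardize) @ self.rotation()

    def class_scores(self, x: np.ndarray, standardize: str = "train") -> np.ndarray:
        t = self.latent_scores(x, standardize)
        return t @ self.y_loadings.T + self.y_mean

    def predict(self, x: np.ndarray, standardize: str = "train") -> np.ndarray:
        """Predict class labels for samples x selected-genes data."""
        if self.prediction_rule == "max_dist":
            scores = self.class_scores(x, standardize)
            idx = scores.argmax(axis=1)
        elif self.prediction_rule == "centroid_dist":
            t = self.latent_scores(x, standardize)
            d = ((t[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
            idx = d.argmin(axis=1)
        else:
            raise ValueError(f"unknown prediction rule {self.prediction_rule!r}")
        return np.array([self.classes[i] for i in idx])

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes,
            "classes": self.classes,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "train_means": self.train_means.tolist(),
            "train_sds": self.train_sds.tolist(),
            "y_mean": self.y_mean.tolist(),
            "centroids": self.centroids.tolist(),
            "n_components": self.n_components,
            "prediction_rule": self.prediction_rule,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SparseDAModel":
        with open(path) as fh:
            payload = json.load(fh)
        for key in (
            "weights", "x_loadings", "y_loadings", "train_means",
            "train_sds", "y_mean", "centroids",
        ):
            payload[key] = np.asarray(payload[key], dtype=float)
        return cls(**payload)


def train_splsda(
    expr: ExpressionMatrix,
    labels: Mapping[str, int] | Sequence[int],
    genes: Sequence[str],
    n_components: int,
    keepx: Sequence[int] | None = None,
    prediction_rule: str = "max_dist",
) -> SparseDAModel:
    """Fit a sparse PLS-DA classifier on the given gene subset.

    Classes are one-hot encoded; each component's weight vector is the
    dominant singular vector of the X'Y cross-covariance, optionally
    soft-thresholded to ``keepx`` genes, with X and Y deflated between
    components.
    """
    genes = list(genes)
    sub = expr.subset_genes(genes)
    x = sub.values.T  # samples x genes
    if isinstance(labels, Mapping):
        y_raw = np.array([labels[s] for s in expr.sample_ids])
    else:
        y_raw = np.asarray(list(labels))
    classes = sorted(set(int(v) for v in y_raw))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int((y_raw == c).sum()) for c in classes}
    singletons = [c for c, n in counts.items() if n < 2]
    if singletons:
        raise ValueError(f"classes with a single sample: {singletons}")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    xs = (x - mu) / np.where(sd > 0, sd, 1.0)
    y = np.stack([(y_raw == c).astype(float) for c in classes], axis=1)
    y_mean = y.mean(axis=0)
    yd = y - y_mean

    n, p = xs.shape
    h_max = min(n_components, p, n - 1)
    xd = xs.copy()
    w_all = np.zeros((p, h_max))
    p_all = np.zeros((p, h_max))
    c_all = np.zeros((len(classes), h_max))
    for h in range(h_max):
        m = xd.T @ yd
        u, s, vt = np.linalg.svd(m, full_matrices=False)
        w = u[:, 0]
        if keepx is not None:
            w = _soft_threshold_keep(w, int(keepx[min(h, len(keepx) - 1)]))
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w = w / norm
        j = np.argmax(np.abs(w))
        if w[j] < 0:
            w = -w
        t = xd @ w
        denom = float(t @ t)
        if denom == 0:
            break
        p_load = xd.T @ t / denom
        c_load = yd.T @ t / denom
        xd = xd - np.outer(t, p_load)
        yd = yd - np.outer(t, c_load)
        w_all[:, h] = w
        p_all[:, h] = p_load
        c_all[:, h] = c_load

    model = SparseDAModel(
        genes=genes,
        classes=classes,
        weights=w_all,
        x_loadings=p_all,
        y_loadings=c_all,
        train_means=mu,
        train_sds=sd,
        y_mean=y_mean,
        centroids=np.zeros((len(classes), h_max)),
        n_components=h_max,
        prediction_rule=prediction_rule,
    )
    scores = model.latent_scores(x, standardize="train")
    model.centroids = np.stack(
        [scores[y_raw == c].mean(axis=0) for c in classes], axis=0
    )
    return model


def balanced_error_rate(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean over classes of each class's misclassification rate."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    rates = []
    for c in sorted(set(y_true.tolist())):
        mask = y_true == c
        rates.append(float((y_pred[mask] != c).mean()))
    return float(np.mean(rates))


def cv_ber(
    expr: ExpressionMatrix,
    labels: Mapping[str, int] | Sequence[int],
    genes: Sequence[str],
    n_components: int,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Repeated stratified k-fold BER of the sparse PLS-DA classifier.

    Returns (mean BER, SD across the fold x repeat evaluations).
    """
    if isinstance(labels, Mapping):
        y = np.array([labels[s] for s in expr.sample_ids])
    else:
        y = np.asarray(list(labels))
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        raise ValueError(
            f"stratification impossible: class counts {counts.to_dict()} < folds={folds}"
        )
    sub = expr.subset_genes(list(genes))
    data = sub.data
    bers = []
    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=seed % (2**32)
    )
    sample_ids = np.array(expr.sample_ids)
    for train_idx, test_idx in splitter.split(np.zeros(y.size), y):
        train_expr = ExpressionMatrix(data.iloc[:, train_idx])
        model = train_splsda(
            train_expr, y[train_idx], list(genes), n_components
        )
        x_test = data.iloc[:, test_idx].to_numpy().T
        pred = model.predict(x_test, standardize="train")
        bers.append(balanced_error_rate(y[test_idx], pred))
    return float(np.mean(bers)), float(np.std(bers, ddof=1))


# ---------------------------------------------------------------------------
# BER trace and elbow selection
# ---------------------------------------------------------------------------


@dataclass
class FeatureSelectionTrace:
    """BER-versus-gene-count curve over the candidate grid."""

    table: pd.DataFrame  # columns n_per_pc, n_genes, mean_ber, sd_ber
    gene_lists: dict[int, list[str]] = field(default_factory=dict)  # n_per_pc -> genes

    def __post_init__(self) -> None:
        bad = self.table[(self.table["mean_ber"] < 0) | (self.table["mean_ber"] > 1)]
        if len(bad):
            raise ValueError("BER outside [0, 1]")


def build_trace(
    expr: ExpressionMatrix,
    labels: Mapping[str, int] | Sequence[int],
    candidate_lists: Sequence[tuple[int, list[str]]],
    n_components: int,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> FeatureSelectionTrace:
    rows = []
    gene_lists = {}
    for n_per_pc, genes in candidate_lists:
        mean_ber, sd_ber = cv_ber(
            expr, labels, genes, n_components, folds=folds, repeats=repeats, seed=seed
        )
        rows.append(
            {
                "n_per_pc": n_per_pc,
                "n_genes": len(genes),
                "mean_ber": mean_ber,
                "sd_ber": sd_ber,
            }
        )
        gene_lists[n_per_pc] = list(genes)
    return FeatureSelectionTrace(pd.DataFrame(rows), gene_lists)


def select_elbow(
    trace: FeatureSelectionTrace,
    loess_span: float = 0.75,
    tolerance: float | None = None,
) -> int:
    """Choose the candidate size at the elbow of the BER curve.

    The mean BER is LOESS-smoothed against effective gene count; the
    inflection is the first sign change in the second differences of
    the fitted curve.  Among grid points at or after the inflection
    whose BER lies within ``tolerance`` (default: the BER SD at the
    inflection point) of the post-inflection minimum, the smallest
    gene count wins.  Returns the chosen ``n_per_pc`` grid value.
    """
    t = trace.table.sort_values("n_genes", kind="mergesort").reset_index(drop=True)
    if len(t) < 5:
        raise ValueError("elbow selection needs at least 5 grid points")
    # grid values mapping to the same effective gene list are one model
    t = t.drop_duplicates(subset="n_genes", keep="first").reset_index(drop=True)
    x = t["n_genes"].to_numpy(dtype=float)
    y = t["mean_ber"].to_numpy(dtype=float)
    fitted = lowess(y, x, frac=loess_span, it=0, xvals=x)
    d2 = fitted[:-2] - 2.0 * fitted[1:-1] + fitted[2:]

    inflection = None
    for i in range(len(d2) - 1):
        if d2[i] * d2[i + 1] < 0:
            inflection = i + 1  # grid index of the curvature change
            break
    if inflection is None:
        nonzero = np.abs(d2) > 1e-12
        if nonzero.any():
            # curvature never crosses zero: take its peak as the elbow
            inflection = int(np.argmax(np.abs(d2))) + 1
        else:
            warnings.warn("BER curve has no curvature; returning global minimum")
            best = t.loc[t["mean_ber"] == t["mean_ber"].min(), "n_genes"].idxmin()
            return int(t.loc[best, "n_per_pc"])

    tail = t.iloc[inflection:]
    post_min = tail["mean_ber"].min()
    tol = tolerance if tolerance is not None else float(t.loc[inflection, "sd_ber"])
    ok = tail[tail["mean_ber"] <= post_min + tol]
    chosen = ok.loc[ok["n_genes"].idxmin()]
    return int(chosen["n_per_pc"])


# ---------------------------------------------------------------------------
# end-to-end distillation and prediction
# ---------------------------------------------------------------------------


def distill_signature(
    expr: ExpressionMatrix,
    labels: Mapping[str, int] | Sequence[int],
    clustering_genes: Sequence[str],
    n_per_pc_grid: Sequence[int] = tuple(range(1, 26)),
    n_components: int | None = None,
    folds: int = 5,
    repeats: int = 10,
    loess_span: float = 0.75,
    seed: int = 0,
) -> tuple[SparseDAModel, FeatureSelectionTrace, int]:
    """Full distillation: PCA candidates -> BER trace -> elbow -> model.

    Returns the final sparse PLS-DA model (trained on the chosen gene
    list), the BER trace and the chosen grid value.
    """
    sub = expr.subset_genes(list(clustering_genes))
    loadings, explained = pca_loadings(sub)
    n_pcs = n_pcs_for_variance(explained)
    if isinstance(labels, Mapping):
        y = np.array([labels[s] for s in expr.sample_ids])
    else:
        y = np.asarray(list(labels))
    if n_components is None:
        n_components = max(1, len(set(y.tolist())) - 1)
    candidates = eigenvector_gene_lists(loadings, n_per_pc_grid, n_pcs)
    trace = build_trace(
        expr, y, candidates, n_components, folds=folds, repeats=repeats, seed=seed
    )
    chosen = select_elbow(trace, loess_span=loess_span)
    genes = trace.gene_lists[chosen]
    model = train_splsda(expr, y, genes, n_components)
    return model, trace, chosen


def predict_clusters(
    model: SparseDAModel,
    expr: ExpressionMatrix,
    standardize: str = "self",
) -> ClusterAssignment:
    """Classify a cohort with a trained model.

    By default new samples are z-scored with the new cohort's own
    per-gene statistics, which makes prediction robust to affine
    platform shifts between cohorts.
    """
    missing = [g for g in model.genes if g not in expr.data.index]
    if missing:
        raise KeyError(f"model genes absent from matrix: {missing}")
    x = expr.subset_genes(model.genes).values.T
    pred = model.predict(x, standardize=standardize)
    labels = {s: int(c) for s, c in zip(expr.sample_ids, pred)}
    return ClusterAssignment(
        labels=labels, k=max(model.classes), inertia=0.0, seed=None
    )
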