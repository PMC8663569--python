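"""Covariate-adjusted differential expression with variance moderation.

Each gene is fitted with the same ordinary-least-squares design
(severity class or patient cluster, plus sex and corticosteroid
covariates).  Residual variances are shrunk toward a common prior by
empirical Bayes: the prior degrees of freedom d0 and prior variance
s0^2 are estimated by matching the first two moments of the log
residual variances to a scaled-F (log-F) distribution, and each
gene's posterior variance is the d0/df-weighted average of prior and
observed.  Moderated t (and omnibus moderated F) statistics then use
d0 + residual df degrees of freedom, which stabilizes inference at
small sample sizes.  Significance is controlled per contrast with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .io import ExpressionMatrix, SampleMetadata


class DesignError(ValueError):
    """The design matrix is unusable (rank deficiency, bad alignment)."""


@dataclass
class DesignMatrix:
    """Numeric samples x covariates design with named contrasts."""

    matrix: pd.DataFrame
    contrasts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = self.matrix.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            # name the columns involved in the collinearity
            bad = []
            cols = list(self.matrix.columns)
            for j in range(x.shape[1]):
                keep = [i for i in range(x.shape[1]) if i != j]
                if np.linalg.matrix_rank(x[:, keep]) == rank:
                    bad.append(cols[j])
            raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)

    def add_contrast(self, name: str, weights: Mapping[str, float]) -> None:
        vec = np.zeros(len(self.matrix.columns))
        for col, w in weights.items():
            if col not in self.matrix.columns:
                raise DesignError(f"contrast {name!r} references unknown column {col!r}")
            vec[self.matrix.columns.get_loc(col)] = w
        self.contrasts[name] = vec


def build_design(
    meta: SampleMetadata,
    group: str | None = None,
    covariates: Sequence[str] = ("sex", "ics_dose", "ocs_use"),
    cell_means: bool = True,
) -> DesignMatrix:
    """Build a design from metadata columns.

    With ``group`` and ``cell_means=True`` the group enters as one
    indicator column per level (no intercept), which makes arbitrary
    between-group contrasts directly expressible; covariates are added
    as numeric columns (sex coded M=1, ocs True=1).
    """
    t = meta.table
    cols: dict[str, np.ndarray] = {}
    if group is not None:
        levels = sorted(pd.unique(t[group]), key=str)
        if cell_means:
            for lv in levels:
                cols[f"{group}={lv}"] = (t[group] == lv).to_numpy(float)
        else:
            cols["intercept"] = np.ones(len(t))
            for lv in levels[1:]:
                cols[f"{group}={lv}"] = (t[group] == lv).to_numpy(float)
    else:
        cols["intercept"] = np.ones(len(t))
    for cov in covariates:
        if cov == "sex":
            cols["sex_M"] = (t["sex"] == "M").to_numpy(float)
        elif cov == "ocs_use":
            cols["ocs"] = t["ocs_use"].to_numpy(float)
        else:
            cols[cov] = t[cov].to_numpy(float)
    return DesignMatrix(pd.DataFrame(cols, index=t.index))


# ---------------------------------------------------------------------------
# BH and empirical Bayes machinery
# ---------------------------------------------------------------------------


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iterations)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log residual variances to a scaled log-F.

    Returns (d0, s0^2): prior degrees of freedom and prior variance.
    d0 = inf when the observed variances are underdispersed relative
    to pure chi-square sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("all residual variances are zero")
    s2 = np.where(s2 > 0, s2, pos.min())
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) if e.size > 1 else 0.0
    excess = e_var - polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(float(excess))
    s0_sq = np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def _posterior_var(s2: np.ndarray, df: float, d0: float, s0_sq: float) -> np.ndarray:
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    if d0 == 0:
        return s2.copy()
    return (d0 * s0_sq + df * s2) / (d0 + df)


@dataclass
class DEResult:
    """Per-gene moderated statistics for one or more contrasts."""

    tables: dict[str, pd.DataFrame]  # contrast -> columns estimate, se, t, p, q
    d0: float
    s0_sq: float
    residual_df: float
    omnibus: pd.DataFrame | None = None  # columns F, p, q (if an F-test was run)

    def significant(self, contrast: str, alpha: float = 0.05) -> pd.DataFrame:
        t = self.tables[contrast]
        return t[(t["p"] < alpha) & (t["q"] < alpha)]


def fit_moderated_lm(
    expr: ExpressionMatrix,
    design: DesignMatrix,
    contrasts: Mapping[str, np.ndarray] | None = None,
    omnibus: Sequence[str] | np.ndarray | None = None,
    prior_df: float | None = None,
) -> DEResult:
    """Per-gene OLS with empirical-Bayes moderated t/F statistics.

    Parameters
    ----------
    contrasts
        Name -> coefficient vector over design columns.  Defaults to
        the design's own contrasts.
    omnibus
        Optional contrast matrix (rows = coefficient vectors) for a
        joint moderated F-test; a list of contrast names selects rows
        from ``contrasts``.
    prior_df
        Override the estimated prior df d0 (0 disables moderation,
        inf shrinks fully to the prior variance).
    """
    x = design.values
    y = expr.values  # genes x samples
    if x.shape[0] != y.shape[1]:
        raise DesignError(
            f"design has {x.shape[0]} rows but matrix has {y.shape[1]} samples"
        )
    n, p = x.shape
    df = n - p
    if df < 1:
        raise DesignError(f"residual df {df} < 1 (n={n}, p={p})")

    contrasts = dict(contrasts if contrasts is not None else design.contrasts)
    if not contrasts and omnibus is None:
        raise ValueError("no contrasts requested")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv  # genes x p
    resid = y - beta @ x.T
    rss = np.einsum("ij,ij->i", resid, resid)
    s2 = rss / df

    if prior_df is None:
        d0, s0_sq = estimate_prior(s2, df)
    elif prior_df == 0:
        d0, s0_sq = 0.0, float(np.median(s2))
    elif np.isinf(prior_df):
        _, s0_sq = estimate_prior(s2, df)
        d0 = np.inf
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_prior(s2, df)

    # guard genes with exactly zero residual variance
    pos = s2[s2 > 0]
    if pos.size and (s2 == 0).any():
        s2 = np.where(s2 > 0, s2, pos.min())
    s2_post = _posterior_var(s2, df, d0, s0_sq)
    df_total = df + d0

    tables: dict[str, pd.DataFrame] = {}
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        est = beta @ c
        v = float(c @ xtx_inv @ c)
        se = np.sqrt(s2_post * v)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, 0.0)
        if np.isinf(df_total):
            pvals = 2.0 * stats.norm.sf(np.abs(t))
        else:
            pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
        tables[name] = pd.DataFrame(
            {
                "estimate": est,
                "se": se,
                "t": t,
                "p": pvals,
                "q": bh_fdr(pvals),
            },
            index=expr.data.index,
        )

    omni_table = None
    if omnibus is not None:
        if isinstance(omnibus, (list, tuple)) and omnibus and isinstance(omnibus[0], str):
            cmat = np.vstack([contrasts[name] for name in omnibus])
        else:
            cmat = np.atleast_2d(np.asarray(omnibus, dtype=float))
        r = cmat.shape[0]
        mid = np.linalg.inv(cmat @ xtx_inv @ cmat.T)
        est = beta @ cmat.T  # genes x r
        quad = np.einsum("ij,jk,ik->i", est, mid, est)
        fstat = quad / (r * s2_post)
        if np.isinf(df_total):
            pvals = stats.chi2.sf(r * fstat, r)
        else:
            pvals = stats.f.sf(fstat, r, df_total)
        omni_table = pd.DataFrame(
            {"F": fstat, "p": pvals, "q": bh_fdr(pvals)}, index=expr.data.index
        )

    return DEResult(
        tables=tables,
        d0=float(d0),
        s0_sq=float(s0_sq),
        residual_df=float(df),
        omnibus=omni_table,
    )


# ---------------------------------------------------------------------------
# study-specific gene calls
# ---------------------------------------------------------------------------


def venn_counts(sets: Mapping[str, set]) -> dict[str, int]:
    """Region counts of the Venn diagram over named sets.

    Keys are '&'-joined sorted member names (e.g. 'HC&SA'); only
    non-empty regions appear.
    """
    names = sorted(sets)
    universe = set().union(*sets.values()) if sets else set()
    counts: dict[str, int] = {}
    for g in universe:
        members = [n for n in names if g in sets[n]]
        key = "&".join(members)
        counts[key] = counts.get(key, 0) + 1
    return counts


@dataclass
class SeverityDEResult:
    per_class: dict[str, dict[str, set[str]]]  # class -> {'up': set, 'down': set}
    union: set[str]
    venn: dict[str, int]
    n_tested: int
    fit: DEResult


def severity_de_genes(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    alpha: float = 0.05,
    covariates: Sequence[str] = ("sex", "ics_dose", "ocs_use"),
    prior_df: float | None = None,
) -> SeverityDEResult:
    """Genes differential across HC/MMA/SA, covariate adjusted.

    An omnibus moderated F over the class effects gates significance
    (p < alpha and BH q < alpha); each gated gene is assigned to a
    class's up/down set when its one-vs-rest contrast is itself
    significant, with direction from the contrast sign.
    """
    meta = meta.aligned_to(expr.sample_ids)
    classes = sorted(pd.unique(meta.table["severity"]), key=str)
    if len(classes) < 2:
        raise DesignError("need at least 2 severity classes")
    vc = meta.table["severity"].value_counts()
    small = vc[vc < 2]
    if len(small):
        raise DesignError(f"severity classes with <2 samples: {list(small.index)}")

    design = build_design(meta, group="severity", covariates=covariates)
    k = len(classes)
    for c in classes:
        w = {f"severity={c}": 1.0}
        for o in classes:
            if o != c:
                w[f"severity={o}"] = -1.0 / (k - 1)
        design.add_contrast(f"{c}_vs_rest", w)
    # omnibus: successive differences between class means
    omni = []
    for a, b in zip(classes[:-1], classes[1:]):
        design.add_contrast(f"{a}_vs_{b}", {f"severity={a}": 1.0, f"severity={b}": -1.0})
        omni.append(f"{a}_vs_{b}")

    fit = fit_moderated_lm(expr, design, omnibus=omni, prior_df=prior_df)
    gated = set(
        fit.omnibus.index[(fit.omnibus["p"] < alpha) & (fit.omnibus["q"] < alpha)]
    )

    per_class: dict[str, dict[str, set[str]]] = {}
    for c in classes:
        t = fit.tables[f"{c}_vs_rest"]
        sig = t[(t["p"] < alpha) & (t["q"] < alpha)]
        sig = sig[sig.index.isin(gated)]
        per_class[c] = {
            "up": set(sig.index[sig["estimate"] > 0]),
            "down": set(sig.index[sig["estimate"] < 0]),
        }
    class_sets = {c: per_class[c]["up"] | per_class[c]["down"] for c in classes}
    return SeverityDEResult(
        per_class=per_class,
        union=gated,
        venn=venn_counts(class_sets),
        n_tested=expr.n_genes,
        fit=fit,
    )


def cluster_specific_genes(
    expr: ExpressionMatrix,
    cluster_labels: Mapping[str, int] | Sequence[int],
    meta: SampleMetadata | None = None,
    alpha: float = 0.05,
    covariates: Sequence[str] = ("sex", "ics_dose", "ocs_use"),
    prior_df: float | None = None,
) -> dict[int, dict[str, set[str]]]:
    """Per-cluster up/down gene sets under the all-pairwise rule.

    A gene is cluster-c-up iff, for every other cluster c', the
    contrast c - c' is significant (p < alpha, BH q < alpha within
    that contrast) with a positive estimate; symmetrically for down.
    Covariates are adjusted when metadata is supplied.
    """
    if isinstance(cluster_labels, Mapping):
        labels = np.array([cluster_labels[s] for s in expr.sample_ids])
    else:
        labels = np.asarray(list(cluster_labels))
    clusters = sorted(set(int(v) for v in labels))
    if len(clusters) < 2:
        raise DesignError("need at least 2 clusters")
    for c in clusters:
        if (labels == c).sum() == 0:
            raise DesignError(f"cluster {c} is empty")

    if meta is not None:
        meta = meta.aligned_to(expr.sample_ids)
        t = meta.table.copy()
    else:
        t = pd.DataFrame(index=pd.Index(expr.sample_ids, name="sample_id"))
        covariates = ()
    t["_cluster"] = labels
    cols: dict[str, np.ndarray] = {}
    for c in clusters:
        cols[f"cl={c}"] = (t["_cluster"] == c).to_numpy(float)
    for cov in covariates:
        if cov == "sex":
            cols["sex_M"] = (t["sex"] == "M").to_numpy(float)
        elif cov == "ocs_use":
            cols["ocs"] = t["ocs_use"].to_numpy(float)
        else:
            cols[cov] = t[cov].to_numpy(float)
    design = DesignMatrix(pd.DataFrame(cols, index=t.index))
    for a in clusters:
        for b in clusters:
            if a != b:
                design.add_contrast(f"{a}-{b}", {f"cl={a}": 1.0, f"cl={b}": -1.0})

    fit = fit_moderated_lm(expr, design, prior_df=prior_df)
    out: dict[int, dict[str, set[str]]] = {}
    for c in clusters:
        others = [o for o in clusters if o != c]
        up = None
        down = None
        for o in others:
            tt = fit.tables[f"{c}-{o}"]
            sig = (tt["p"] < alpha) & (tt["q"] < alpha)
            u = set(tt.index[sig & (tt["estimate"] > 0)])
            d = set(tt.index[sig & (tt["estimate"] < 0)])
            up = u if up is None else up & u
            down = d if down is None else down & d
        out[c] = {"up": up or set(), "down": down or set()}
    return out


def ocs_contrast_overlap(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    clustering_genes: Iterable[str],
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> tuple[int, int, set[str]]:
    """OCS user vs non-user DE (adjusting severity, ICS, sex) and its
    overlap with the clustering gene set.

    Returns (number of significant genes, overlap size, the
    significant set).
    """
    meta = meta.aligned_to(expr.sample_ids)
    ocs = meta.table["ocs_use"].to_numpy(bool)
    if ocs.all() or (~ocs).all():
        raise DesignError("all samples share the same OCS status")
    t = meta.table
    classes = sorted(pd.unique(t["severity"]), key=str)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(t))}
    cols["ocs"] = ocs.astype(float)
    for lv in classes[1:]:
        cols[f"severity={lv}"] = (t["severity"] == lv).to_numpy(float)
    cols["ics_dose"] = t["ics_dose"].to_numpy(float)
    cols["sex_M"] = (t["sex"] == "M").to_numpy(float)
    design = DesignMatrix(pd.DataFrame(cols, index=t.index))
    design.add_contrast("ocs_effect", {"ocs": 1.0})
    fit = fit_moderated_lm(expr, design, prior_df=prior_df)
    sig = set(fit.significant("ocs_effect", alpha).index)
    overlap = sig & set(clustering_genes)
    return len(sig), len(overlap), sig
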