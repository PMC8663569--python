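"""Elastic-net modeling of lung function on the distilled signature.

FEV1 (% predicted) is regressed on z-scored expression of the
signature genes under the mixed L1/L2 penalty

    (1/2n) ||y - X b||^2 + lambda * (alpha ||b||_1 + (1-alpha)/2 ||b||_2^2)

with the regularization strength chosen by leave-one-out (LOO)
cross-validated mean squared error along a 100-point log-spaced
lambda path.  Model quality is judged the way a clinician would read
it: Spearman rank correlation between the LOO-predicted and measured
FEV1, plus per-gene Spearman checks that each retained coefficient's
sign agrees with the marginal expression-lung-function association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import enet_path

from .diffexpr import bh_fdr
from .io import ExpressionMatrix


@dataclass
class ENModel:
    """Fitted elastic-net lung-function model."""

    genes: list[str]
    intercept: float
    coef: pd.Series  # per-gene, standardized-expression units -> %predicted
    alpha: float  # L1 mixing in [0, 1]
    lambda_path: np.ndarray
    lambda_selected: float
    loo_predictions: pd.Series  # per-sample LOO prediction
    loo_mse_path: np.ndarray = field(repr=False, default=None)
    train_means: np.ndarray = field(repr=False, default=None)
    train_sds: np.ndarray = field(repr=False, default=None)

    @property
    def nonzero_genes(self) -> list[str]:
        return list(self.coef.index[self.coef != 0])

    def predict(self, expr: ExpressionMatrix) -> pd.Series:
        x = expr.subset_genes(self.genes).values.T
        xs = (x - self.train_means) / self.train_sds
        return pd.Series(
            self.intercept + xs @ self.coef.to_numpy(), index=expr.sample_ids
        )

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"coef": self.coef})
        out["selected"] = out["coef"] != 0
        return out.sort_values("coef")


def _lambda_grid(
    x: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int = 100, eps: float = 1e-4
) -> np.ndarray:
    n = x.shape[0]
    yc = y - y.mean()
    lam_max = np.max(np.abs(x.T @ yc)) / (n * max(alpha, 1e-3))
    return np.logspace(np.log10(lam_max), np.log10(lam_max * eps), n_lambda)


def fit_elastic_net(
    expr: ExpressionMatrix,
    fev1: Mapping[str, float] | pd.Series | Sequence[float],
    genes: Sequence[str] | None = None,
    alpha: float = 0.5,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> ENModel:
    """Elastic net of FEV1 on z-scored signature-gene expression.

    The penalty weight lambda is selected at the minimum of the
    leave-one-out mean squared error computed over the whole path
    (each left-out sample is predicted from a path fitted, and
    standardized, on the remaining samples).
    """
    genes = list(genes) if genes is not None else expr.gene_ids
    sub = expr.subset_genes(genes)
    x = sub.values.T  # samples x genes
    if isinstance(fev1, Mapping):
        y = np.array([float(fev1[s]) for s in expr.sample_ids])
    elif isinstance(fev1, pd.Series):
        y = fev1.loc[expr.sample_ids].to_numpy(dtype=float)
    else:
        y = np.asarray(list(fev1), dtype=float)
    n = y.size
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if n < 10:
        warnings.warn("fewer than 10 samples: elastic-net selection is unstable")
    if not np.all(np.isfinite(y)):
        raise ValueError("FEV1 values must be finite")
    if np.ptp(y) == 0:
        raise ValueError("FEV1 is constant")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")

    mu_full = x.mean(axis=0)
    sd_full = x.std(axis=0)
    sd_full = np.where(sd_full > 0, sd_full, 1.0)
    xs_full = (x - mu_full) / sd_full

    if lambda_grid is None:
        lambda_grid = _lambda_grid(xs_full, y, alpha)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    l1_ratio = max(alpha, 1e-12)  # sklearn forbids exactly 0 on a path
    loo_pred = np.zeros((n, lambda_grid.size))
    order = np.argsort(-lambda_grid)  # enet_path wants decreasing alphas
    lam_sorted = lambda_grid[order]
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xtr = x[mask]
        mu = xtr.mean(axis=0)
        sd = xtr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        xtr_s = (xtr - mu) / sd
        ytr = y[mask]
        ytr_c = ytr - ytr.mean()
        _, coefs, _ = enet_path(
            xtr_s, ytr_c, l1_ratio=l1_ratio, alphas=lam_sorted, max_iter=5000
        )
        xi = (x[i] - mu) / sd
        pred_sorted = ytr.mean() + xi @ coefs
        loo_pred[i, order] = pred_sorted

    mse = ((loo_pred - y[:, None]) ** 2).mean(axis=0)
    best = int(np.argmin(mse))
    lam_star = float(lambda_grid[best])

    yc = y - y.mean()
    _, coefs, _ = enet_path(
        xs_full, yc, l1_ratio=l1_ratio, alphas=lam_sorted, max_iter=5000
    )
    coef_full = coefs[:, order][:, best]
    coef = pd.Series(coef_full, index=genes)
    return ENModel(
        genes=genes,
        intercept=float(y.mean()),
        coef=coef,
        alpha=alpha,
        lambda_path=lambda_grid,
        lambda_selected=lam_star,
        loo_predictions=pd.Series(loo_pred[:, best], index=expr.sample_ids),
        loo_mse_path=mse,
        train_means=mu_full,
        train_sds=sd_full,
    )


def spearman(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Spearman rho with tie-averaged ranks; two-sided p by the
    t-approximation.  Returns (rho, p); p is NaN below n=4 or for
    constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant input: Spearman rho undefined")
        return np.nan, np.nan
    rho, p = stats.spearmanr(a, b)
    if a.size < 4:
        warnings.warn("n < 4: Spearman p-value undefined")
        return float(rho), np.nan
    return float(rho), float(p)


def validate_predictions(
    model: ENModel, fev1: Mapping[str, float] | pd.Series
) -> tuple[float, float]:
    """Spearman correlation of LOO-predicted versus measured FEV1."""
    if model.loo_predictions is None or model.loo_predictions.empty:
        raise ValueError("model carries no LOO predictions")
    ids = list(model.loo_predictions.index)
    if isinstance(fev1, Mapping):
        y = np.array([float(fev1[s]) for s in ids])
    else:
        y = fev1.loc[ids].to_numpy(dtype=float)
    return spearman(model.loo_predictions.to_numpy(), y)


def coefficient_gene_validation(
    model: ENModel,
    expr: ExpressionMatrix,
    fev1: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Per-gene Spearman check of every nonzero-coefficient gene.

    Returns a table with rho, p, BH q and a flag for agreement
    between the marginal correlation sign and the coefficient sign.
    Constant genes get NaN rho and are flagged.
    """
    ids = expr.sample_ids
    if isinstance(fev1, Mapping):
        y = np.array([float(fev1[s]) for s in ids])
    else:
        y = fev1.loc[ids].to_numpy(dtype=float)
    rows = []
    for g in model.nonzero_genes:
        vals = expr.data.loc[g].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = spearman(vals, y)
        beta = float(model.coef[g])
        rows.append(
            {
                "gene": g,
                "coef": beta,
                "rho": rho,
                "p": p,
                "sign_agrees": bool(np.sign(rho) == np.sign(beta))
                if np.isfinite(rho)
                else False,
                "defined": bool(np.isfinite(rho)),
            }
        )
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["coef", "rho", "p", "sign_agrees", "defined"]
    )
    if len(table):
        ps = table["p"].to_numpy(dtype=float)
        q = np.full(ps.size, np.nan)
        ok = np.isfinite(ps)
        if ok.any():
            q[ok] = bh_fdr(ps[ok])
        table["q"] = q
    else:
        table["q"] = []
    return table
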