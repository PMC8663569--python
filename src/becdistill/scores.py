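"""Per-sample composite expression scores.

Cytokine-response and T2-phenotype signatures are summarized per
participant either as the arithmetic mean of log2 expression or as
the geometric mean on the linear scale (the two agree:
geometric-mean(2^x) = 2^(mean x)).  A Spearman helper correlates
scores with each other or with single genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .fev1 import spearman
from .io import ExpressionMatrix


@dataclass
class SignatureScore:
    name: str
    genes: list[str]
    aggregation: str  # 'mean' | 'geometric_mean'
    scores: pd.Series  # sample -> score

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has an empty gene list")
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValueError(f"signature {self.name!r} has non-finite scores")


def _subset(expr: ExpressionMatrix, genes: Iterable[str]) -> np.ndarray:
    genes = list(genes)
    missing = [g for g in genes if g not in expr.data.index]
    if missing:
        raise KeyError(f"signature genes absent from matrix: {missing}")
    return expr.data.loc[genes].to_numpy(dtype=float)


def mean_signature(
    expr: ExpressionMatrix, genes: Iterable[str], name: str = "signature"
) -> SignatureScore:
    """Arithmetic mean of log2 expression across the gene list."""
    genes = list(genes)
    vals = _subset(expr, genes)
    return SignatureScore(
        name=name,
        genes=genes,
        aggregation="mean",
        scores=pd.Series(vals.mean(axis=0), index=expr.sample_ids),
    )


def geometric_mean_signature(
    expr_linear: ExpressionMatrix, genes: Iterable[str], name: str = "signature"
) -> SignatureScore:
    """Geometric mean of strictly positive linear-scale expression."""
    genes = list(genes)
    vals = _subset(expr_linear, genes)
    if np.any(vals <= 0):
        raise ValueError("geometric mean needs strictly positive values")
    return SignatureScore(
        name=name,
        genes=genes,
        aggregation="geometric_mean",
        scores=pd.Series(np.exp(np.log(vals).mean(axis=0)), index=expr_linear.sample_ids),
    )


def score_signature(
    expr_log2: ExpressionMatrix,
    genes: Iterable[str],
    aggregation: str = "geometric_mean",
    name: str = "signature",
) -> SignatureScore:
    """Score a log2 matrix with either aggregation.

    The geometric mean is taken on the linear (2^x) scale, matching
    the convention of reporting geometric-mean expression scores.
    """
    if aggregation == "mean":
        return mean_signature(expr_log2, genes, name)
    if aggregation == "geometric_mean":
        linear = ExpressionMatrix(2.0 ** expr_log2.data)
        return geometric_mean_signature(linear, genes, name)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def score_gene_correlation(
    a: SignatureScore | pd.Series | Mapping[str, float],
    b: SignatureScore | pd.Series | Mapping[str, float],
) -> tuple[float, float]:
    """Spearman correlation between two per-sample quantities.

    Accepts signature scores, series or mappings; samples are aligned
    on the intersection of IDs.
    """

    def as_series(v) -> pd.Series:
        if isinstance(v, SignatureScore):
            return v.scores
        if isinstance(v, pd.Series):
            return v
        return pd.Series(dict(v))

    sa, sb = as_series(a), as_series(b)
    common = sa.index.intersection(sb.index)
    if len(common) < 4:
        raise ValueError(f"need >= 4 paired samples, got {len(common)}")
    return spearman(sa.loc[common].to_numpy(), sb.loc[common].to_numpy())
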