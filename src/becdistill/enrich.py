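"""Gene-set enrichment: over-representation and preranked GSEA.

Over-representation uses the upper-tail hypergeometric test of the
query/set overlap against a fixed gene universe.  Preranked GSEA
walks the score-ranked gene list with the weighted Kolmogorov-Smirnov
running sum (hits add |score|^p normalized by the in-set total,
misses subtract 1/(N - N_hit)); the enrichment score ES is the signed
maximum deviation, and significance comes from a gene-label
permutation null with the normalized score NES = ES divided by the
mean |null ES| of matching sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .io import GeneSetLibrary

logger = logging.getLogger(__name__)


def hypergeom_enrich(
    query_genes: Iterable[str],
    library: GeneSetLibrary,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    For each set: population = universe, successes = set intersected
    with the universe, draws = |query|; p = P(X >= observed overlap).
    Returns a table indexed by term with columns type, overlap,
    set_size, universe_size, p, q and the overlapping genes.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    if not query:
        raise ValueError("empty query (after intersecting with universe)")

    big_n, n_draw = len(universe), len(query)
    rows = []
    for gs in library:
        members = set(gs.genes) & universe
        if not members:
            continue
        overlap = sorted(query & members)
        p = float(stats.hypergeom.sf(len(overlap) - 1, big_n, len(members), n_draw))
        rows.append(
            {
                "term": gs.name,
                "type": gs.set_type,
                "overlap": len(overlap),
                "set_size": len(members),
                "universe_size": big_n,
                "p": min(p, 1.0),
                "enriched_genes": tuple(overlap),
            }
        )
    table = pd.DataFrame(rows).set_index("term") if rows else pd.DataFrame(
        columns=["type", "overlap", "set_size", "universe_size", "p", "enriched_genes"]
    )
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
    else:
        table["q"] = []
    return table


def top_terms(results: pd.DataFrame, n: int = 5, alpha: float = 0.05) -> list[str]:
    """Top-n significant terms: q < alpha, ordered by p ascending with
    ties broken by larger overlap then term name."""
    if results.empty:
        return []
    sig = results[results["q"] < alpha].copy()
    if sig.empty:
        return []
    sig = sig.sort_values(
        by=["p", "overlap"], ascending=[True, False], kind="mergesort"
    )
    # stable final tie-break on the term name
    sig["_name"] = sig.index
    sig = sig.sort_values(by=["p", "overlap", "_name"], ascending=[True, False, True], kind="mergesort")
    return list(sig.index[:n])


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------


@dataclass
class GseaResult:
    es: float
    nes: float
    p: float
    n_hits: int
    n_perm: int


def enrichment_score(
    scores: np.ndarray, is_hit: np.ndarray, weight_p: float = 1.0
) -> float:
    """Weighted KS running-sum enrichment score on a pre-ranked list.

    ``scores`` must already be sorted descending; ``is_hit`` flags set
    membership per position.  Ties in |max| vs |min| deviation resolve
    to the positive excursion.
    """
    n = scores.size
    n_hit = int(is_hit.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must hit a strict subset of the ranked list")
    w = np.abs(scores[is_hit]) ** weight_p
    total = w.sum()
    if total == 0:  # all hit scores zero: fall back to unweighted steps
        w = np.ones(n_hit)
        total = float(n_hit)
    miss_step = 1.0 / (n - n_hit)
    running = 0.0
    best = 0.0
    hit_i = 0
    for i in range(n):
        if is_hit[i]:
            running += w[hit_i] / total
            hit_i += 1
        else:
            running -= miss_step
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return float(best)


def _es_from_positions(
    pos: np.ndarray, abs_scores_p: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for many hit-position sets (permutations x m).

    Uses the closed form of the running sum at/before each hit; the
    extremum of the walk always occurs there (or is zero).
    """
    pos = np.sort(pos, axis=1)
    m = pos.shape[1]
    w = abs_scores_p[pos]
    total = w.sum(axis=1, keepdims=True)
    total = np.where(total > 0, total, m)  # degenerate all-zero weights
    cum = np.cumsum(w, axis=1) / total
    j = np.arange(m)[None, :]
    drop = (pos - j) / (n - m)
    v_after = cum - drop
    v_before = cum - w / total - drop
    hi = np.maximum(v_after.max(axis=1), 0.0)
    lo = np.minimum(v_before.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def gsea_preranked(
    ranked_stats: Mapping[str, float] | pd.Series,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
    min_size: int = 2,
) -> GseaResult | None:
    """Preranked GSEA for one gene set with a gene-label permutation null.

    Returns None (with a warning) when fewer than ``min_size`` set
    members appear in the ranked list.  p carries a +1 pseudocount in
    both numerator and denominator of the matching-sign tail fraction.
    """
    if isinstance(ranked_stats, Mapping):
        series = pd.Series(ranked_stats, dtype=float)
    else:
        series = ranked_stats.astype(float)
    if not np.all(np.isfinite(series.to_numpy())):
        raise ValueError("ranking statistics must be finite")
    series = series.sort_values(ascending=False, kind="mergesort")
    genes = series.index.to_numpy()
    scores = series.to_numpy()
    hits = np.isin(genes, list(set(gene_set)))
    n_hit = int(hits.sum())
    if n_hit < min_size or n_hit >= genes.size:
        logger.warning("gene set has %d effective members; skipped", n_hit)
        return None

    es = enrichment_score(scores, hits, weight_p)

    rng = np.random.default_rng(seed)
    abs_p = np.abs(scores) ** weight_p
    perm_pos = np.argsort(rng.random((n_perm, genes.size)), axis=1)[:, :n_hit]
    null = _es_from_positions(perm_pos, abs_p, genes.size)

    same = null[null > 0] if es >= 0 else null[null < 0]
    if same.size:
        nes = es / np.abs(same).mean()
        p = (np.sum(np.abs(same) >= abs(es)) + 1.0) / (same.size + 1.0)
    else:
        nes = np.nan
        p = 1.0
    return GseaResult(es=float(es), nes=float(nes), p=float(p), n_hits=n_hit, n_perm=n_perm)


def gsea_library(
    ranked_stats: Mapping[str, float] | pd.Series,
    library: GeneSetLibrary,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Run preranked GSEA over a library; BH q across tested sets."""
    rows = []
    for i, gs in enumerate(library):
        if not min_size <= len(gs.genes):
            continue
        if len(gs.genes) > max_size:
            continue
        res = gsea_preranked(
            ranked_stats, gs.genes, n_perm=n_perm, weight_p=weight_p,
            seed=seed + i, min_size=min_size,
        )
        if res is None:
            continue
        rows.append(
            {
                "term": gs.name,
                "type": gs.set_type,
                "overlap": res.n_hits,
                "ES": res.es,
                "NES": res.nes,
                "p": res.p,
            }
        )
    table = pd.DataFrame(rows).set_index("term") if rows else pd.DataFrame(
        columns=["type", "overlap", "ES", "NES", "p"]
    )
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
    else:
        table["q"] = []
    return table
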