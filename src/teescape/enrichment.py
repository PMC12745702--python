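"""Gene-set enrichment: hypergeometric overrepresentation (ORA), weighted
running-sum GSEA with a member-resampling permutation null, and
Benjamini-Hochberg FDR.

GSEA here operates on a DE-derived ranking (signed -log10 p), so the
permutation null resamples gene labels into same-size sets rather than
permuting sample phenotypes — per-sample expression is upstream of this
pipeline and not available at this layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneSetCollection, TeescapeError
from .rrho import RankedList

logger = logging.getLogger(__name__)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("pvalues must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class OraResult:
    k_overlap: int
    query_size: int
    category_size: int
    universe_size: int
    p: float
    odds: float


def ora_test(
    query: Sequence[str] | frozenset[str],
    category: Sequence[str] | frozenset[str],
    universe: Sequence[str] | frozenset[str],
) -> OraResult:
    """Upper-tail hypergeometric overrepresentation test.

    Population = universe, successes = category ∩ universe, draws = query;
    p = P[X >= k] where k is the observed overlap. The query must be a
    subset of the universe. The odds ratio is the 2x2 table's cross ratio
    (inf when the off-diagonal is empty).
    """
    uni = frozenset(universe)
    q = frozenset(query)
    if not uni:
        raise TeescapeError("empty universe")
    if not q:
        raise TeescapeError("empty query set")
    if not q <= uni:
        raise TeescapeError(f"query has {len(q - uni)} ids outside the universe")
    cat = frozenset(category) & uni
    k = len(q & cat)
    M, K, n = len(uni), len(cat), len(q)
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    a, b, c, d = k, n - k, K - k, M - n - K + k
    odds = float("nan") if (a * d == 0 and b * c == 0) else (
        float("inf") if b * c == 0 else (a * d) / (b * c)
    )
    return OraResult(
        k_overlap=k, query_size=n, category_size=K, universe_size=M,
        p=min(p, 1.0), odds=odds,
    )


@dataclass(frozen=True)
class EnrichmentConfig:
    """Knobs for set-based enrichment.

    Category sizes outside [min_set_size, max_set_size] (after intersection
    with the tested universe) are skipped to keep terms specific; the
    defaults cap categories at 300 genes and call terms at FDR < 0.01.
    """

    min_set_size: int = 5
    max_set_size: int = 300
    fdr_cutoff: float = 0.01
    n_permutations: int = 1000
    weight_exponent: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.min_set_size > self.max_set_size:
            raise ValueError("min_set_size must not exceed max_set_size")
        if not (0 < self.fdr_cutoff < 1):
            raise ValueError("fdr_cutoff must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int
    k_overlap: int
    es: float
    nes: float | None
    p: float
    fdr: float
    direction: str
    leading_edge_size: int = 0

    @property
    def es_or_odds(self) -> float:
        return self.es


def _running_sum_es(
    weights: np.ndarray, hit_positions: np.ndarray, n: int
) -> tuple[float, int]:
    """Signed maximal deviation of the weighted KS running sum.

    ``weights`` are |score|^exponent over the full ranking; hit increments
    are proportional to the hit's weight, miss decrements uniform. Returns
    (ES, leading-edge size: hits at or before the extremum when ES > 0).
    The extrema of the path occur immediately after a hit (maximum
    candidates) or immediately before one (minimum candidates), so only hit
    positions need inspection.
    """
    pos = np.sort(hit_positions)
    m = pos.size
    if m == 0:
        raise TeescapeError("gene set has no members in the ranking")
    w = weights[pos]
    wsum = w.sum()
    if wsum <= 0:
        # all hit scores are exactly zero: fall back to unweighted increments
        w = np.ones(m)
        wsum = float(m)
    cum_hit = np.cumsum(w) / wsum
    n_miss = n - m
    if n_miss == 0:
        return 1.0, m
    miss_before = (pos - np.arange(m)) / n_miss
    after_hit = cum_hit - miss_before
    before_hit = np.concatenate(([0.0], cum_hit[:-1])) - miss_before
    i_max = int(np.argmax(after_hit))
    i_min = int(np.argmin(before_hit))
    es_max = float(after_hit[i_max])
    es_min = float(before_hit[i_min])
    if es_max >= -es_min:
        return es_max, i_max + 1
    return es_min, i_min


def _null_es(
    weights: np.ndarray,
    m: int,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 256,
) -> np.ndarray:
    """ES of ``n_perm`` random same-size member sets (vectorized)."""
    n = weights.size
    n_miss = n - m
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # b random m-subsets of positions, each row sorted
        pos = np.argsort(rng.random((b, n)), axis=1)[:, :m]
        pos.sort(axis=1)
        w = weights[pos]
        wsum = w.sum(axis=1, keepdims=True)
        degenerate = (wsum <= 0).ravel()  # all-zero draws fall back to unweighted
        if degenerate.any():
            w[degenerate] = 1.0
            wsum = w.sum(axis=1, keepdims=True)
        cum_hit = np.cumsum(w, axis=1) / wsum
        if n_miss == 0:
            out[done : done + b] = 1.0
            done += b
            continue
        miss_before = (pos - np.arange(m)[None, :]) / n_miss
        after_hit = cum_hit - miss_before
        before_hit = np.concatenate(
            [np.zeros((b, 1)), cum_hit[:, :-1]], axis=1
        ) - miss_before
        es_max = after_hit.max(axis=1)
        es_min = before_hit.min(axis=1)
        out[done : done + b] = np.where(es_max >= -es_min, es_max, es_min)
        done += b
    return out


def gsea(
    ranked: RankedList,
    sets: GeneSetCollection,
    cfg: EnrichmentConfig | None = None,
) -> list[EnrichmentResult]:
    """Weighted running-sum gene-set enrichment over a signed ranking.

    For each surviving set: ES is the signed maximal deviation of the
    running sum (hit increments ∝ |score|^weight_exponent, miss decrements
    uniform); the null is ``n_permutations`` random same-size member sets;
    NES normalizes ES by the mean |null ES| of matching sign; p is the
    sign-matched empirical tail with the +1 correction; FDR is BH across
    the reported terms.
    """
    cfg = cfg or EnrichmentConfig()
    n = len(ranked)
    ids = list(ranked.ids)
    index = {fid: i for i, fid in enumerate(ids)}
    weights = np.abs(ranked.scores) ** cfg.weight_exponent
    surviving = sets.filtered(ids, cfg.min_set_size, cfg.max_set_size)
    if len(surviving) == 0:
        logger.warning(
            "no gene sets within size [%d, %d] after intersection",
            cfg.min_set_size,
            cfg.max_set_size,
        )
        return []
    rng = np.random.default_rng(cfg.rng_seed)

    # one shared null per set size keeps permutation cost linear in #sizes
    names = sorted(surviving.sets)
    sizes = sorted({len(surviving.sets[nm]) for nm in names})
    null_by_size = {
        m: _null_es(weights, m, cfg.n_permutations, rng) for m in sizes
    }

    results: list[EnrichmentResult] = []
    for name in names:
        members = surviving.sets[name]
        pos = np.array([index[g] for g in members])
        es, lead = _running_sum_es(weights, pos, n)
        null = null_by_size[len(members)]
        same_sign = null >= 0 if es >= 0 else null < 0
        null_same = null[same_sign]
        if null_same.size:
            p = (1 + int(np.sum(np.abs(null_same) >= abs(es)))) / (1 + null_same.size)
            nes = es / float(np.mean(np.abs(null_same))) if np.mean(np.abs(null_same)) > 0 else None
        else:
            p, nes = 1.0, None
        results.append(
            EnrichmentResult(
                set_name=name,
                set_size=len(members),
                k_overlap=len(members),
                es=es,
                nes=nes,
                p=p,
                fdr=1.0,
                direction="up" if es >= 0 else "down",
                leading_edge_size=lead,
            )
        )
    fdrs = bh_fdr([r.p for r in results])
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "set_size": r.set_size,
                "es": r.es,
                "nes": r.nes,
                "p": r.p,
                "fdr": r.fdr,
                "direction": r.direction,
                "leading_edge_size": r.leading_edge_size,
            }
            for r in results
        ]
    )


def ora_frame(
    query,
    sets: GeneSetCollection,
    universe,
    min_set_size: int = 5,
    max_set_size: int = 300,
) -> pd.DataFrame:
    """ORA of one query against every set in a collection, BH-adjusted."""
    surviving = sets.filtered(universe, min_set_size, max_set_size)
    rows = []
    for name in sorted(surviving.sets):
        r = ora_test(query, surviving.sets[name], universe)
        rows.append(
            {
                "set_name": name,
                "k_overlap": r.k_overlap,
                "set_size": r.category_size,
                "odds": r.odds,
                "p": r.p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values(["p", "set_name"]).reset_index(drop=True)
    return df
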