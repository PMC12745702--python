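"""Rank-rank hypergeometric overlap (RRHO) between two DE tables.

Features are ranked by a signed significance score, -log10(p) * sign(log2fc),
so the strongest upregulation leads the list and the strongest downregulation
trails it. For every pair of rank thresholds on a step grid, the overlap of
the two top-lists is scored by a hypergeometric tail; the map stores signed
-log10(p): positive where the overlap exceeds its expectation (enrichment),
negative where it falls short (depletion). With this orientation the
lower-left corner of the map captures coupregulation and the upper-right
codownregulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import TeescapeError, UniverseMismatchError
from .io import DEResultTable

P_FLOOR = 1e-300


@dataclass
class RankedList:
    """Feature ids in descending signed-score order."""

    ids: tuple[str, ...]
    scores: np.ndarray
    condition_label: str = ""

    def __post_init__(self):
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate feature ids in ranked list")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.ids)

    def __len__(self) -> int:
        return len(self.ids)


def rank_features(
    table: DEResultTable,
    include_tes: bool = False,
    p_floor: float = P_FLOOR,
) -> RankedList:
    """Rank a DE table by -log10(p) * sign(log2fc), descending.

    TE subfamilies are excluded by default so the comparison covers canonical
    genes only. Ties (including all-zero scores) break lexicographically by
    feature id for cross-platform determinism.
    """
    df = table.data if include_tes else table.genes
    if len(df) < 2:
        raise TeescapeError("ranking needs at least 2 features")
    p = np.clip(df["pvalue"].to_numpy(float), p_floor, None)
    score = -np.log10(p) * np.sign(df["log2fc"].to_numpy(float))
    order = sorted(range(len(df)), key=lambda i: (-score[i], df["feature_id"].iat[i]))
    return RankedList(
        ids=tuple(df["feature_id"].iat[i] for i in order),
        scores=score[list(order)],
        condition_label=table.condition_label,
    )


@dataclass
class RRHOMap:
    """Signed -log10 hypergeometric overlap p-values over a threshold grid.

    ``values[i, j]`` scores the overlap of the top ``thresholds[i]`` of
    list 1 with the top ``thresholds[j]`` of list 2; ``counts`` holds the
    raw overlap sizes.
    """

    step: int
    thresholds: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    n_features: int
    labels: tuple[str, str] = ("list1", "list2")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.thresholds, name="rank1"),
            columns=pd.Index(self.thresholds, name="rank2"),
        )


def _signed_log_p(counts: np.ndarray, i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    """Signed -log10 hypergeometric tail for overlap counts k at draws i,
    successes j, population n. Enrichment (k above expectation i*j/n) is
    positive via the upper tail; depletion negative via the lower tail."""
    expected = np.outer(i, j) / n
    jj = np.broadcast_to(j[None, :], counts.shape)
    ii = np.broadcast_to(i[:, None], counts.shape)
    p_enrich = stats.hypergeom.sf(counts - 1, n, jj, ii)
    p_deplete = stats.hypergeom.cdf(counts, n, jj, ii)
    enrich = counts > expected
    p = np.where(enrich, p_enrich, p_deplete)
    p = np.clip(p, P_FLOOR, 1.0)
    return np.where(enrich, -np.log10(p), np.log10(p))


def rrho_map(list1: RankedList, list2: RankedList, step: int | None = None) -> RRHOMap:
    """Compute the RRHO map of two ranked lists over a shared universe.

    ``step`` defaults to max(1, N // 100) (about a 100 x 100 grid).
    """
    if list1.universe != list2.universe:
        diff = len(list1.universe.symmetric_difference(list2.universe))
        raise UniverseMismatchError(
            f"ranked lists differ in {diff} features; identical universes required"
        )
    n = len(list1)
    if step is None:
        step = max(1, n // 100)
    if not (1 <= step <= n):
        raise ValueError(f"step must lie in [1, {n}], got {step}")

    thresholds = np.arange(step, n + 1, step)
    if thresholds[-1] != n:
        thresholds = np.append(thresholds, n)

    # rank (0-based) of every feature in each list
    rank2 = {fid: r for r, fid in enumerate(list2.ids)}
    pos2 = np.array([rank2[fid] for fid in list1.ids])
    # cumulative 2D counts: C[a, b] = |top-thresholds[a] of 1 ∩ top-thresholds[b] of 2|
    edges = np.concatenate(([0], thresholds))
    hist, _, _ = np.histogram2d(
        np.arange(n), pos2, bins=[edges, edges]
    )
    counts = hist.cumsum(axis=0).cumsum(axis=1)

    values = _signed_log_p(counts, thresholds, thresholds, n)
    return RRHOMap(
        step=step,
        thresholds=thresholds,
        values=values,
        counts=counts.astype(int),
        n_features=n,
        labels=(list1.condition_label, list2.condition_label),
    )


@dataclass(frozen=True)
class RRHOSummary:
    max_coupregulation: float
    max_codownregulation: float
    concordance: float
    bonferroni_alpha_neglog10: float


def rrho_summary(rmap: RRHOMap, alpha: float = 0.05) -> RRHOSummary:
    """Summarize an RRHO map.

    Concordant quadrants are the cells with both thresholds in the same half
    of the ranking (coupregulation at small ranks, codownregulation at large
    ranks). In a top-list overlap map, evidence of anti-regulation (up in one
    condition, down in the other) appears as overlap *depletion* in the mixed
    quadrants: enrichment of top-i of list 1 within the bottom-m of list 2
    has exactly the tail probability of depletion of top-i within the
    top-(N-m), with opposite sign. Discordance evidence is therefore the
    negated map value over the mixed quadrants, and the concordance score is
    mean(concordant values) - mean(discordance evidence). Positive means the
    two conditions agree transcriptome-wide; negative means they oppose.
    The Bonferroni level reported is -log10(alpha / #cells), the map-wide
    significance bar for any single cell.
    """
    t = rmap.thresholds
    half = rmap.n_features / 2
    top = t <= half
    bottom = ~top
    v = rmap.values
    ll = v[np.ix_(top, top)]  # coupregulation
    ur = v[np.ix_(bottom, bottom)]  # codownregulation
    lr = -v[np.ix_(top, bottom)]  # up in 1, down in 2
    ul = -v[np.ix_(bottom, top)]  # down in 1, up in 2
    concordant = np.concatenate([ll.ravel(), ur.ravel()])
    discordant = np.concatenate([lr.ravel(), ul.ravel()])
    concordance = float(concordant.mean() - discordant.mean()) if discordant.size else float(concordant.mean())
    return RRHOSummary(
        max_coupregulation=float(ll.max()) if ll.size else float("nan"),
        max_codownregulation=float(ur.max()) if ur.size else float("nan"),
        concordance=concordance,
        bonferroni_alpha_neglog10=float(-np.log10(alpha / v.size)),
    )
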