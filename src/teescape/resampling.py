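"""Resampling empirical-null percentile for subset enrichment.

The question: is the observed subset of a gene pool (e.g. the DETE-proximal
genes that are also DEGs) more enriched for a target set than equally sized
random subsets of the same pool? The observed ORA p-value is placed within
an empirical distribution of ORA p-values from ``n_subsets`` random draws;
the reported percentile uses the rank/(N+1) convention with ties counting
toward the rank (a value at or below the observed p increments the rank),
so one tied-or-smaller null among 100 gives 100 * 2/101 = 1.98.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core import ConfigError, GeneSetCollection, TeescapeError
from .enrichment import ora_test


@dataclass(frozen=True)
class ResamplingConfig:
    n_subsets: int = 100
    subset_size: int | None = None  # defaults to |observed subset|
    target_set_name: str = ""
    rng_seed: int = 0
    percentile_convention: str = "rank_over_n_plus_1"  # or "rank_over_n"

    def __post_init__(self):
        if self.n_subsets < 1:
            raise ConfigError("n_subsets must be positive")
        if self.percentile_convention not in ("rank_over_n_plus_1", "rank_over_n"):
            raise ConfigError("unknown percentile convention")


def empirical_percentile(
    observed_p: float,
    null_ps: Sequence[float],
    convention: str = "rank_over_n_plus_1",
) -> tuple[float, int]:
    """Percentile of an observed p within an empirical null.

    rank = |{x in null : x <= observed}| + 1 (ties count); percentile is
    100 * rank / (N + 1) by default, or 100 * rank / N under the plain-rank
    convention. Small percentiles mean the observed p is extreme (small)
    relative to the null.
    """
    null = np.asarray(null_ps, dtype=float)
    if null.size == 0:
        raise TeescapeError("empty null distribution")
    rank = int(np.sum(null <= observed_p)) + 1
    denom = null.size + 1 if convention == "rank_over_n_plus_1" else null.size
    return 100.0 * rank / denom, rank


@dataclass
class ResamplingResult:
    observed_p: float
    null_ps: np.ndarray
    percentile: float
    rank: int
    subset_size: int
    n_subsets: int
    target_set_name: str


def _vectorized_ora_p(
    k: np.ndarray, universe_size: int, category_size: int, draws: int
) -> np.ndarray:
    return stats.hypergeom.sf(k - 1, universe_size, category_size, draws)


def resample_enrichment(
    pool: Sequence[str] | frozenset[str],
    observed_subset: Sequence[str] | frozenset[str],
    target_set: Sequence[str] | frozenset[str],
    universe: Sequence[str] | frozenset[str],
    cfg: ResamplingConfig | None = None,
) -> ResamplingResult:
    """Empirical-null percentile of the observed subset's target enrichment.

    Null subsets are drawn uniformly without replacement from ``pool``
    (independently across subsets, so a gene may recur between draws), each
    of the observed subset's size unless overridden, and scored by the same
    upper-tail hypergeometric ORA against the same universe.
    """
    cfg = cfg or ResamplingConfig()
    pool_ids = sorted(set(pool))
    obs = frozenset(observed_subset)
    uni = frozenset(universe)
    if not obs <= set(pool_ids):
        raise ConfigError("observed subset must be contained in the pool")
    if not set(pool_ids) <= uni:
        raise ConfigError("pool must be contained in the universe")
    size = cfg.subset_size if cfg.subset_size is not None else len(obs)
    if size < 1 or size > len(pool_ids):
        raise ConfigError(
            f"subset_size {size} outside [1, |pool|={len(pool_ids)}]"
        )

    observed = ora_test(obs, target_set, uni)

    target_in_uni = frozenset(target_set) & uni
    member = np.array([g in target_in_uni for g in pool_ids])
    rng = np.random.default_rng(cfg.rng_seed)
    ks = np.empty(cfg.n_subsets, dtype=int)
    for i in range(cfg.n_subsets):
        idx = rng.choice(len(pool_ids), size=size, replace=False)
        ks[i] = int(member[idx].sum())
    null_ps = _vectorized_ora_p(ks, len(uni), len(target_in_uni), size)
    null_ps = np.minimum(null_ps, 1.0)

    percentile, rank = empirical_percentile(
        observed.p, null_ps, cfg.percentile_convention
    )
    return ResamplingResult(
        observed_p=observed.p,
        null_ps=null_ps,
        percentile=percentile,
        rank=rank,
        subset_size=size,
        n_subsets=cfg.n_subsets,
        target_set_name=cfg.target_set_name,
    )


def summarize_resampling(result: ResamplingResult) -> dict:
    """One report row: observed p, percentile, and null quantiles."""
    q = np.quantile(result.null_ps, [0.0, 0.05, 0.5, 0.95, 1.0])
    return {
        "target_set": result.target_set_name,
        "observed_p": result.observed_p,
        "percentile": result.percentile,
        "rank": result.rank,
        "n_subsets": result.n_subsets,
        "subset_size": result.subset_size,
        "null_min": float(q[0]),
        "null_q05": float(q[1]),
        "null_median": float(q[2]),
        "null_q95": float(q[3]),
        "null_max": float(q[4]),
    }
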