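"""Independent brute-force reference implementations used only by tests.

Each oracle is written against the mathematical definition (enumeration,
quadratic scans, triple loops) and deliberately shares no code with the
package's implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def hypergeom_upper_tail_enumerated(k: int, universe: int, successes: int, draws: int) -> float:
    """P[overlap >= k] by enumerating every size-``draws`` subset of the
    universe. Feasible for universe <= 12."""
    items = list(range(universe))
    hits = set(items[:successes])
    total = 0
    ge = 0
    for subset in itertools.combinations(items, draws):
        total += 1
        if len(hits.intersection(subset)) >= k:
            ge += 1
    return ge / total


def hypergeom_lower_tail_enumerated(k: int, universe: int, successes: int, draws: int) -> float:
    """P[overlap <= k] by exhaustive enumeration."""
    items = list(range(universe))
    hits = set(items[:successes])
    total = 0
    le = 0
    for subset in itertools.combinations(items, draws):
        total += 1
        if len(hits.intersection(subset)) <= k:
            le += 1
    return le / total


def bh_quadratic(pvalues) -> np.ndarray:
    """Benjamini-Hochberg by the definition: adj_i = min over j with
    p_j >= p_i of p_j * n / rank(p_j), capped at 1. O(n^2)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    candidates = p * n / ranks
    out = np.empty(n)
    for i in range(n):
        out[i] = min(1.0, candidates[p >= p[i]].min())
    return out


def running_sum_es_bruteforce(scores, member_flags, weight_exponent=1.0) -> float:
    """Walk the weighted KS running sum position by position and return the
    signed maximal deviation."""
    w = np.abs(np.asarray(scores, dtype=float)) ** weight_exponent
    member = np.asarray(member_flags, dtype=bool)
    n = member.size
    m = int(member.sum())
    wsum = w[member].sum()
    if wsum <= 0:
        w = np.ones(n)
        wsum = float(m)
    if n == m:
        return 1.0
    running = 0.0
    best = 0.0
    for i in range(n):
        if member[i]:
            running += w[i] / wsum
        else:
            running -= 1.0 / (n - m)
        if abs(running) > abs(best):
            best = running
    return best


def proximal_genes_bruteforce(dete_loci, contacts, genes, max_distance, anchor_rule, cell_type):
    """Triple loop over (DETE locus, contact, gene); returns
    {gene_id: best distance}."""

    def gap(a, b):
        if a.chrom != b.chrom:
            return math.inf
        if a.start < b.end and b.start < a.end:
            return 0
        return b.start - a.end if a.end <= b.start else a.start - b.end

    best: dict[str, float] = {}
    for c in contacts:
        if cell_type is not None and c.cell_type and c.cell_type != cell_type:
            continue
        for _, locus in dete_loci:
            for anchor, other in ((c.anchor_a, c.anchor_b), (c.anchor_b, c.anchor_a)):
                if gap(locus, anchor) == 0:
                    targets = [other] if anchor_rule == "distal_anchor" else [c.anchor_a, c.anchor_b]
                    for t in targets:
                        for g in genes:
                            d = gap(t, g.body)
                            if d <= max_distance:
                                best[g.gene_id] = min(best.get(g.gene_id, math.inf), d)
    return best


def annotate_bruteforce(loci, genes, enhancers, promoter_window):
    """All-pairs precedence labeling of de-duplicated loci."""

    def overlaps(chrom, s, e, iv):
        return chrom == iv.chrom and s < iv.end and iv.start < e

    out = {}
    for te_id, iv in loci:
        key = (iv.chrom, iv.start, iv.end)
        if key in out:
            continue
        label = "intergenic"
        for g in genes:
            ps = max(0, g.tss - promoter_window)
            if iv.chrom == g.body.chrom and iv.start < g.tss + promoter_window and ps < iv.end:
                label = "promoter"
                break
        if label == "intergenic":
            for g in genes:
                if overlaps(iv.chrom, iv.start, iv.end, g.body):
                    label = "intron"
                    break
        if label == "intergenic":
            for e in enhancers:
                if overlaps(iv.chrom, iv.start, iv.end, e):
                    label = "distal_enhancer"
                    break
        out[key] = label
    return out
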