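"""Hi-C contact-anchored proximity between DETE loci and genes.

A contact pair is DETE-anchored when any locus of a (FDR-surviving) DETE
subfamily overlaps one of its anchors; genes whose body (or TSS) lies within
``max_distance`` bp of the *other* anchor are DETE-proximal under the
default distal-anchor rule, reflecting a cis-regulatory looping reading of
the contact. Distances are boundary gaps, 0 when overlapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import ContactPair, GeneModel, GenomicInterval, TeescapeError, interval_distance
from .enrichment import bh_fdr
from .io import DEResultTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProximityConfig:
    max_distance: int = 20_000
    cell_type: str | None = "excitatory"
    dete_fdr: float = 0.1
    anchor_rule: str = "distal_anchor"  # or "either_anchor"
    joint_bh: bool = False  # BH over genes+TEs jointly instead of TEs only
    use_tss: bool = False  # measure to gene TSS instead of gene body

    def __post_init__(self):
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        if self.anchor_rule not in ("distal_anchor", "either_anchor"):
            raise ValueError("anchor_rule must be distal_anchor or either_anchor")
        if not (0 < self.dete_fdr < 1):
            raise ValueError("dete_fdr must lie in (0, 1)")


def select_hic_detes(
    de_table: DEResultTable, cfg: ProximityConfig | None = None
) -> list[str]:
    """TE subfamilies surviving BH FDR < cfg.dete_fdr.

    The adjustment is recomputed here over the table's TE rows (or over all
    rows when ``joint_bh``), independent of any padj column the table came
    with.
    """
    cfg = cfg or ProximityConfig()
    tes = de_table.tes
    if len(tes) == 0:
        raise TeescapeError(f"{de_table.condition_label}: no TE rows")
    scope = de_table.data if cfg.joint_bh else tes
    adj = bh_fdr(scope["pvalue"].to_numpy())
    adj_by_id = dict(zip(scope["feature_id"], adj))
    return [
        fid for fid in tes["feature_id"] if adj_by_id[fid] < cfg.dete_fdr
    ]


@dataclass
class SupportingContact:
    dete_id: str
    contact: ContactPair
    distance: float
    gene_anchor: GenomicInterval


@dataclass
class ProximityResult:
    """Genes found in DETE-anchored contacts within the distance cutoff."""

    dete_proximal_genes: set[str]
    supporting: dict[str, list[SupportingContact]]
    config: ProximityConfig
    n_contacts_used: int

    def best_distance(self, gene_id: str) -> float:
        return min(s.distance for s in self.supporting[gene_id])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid in sorted(self.dete_proximal_genes):
            best = min(self.supporting[gid], key=lambda s: s.distance)
            a, b = best.contact.anchor_a, best.contact.anchor_b
            rows.append(
                {
                    "gene_id": gid,
                    "best_distance": best.distance,
                    "dete_id": best.dete_id,
                    "n_supporting": len(self.supporting[gid]),
                    "contact": f"{a.chrom}:{a.start}-{a.end}|{b.chrom}:{b.start}-{b.end}",
                }
            )
        return pd.DataFrame(
            rows,
            columns=["gene_id", "best_distance", "dete_id", "n_supporting", "contact"],
        )


def _gene_query_interval(g: GeneModel, use_tss: bool) -> GenomicInterval:
    if not use_tss:
        return g.body
    # TSS as a 1-bp interval (clamped into the chromosome)
    start = max(0, g.tss if g.tss < g.body.end else g.tss - 1)
    return GenomicInterval(g.body.chrom, start, start + 1, g.body.strand)


def find_proximal_genes(
    dete_loci: Sequence[tuple[str, GenomicInterval]],
    contacts: Sequence[ContactPair],
    genes: Sequence[GeneModel],
    cfg: ProximityConfig | None = None,
) -> ProximityResult:
    """Find genes within ``max_distance`` of DETE-anchored contacts.

    Under ``distal_anchor`` the gene is sought near the anchor *not*
    containing the DETE locus; under ``either_anchor`` near both. When the
    config names a cell type and the contacts carry labels, non-matching
    pairs are dropped first. A zero chromosome-name overlap between contacts
    and genes is a hard error (it signals mismatched naming schemes, not a
    biological absence of proximity).
    """
    cfg = cfg or ProximityConfig()
    if cfg.cell_type is not None and any(c.cell_type for c in contacts):
        contacts = [c for c in contacts if c.cell_type == cfg.cell_type]

    gene_chroms = {g.body.chrom for g in genes}
    contact_chroms = {c.anchor_a.chrom for c in contacts} | {
        c.anchor_b.chrom for c in contacts
    }
    if contacts and gene_chroms.isdisjoint(contact_chroms):
        raise TeescapeError(
            "no chromosome names shared between contacts and gene models: "
            f"genes use e.g. {sorted(gene_chroms)[:3]}, contacts "
            f"{sorted(contact_chroms)[:3]}"
        )

    # DETE locus lookup trees
    locus_trees: dict[str, IntervalTree] = {}
    for te_id, iv in dete_loci:
        locus_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, te_id)

    # gene lookup trees over query intervals expanded by max_distance
    gene_trees: dict[str, IntervalTree] = {}
    query_iv: dict[str, GenomicInterval] = {}
    for g in genes:
        iv = _gene_query_interval(g, cfg.use_tss)
        query_iv[g.gene_id] = iv
        gene_trees.setdefault(iv.chrom, IntervalTree()).addi(
            max(0, iv.start - cfg.max_distance), iv.end + cfg.max_distance, g.gene_id
        )

    def _detes_on(anchor: GenomicInterval) -> set[str]:
        tree = locus_trees.get(anchor.chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(anchor.start, anchor.end)}

    def _genes_near(anchor: GenomicInterval) -> list[tuple[str, float]]:
        tree = gene_trees.get(anchor.chrom)
        if tree is None:
            return []
        out = []
        for hit in tree.overlap(anchor.start, anchor.end):
            gid = hit.data
            d = interval_distance(anchor, query_iv[gid])
            if d <= cfg.max_distance:
                out.append((gid, d))
        return out

    supporting: dict[str, list[SupportingContact]] = {}
    for c in contacts:
        hits_a = _detes_on(c.anchor_a)
        hits_b = _detes_on(c.anchor_b)
        if not hits_a and not hits_b:
            continue
        # (dete ids, anchor to search for genes)
        searches: list[tuple[set[str], GenomicInterval]] = []
        if cfg.anchor_rule == "distal_anchor":
            if hits_a:
                searches.append((hits_a, c.anchor_b))
            if hits_b:
                searches.append((hits_b, c.anchor_a))
        else:
            both = hits_a | hits_b
            searches.append((both, c.anchor_a))
            searches.append((both, c.anchor_b))
        for dete_ids, anchor in searches:
            for gid, d in _genes_near(anchor):
                for te_id in sorted(dete_ids):
                    supporting.setdefault(gid, []).append(
                        SupportingContact(te_id, c, d, anchor)
                    )
    return ProximityResult(
        dete_proximal_genes=set(supporting),
        supporting=supporting,
        config=cfg,
        n_contacts_used=len(contacts),
    )


@dataclass
class DEGIntersection:
    degs: pd.DataFrame  # gene_id, direction, log2fc, pvalue, best_distance
    fraction_down: float | None

    def counts(self) -> dict[str, int]:
        return {
            "proximal_degs": len(self.degs),
            "up": int((self.degs["direction"] == "up").sum()),
            "down": int((self.degs["direction"] == "down").sum()),
        }


def intersect_with_degs(
    result: ProximityResult, degs: pd.DataFrame
) -> DEGIntersection:
    """Intersect DETE-proximal genes with a called DEG table (from
    :func:`teescape.dete.call_significant`); fraction_down is
    down / (up + down), None when no directed DEG is proximal."""
    sub = degs[degs["feature_id"].isin(result.dete_proximal_genes)].copy()
    sub = sub.rename(columns={"feature_id": "gene_id"})
    sub["best_distance"] = [result.best_distance(g) for g in sub["gene_id"]]
    directed = sub[sub["direction"].isin(["up", "down"])]
    n_up = int((directed["direction"] == "up").sum())
    n_down = int((directed["direction"] == "down").sum())
    frac = n_down / (n_up + n_down) if (n_up + n_down) else None
    cols = ["gene_id", "direction", "log2fc", "pvalue", "padj", "best_distance"]
    sub = sub[[c for c in cols if c in sub.columns]].sort_values("gene_id").reset_index(drop=True)
    return DEGIntersection(degs=sub, fraction_down=frac)
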