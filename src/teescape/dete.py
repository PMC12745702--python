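"""DETE/DEG calling, TE class attribution, genomic-feature annotation and
class-composition testing.

Significance defaults follow the study design this pipeline supports:
unadjusted P < 0.05 for the descriptive DEG/DETE sets, with an FDR-based
variant used by the Hi-C-facing stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import GeneModel, GenomicInterval, TEFeature, TeescapeError, parse_te_id
from .io import DEResultTable

logger = logging.getLogger(__name__)

CANONICAL_CLASSES = ("LTR", "non-LTR", "DNA")
CLASS_BUCKETS = CANONICAL_CLASSES + ("other",)
FEATURE_LABELS = ("promoter", "exon", "intron", "distal_enhancer", "intergenic")


@dataclass(frozen=True)
class SignificanceConfig:
    """Thresholds for calling DEGs/DETEs."""

    p_threshold: float = 0.05
    use_adjusted: bool = False
    fdr_threshold: float = 0.1

    def __post_init__(self):
        for name in ("p_threshold", "fdr_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class SignificantSets:
    """DEGs and DETEs called from one DE table.

    Each frame carries feature_id, base_mean, log2fc, pvalue, padj and a
    ``direction`` column ('up'|'down'|'zero'); rows with log2fc == 0 are
    direction-less and excluded from up/down counts but kept for audit.
    """

    condition_label: str
    degs: pd.DataFrame
    detes: pd.DataFrame
    n_zero_lfc: int

    @staticmethod
    def _directed(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["direction"] != "zero"]

    @property
    def deg_ids(self) -> list[str]:
        return self._directed(self.degs)["feature_id"].tolist()

    @property
    def dete_ids(self) -> list[str]:
        return self._directed(self.detes)["feature_id"].tolist()

    def counts(self) -> dict[str, int]:
        d, t = self._directed(self.degs), self._directed(self.detes)
        return {
            "degs": len(d),
            "degs_up": int((d["direction"] == "up").sum()),
            "degs_down": int((d["direction"] == "down").sum()),
            "detes": len(t),
            "detes_up": int((t["direction"] == "up").sum()),
            "detes_down": int((t["direction"] == "down").sum()),
        }


def call_significant(
    table: DEResultTable, cfg: SignificanceConfig | None = None
) -> SignificantSets:
    """Partition a DE table's significant rows into DEGs and DETEs.

    Significance is pvalue < p_threshold, or padj < fdr_threshold when
    ``cfg.use_adjusted`` (rows lacking padj are then never significant).
    """
    cfg = cfg or SignificanceConfig()
    if len(table) == 0:
        raise TeescapeError("empty DE table")
    df = table.data
    if cfg.use_adjusted:
        mask = df["padj"].notna() & (df["padj"] < cfg.fdr_threshold)
    else:
        mask = df["pvalue"] < cfg.p_threshold
    sig = df[mask].copy()
    sig["direction"] = np.where(
        sig["log2fc"] > 0, "up", np.where(sig["log2fc"] < 0, "down", "zero")
    )
    n_zero = int((sig["direction"] == "zero").sum())
    if n_zero:
        logger.info(
            "%s: %d significant rows with log2fc == 0 excluded from direction labels",
            table.condition_label,
            n_zero,
        )
    return SignificantSets(
        condition_label=table.condition_label,
        degs=sig[sig["feature_kind"] == "gene"].reset_index(drop=True),
        detes=sig[sig["feature_kind"] == "te"].reset_index(drop=True),
        n_zero_lfc=n_zero,
    )


def classify_te_class(te_class_raw: str) -> str:
    """Collapse a RepeatMasker class label into LTR / non-LTR / DNA / other.

    LINE and SINE aggregate into non-LTR; trailing '?' and any '/subclass'
    qualifier are ignored; everything else (Satellite, Simple_repeat, RC,
    Retroposon, Unknown, ...) is 'other'.
    """
    base = te_class_raw.strip().split("/")[0].rstrip("?")
    if base in ("LINE", "SINE"):
        return "non-LTR"
    if base == "LTR":
        return "LTR"
    if base == "DNA":
        return "DNA"
    return "other"


@dataclass
class ClassBreakdown:
    """DETE counts per collapsed TE class, overall and split by direction."""

    counts: dict[str, int]
    by_direction: dict[str, dict[str, int]]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def shares(self, canonical_only: bool = True) -> dict[str, float | None]:
        """Class proportions; over the three canonical classes by default
        (the 'other' bucket excluded from the denominator). None when the
        denominator is zero."""
        buckets = CANONICAL_CLASSES if canonical_only else CLASS_BUCKETS
        denom = sum(self.counts.get(b, 0) for b in buckets)
        if denom == 0:
            return {b: None for b in buckets}
        return {b: self.counts.get(b, 0) / denom for b in buckets}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        sc, sa = self.shares(True), self.shares(False)
        for b in CLASS_BUCKETS:
            rows.append(
                {
                    "te_class": b,
                    "count": self.counts.get(b, 0),
                    "up": self.by_direction["up"].get(b, 0),
                    "down": self.by_direction["down"].get(b, 0),
                    "share_canonical": sc.get(b),
                    "share_all": sa[b],
                }
            )
        return pd.DataFrame(rows)


def class_breakdown(
    detes: pd.DataFrame,
    te_annotation: Sequence[TEFeature] | None = None,
    te_id_delimiter: str = ":",
) -> ClassBreakdown:
    """Attribute each called DETE to a collapsed TE class.

    Classes come from the annotation when provided; ids absent from it fall
    back to the class encoded in the name:family:class triplet, and ids that
    resolve neither way are counted as 'other' with a warning.
    """
    lookup: dict[str, str] = {}
    if te_annotation is not None:
        lookup = {te.te_id: classify_te_class(te.te_class_raw) for te in te_annotation}
    counts = {b: 0 for b in CLASS_BUCKETS}
    by_dir = {"up": {b: 0 for b in CLASS_BUCKETS}, "down": {b: 0 for b in CLASS_BUCKETS}}
    for _, row in detes.iterrows():
        fid = row["feature_id"]
        if fid in lookup:
            klass = lookup[fid]
        else:
            try:
                _, _, raw = parse_te_id(fid, te_id_delimiter)
                klass = classify_te_class(raw)
            except ValueError:
                logger.warning("DETE id %r unresolvable; counted as other", fid)
                klass = "other"
        counts[klass] += 1
        direction = row.get("direction")
        if direction in ("up", "down"):
            by_dir[direction][klass] += 1
    return ClassBreakdown(counts=counts, by_direction=by_dir)


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float
    cells: tuple[str, ...]


def class_composition_test(
    observed: ClassBreakdown, reference: ClassBreakdown
) -> Chi2Result:
    """Pearson chi-square goodness-of-fit of an observed DETE class
    composition against the proportions of a reference condition.

    Cells with expected count < 1 are pooled into 'other' (logged); the
    reference must have a nonzero total over the cells used.
    """
    ref_total = reference.total
    if ref_total == 0:
        raise TeescapeError("reference breakdown is all-zero; test undefined")
    obs_total = observed.total
    if obs_total == 0:
        raise TeescapeError("observed breakdown is all-zero; test undefined")

    obs = {b: observed.counts.get(b, 0) for b in CLASS_BUCKETS}
    ref_prop = {b: reference.counts.get(b, 0) / ref_total for b in CLASS_BUCKETS}

    # Pool cells whose expected count under the reference proportions is < 1
    # (including zero-probability cells) into 'other'.
    pooled_obs: dict[str, int] = {}
    pooled_into_other = 0
    ref_other = ref_prop["other"]
    for b in CANONICAL_CLASSES:
        expected = ref_prop[b] * obs_total
        if expected < 1:
            logger.info("pooling class %s (expected %.3f < 1) into other", b, expected)
            pooled_into_other += obs[b]
            ref_other += ref_prop[b]
        else:
            pooled_obs[b] = obs[b]
    other_count = obs["other"] + pooled_into_other
    if ref_other * obs_total >= 1 or other_count > 0:
        if ref_other == 0 and other_count > 0:
            raise TeescapeError(
                "observed counts in classes with zero reference probability; "
                "reference proportions cannot serve as expected values"
            )
        if ref_other > 0:
            pooled_obs["other"] = other_count
    cells = tuple(pooled_obs)
    f_obs = np.array([pooled_obs[c] for c in cells], dtype=float)
    probs = np.array([ref_prop[c] if c != "other" else ref_other for c in cells])
    probs = probs / probs.sum()
    f_exp = probs * f_obs.sum()
    chi2, p = stats.chisquare(f_obs, f_exp)
    return Chi2Result(chi2=float(chi2), df=len(cells) - 1, p=float(p), cells=cells)


@dataclass
class FeatureBreakdown:
    """Counts of de-duplicated DETE loci per genomic feature label."""

    counts: dict[str, int]
    assignments: list[tuple[str, GenomicInterval, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        total = self.total
        return pd.DataFrame(
            [
                {
                    "feature": lab,
                    "count": self.counts.get(lab, 0),
                    "share": (self.counts.get(lab, 0) / total) if total else None,
                }
                for lab in FEATURE_LABELS
            ]
        )


def _build_tree(intervals: Iterable[tuple[GenomicInterval, object]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv, payload in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)
    return trees


def annotate_features(
    dete_loci: Sequence[tuple[str, GenomicInterval]],
    genes: Sequence[GeneModel],
    enhancers: Sequence[GenomicInterval] = (),
    promoter_window: int = 1000,
    exons: Sequence[GenomicInterval] | None = None,
) -> FeatureBreakdown:
    """Assign each unique DETE locus exactly one genomic-feature label.

    Precedence: promoter > exon > intron > distal_enhancer > intergenic.
    Promoters are [tss - promoter_window, tss + promoter_window); gene-body
    overlap outside promoter and exons counts as intron (when no exon models
    are supplied, any non-promoter body overlap is intronic). Identical
    intervals are de-duplicated before counting, so a subfamily's repeated
    locus contributes once.
    """
    promoter_ivs = []
    for g in genes:
        p_start = max(0, g.tss - promoter_window)
        p_end = g.tss + promoter_window
        if p_end > p_start:
            promoter_ivs.append((GenomicInterval(g.body.chrom, p_start, p_end), g.gene_id))
    prom_trees = _build_tree(promoter_ivs)
    body_trees = _build_tree((g.body, g.gene_id) for g in genes)
    exon_trees = _build_tree((e, None) for e in exons) if exons else {}
    enh_trees = _build_tree((e, None) for e in enhancers)

    seen: set[tuple[str, int, int]] = set()
    counts = {lab: 0 for lab in FEATURE_LABELS}
    assignments: list[tuple[str, GenomicInterval, str]] = []
    for te_id, iv in dete_loci:
        key = iv.as_key()
        if key in seen:
            continue
        seen.add(key)
        chrom, s, e = iv.chrom, iv.start, iv.end
        if chrom in prom_trees and prom_trees[chrom].overlap(s, e):
            label = "promoter"
        elif chrom in exon_trees and exon_trees[chrom].overlap(s, e):
            label = "exon"
        elif chrom in body_trees and body_trees[chrom].overlap(s, e):
            label = "intron"
        elif chrom in enh_trees and enh_trees[chrom].overlap(s, e):
            label = "distal_enhancer"
        else:
            label = "intergenic"
        counts[label] += 1
        assignments.append((te_id, iv, label))
    return FeatureBreakdown(counts=counts, assignments=assignments)


def dete_loci_from_annotation(
    dete_ids: Iterable[str], te_annotation: Sequence[TEFeature]
) -> list[tuple[str, GenomicInterval]]:
    """Resolve called DETE ids to their genomic loci; subfamilies with no
    locus are dropped with a warning (they cannot enter locus-based stages)."""
    by_id = {te.te_id: te for te in te_annotation}
    out: list[tuple[str, GenomicInterval]] = []
    for fid in dete_ids:
        te = by_id.get(fid)
        if te is None or not te.loci:
            logger.warning("DETE %s has no resolved genomic locus; skipped", fid)
            continue
        for iv in te.loci:
            out.append((fid, iv))
    return out
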