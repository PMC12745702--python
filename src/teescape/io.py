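"""Readers and writers for the pipeline's standard formats.

Formats handled: tab-separated DESeq2-style DE result tables (genes + TE
subfamilies quantified TEtranscripts-style), BED6 / GTF annotations, BEDPE
contact pairs (two optional trailing columns: cell_type, support), and GMT
gene sets. GTF coordinates (1-based, closed) are converted to the internal
0-based half-open convention on read and back on write.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ContactPair,
    EmptyInputError,
    FormatError,
    GeneModel,
    GeneSetCollection,
    GenomicInterval,
    MalformedRecordError,
    TEFeature,
    is_te_feature_id,
)

logger = logging.getLogger(__name__)

#: Default mapping from internal column names to on-disk header names
#: (TEtranscripts + DESeq2 output dialect).
DEFAULT_DE_COLUMNS: Mapping[str, str] = {
    "base_mean": "baseMean",
    "log2fc": "log2FoldChange",
    "pvalue": "pvalue",
    "padj": "padj",
}

DE_TABLE_COLUMNS = ("feature_id", "feature_kind", "base_mean", "log2fc", "pvalue", "padj")


@dataclass
class DEResultTable:
    """Differential-expression results for one condition vs a shared reference.

    ``data`` holds one row per tested feature with columns
    feature_id, feature_kind ('gene'|'te'), base_mean, log2fc, pvalue, padj.
    padj may be NaN; pvalue is present for every retained row.
    """

    condition_label: str
    data: pd.DataFrame
    reference_label: str = "GFP"

    def __post_init__(self):
        missing = [c for c in DE_TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"DE table missing columns: {missing}")
        if self.data["feature_id"].duplicated().any():
            dups = self.data.loc[self.data["feature_id"].duplicated(), "feature_id"]
            raise FormatError(
                f"duplicate feature ids in {self.condition_label}: "
                f"{sorted(set(dups))[:5]}"
            )
        if self.data["pvalue"].isna().any():
            raise FormatError("retained rows must all carry a pvalue")
        bad_p = self.data[(self.data["pvalue"] <= 0) | (self.data["pvalue"] > 1)]
        if len(bad_p):
            raise FormatError(
                f"pvalues outside (0, 1]: {bad_p['feature_id'].tolist()[:5]}"
            )
        self.data = self.data.reset_index(drop=True)

    @property
    def genes(self) -> pd.DataFrame:
        return self.data[self.data["feature_kind"] == "gene"]

    @property
    def tes(self) -> pd.DataFrame:
        return self.data[self.data["feature_kind"] == "te"]

    def __len__(self) -> int:
        return len(self.data)


def read_de_table(
    path: str | Path,
    condition_label: str,
    reference_label: str = "GFP",
    column_map: Mapping[str, str] | None = None,
    id_column: str | None = None,
    te_id_delimiter: str = ":",
) -> DEResultTable:
    """Read a tab-separated DESeq2-style result table.

    Rows are classified gene vs te by the name:family:class triplet pattern
    of the feature id. Rows with a missing pvalue (e.g. DESeq2 independent
    filtering) are dropped and the count logged.
    """
    path = Path(path)
    cols = dict(DEFAULT_DE_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(
        path, sep="\t", na_values=["NA", "NaN", ""], float_precision="round_trip"
    )
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: no data rows")
    if id_column is None:
        id_column = df.columns[0]
    for internal, ondisk in (("log2fc", cols["log2fc"]), ("pvalue", cols["pvalue"])):
        if ondisk not in df.columns:
            raise FormatError(f"{path}: mandatory column {ondisk!r} absent")
    if id_column not in df.columns:
        raise FormatError(f"{path}: feature id column {id_column!r} absent")

    out = pd.DataFrame({"feature_id": df[id_column].astype(str)})
    out["feature_kind"] = [
        "te" if is_te_feature_id(f, te_id_delimiter) else "gene"
        for f in out["feature_id"]
    ]
    out["base_mean"] = (
        pd.to_numeric(df[cols["base_mean"]], errors="coerce")
        if cols["base_mean"] in df.columns
        else np.nan
    )
    out["log2fc"] = pd.to_numeric(df[cols["log2fc"]], errors="coerce")
    out["pvalue"] = pd.to_numeric(df[cols["pvalue"]], errors="coerce")
    out["padj"] = (
        pd.to_numeric(df[cols["padj"]], errors="coerce")
        if cols["padj"] in df.columns
        else np.nan
    )

    n_missing = int(out["pvalue"].isna().sum())
    if n_missing:
        logger.info(
            "%s: dropped %d rows with missing pvalue (independent filtering)",
            path,
            n_missing,
        )
        out = out[out["pvalue"].notna()]
    if out.shape[0] == 0:
        raise EmptyInputError(f"{path}: no rows with a tested pvalue")
    return DEResultTable(
        condition_label=condition_label,
        reference_label=reference_label,
        data=out.reset_index(drop=True),
    )


def write_de_table(table: DEResultTable, path: str | Path) -> None:
    """Write a DE table in the dialect :func:`read_de_table` consumes."""
    df = table.data
    disk = pd.DataFrame(
        {
            "feature_id": df["feature_id"],
            "baseMean": df["base_mean"],
            "log2FoldChange": df["log2fc"],
            "pvalue": df["pvalue"],
            "padj": df["padj"],
        }
    )
    disk.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# BEDPE contact pairs


def read_contacts(
    path: str | Path, cell_type_filter: str | None = None
) -> list[ContactPair]:
    """Read BEDPE-like contact pairs.

    Columns: chromA startA endA chromB startB endB [cell_type] [support],
    0-based half-open. Anchors are normalized to canonical order; when
    ``cell_type_filter`` is given only matching pairs are retained.
    """
    pairs: list[ContactPair] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise MalformedRecordError(
                    f"expected >= 6 tab-separated fields, got {len(f)}", lineno
                )
            try:
                sa, ea, sb, eb = int(f[1]), int(f[2]), int(f[4]), int(f[5])
            except ValueError as exc:
                raise MalformedRecordError(str(exc), lineno) from exc
            if sa >= ea:
                raise MalformedRecordError(
                    f"anchor A start {sa} >= end {ea}", lineno
                )
            if sb >= eb:
                raise MalformedRecordError(
                    f"anchor B start {sb} >= end {eb}", lineno
                )
            cell_type = f[6] if len(f) > 6 else ""
            support = int(f[7]) if len(f) > 7 else 1
            if cell_type_filter is not None and cell_type != cell_type_filter:
                continue
            pairs.append(
                ContactPair(
                    anchor_a=GenomicInterval(f[0], sa, ea),
                    anchor_b=GenomicInterval(f[3], sb, eb),
                    cell_type=cell_type,
                    support=support,
                )
            )
    return pairs


def write_contacts(pairs: Sequence[ContactPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            a, b = p.anchor_a, p.anchor_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t{p.cell_type}\t{p.support}\n"
            )


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path, namespace: str = "symbol") -> GeneSetCollection:
    """Read GMT: one set per line, fields name, description, members...
    Duplicate members within a set are collapsed."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise MalformedRecordError(
                    "GMT line needs name, description and >= 1 member", lineno
                )
            members = frozenset(m for m in f[2:] if m)
            if not members:
                raise MalformedRecordError(f"set {f[0]!r} has no members", lineno)
            sets[f[0]] = members
    if not sets:
        raise EmptyInputError(f"{path}: no gene sets")
    return GeneSetCollection(sets=sets, namespace=namespace)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


# ---------------------------------------------------------------------------
# Gene models (GTF or BED)


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _gtf_to_interval(
    chrom: str, start_1based: str, end_closed: str, strand: str, lineno: int
) -> GenomicInterval:
    try:
        start = int(start_1based) - 1
        end = int(end_closed)
    except ValueError as exc:
        raise MalformedRecordError(str(exc), lineno) from exc
    if start < 0 or end <= start:
        raise MalformedRecordError(
            f"bad coordinates after GTF conversion: [{start}, {end})", lineno
        )
    if strand not in ("+", "-", "."):
        strand = "."
    return GenomicInterval(chrom, start, end, strand)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF (feature type 'gene') or BED6.

    TSS is the strand-aware 5' boundary of the gene body: start on '+'
    (and unstranded), end on '-'.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 9:
                    raise MalformedRecordError("GTF needs 9 fields", lineno)
                if f[2] != "gene":
                    continue
                body = _gtf_to_interval(f[0], f[3], f[4], f[6], lineno)
                attrs = _parse_gtf_attributes(f[8])
                gene_id = attrs.get("gene_id")
                if not gene_id:
                    raise MalformedRecordError("gene record lacks gene_id", lineno)
                symbol = attrs.get("gene_name", gene_id)
                tss = body.start if body.strand != "-" else body.end
                if gene_id in seen:
                    raise MalformedRecordError(f"duplicate gene_id {gene_id}", lineno)
                seen.add(gene_id)
                genes.append(GeneModel(gene_id, symbol, body, tss))
    else:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise MalformedRecordError("BED gene record needs >= 4 fields", lineno)
                try:
                    start, end = int(f[1]), int(f[2])
                except ValueError as exc:
                    raise MalformedRecordError(str(exc), lineno) from exc
                strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
                if start < 0 or end <= start:
                    raise MalformedRecordError(
                        f"bad BED coordinates [{start}, {end})", lineno
                    )
                body = GenomicInterval(f[0], start, end, strand)
                gene_id = f[3]
                if gene_id in seen:
                    raise MalformedRecordError(f"duplicate gene id {gene_id}", lineno)
                seen.add(gene_id)
                tss = body.start if strand != "-" else body.end
                genes.append(GeneModel(gene_id, gene_id, body, tss))
    if not genes:
        raise EmptyInputError(f"{path}: no gene records")
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF 'gene' records (coordinates converted back
    to 1-based closed)."""
    with open(path, "w") as fh:
        for g in genes:
            b = g.body
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_symbol}";'
            fh.write(
                f"{b.chrom}\tteescape\tgene\t{b.start + 1}\t{b.end}\t.\t"
                f"{b.strand if b.strand != '.' else '.'}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# TE locus annotation (BED with triplet names, or RepeatMasker-style GTF)


def read_te_annotation(
    path: str | Path, te_id_delimiter: str = ":"
) -> list[TEFeature]:
    """Read TE loci and group them into subfamilies.

    BED: column 4 carries the name:family:class triplet. GTF: attributes
    gene_id / family_id / class_id (TEtranscripts' RepeatMasker dialect).
    """
    path = Path(path)
    loci: dict[tuple[str, str, str], list[GenomicInterval]] = {}
    order: list[tuple[str, str, str]] = []

    def _add(key: tuple[str, str, str], iv: GenomicInterval) -> None:
        if key not in loci:
            loci[key] = []
            order.append(key)
        loci[key].append(iv)

    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 9:
                    raise MalformedRecordError("GTF needs 9 fields", lineno)
                iv = _gtf_to_interval(f[0], f[3], f[4], f[6], lineno)
                attrs = _parse_gtf_attributes(f[8])
                name = attrs.get("gene_id")
                family = attrs.get("family_id")
                klass = attrs.get("class_id")
                if not name:
                    raise MalformedRecordError("TE record lacks gene_id", lineno)
                if family is None or klass is None:
                    try:
                        name, family, klass = name.split(te_id_delimiter)
                    except ValueError as exc:
                        raise MalformedRecordError(
                            f"cannot resolve family/class for {name!r}", lineno
                        ) from exc
                _add((name, family, klass), iv)
    else:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise MalformedRecordError("BED TE record needs >= 4 fields", lineno)
                try:
                    start, end = int(f[1]), int(f[2])
                except ValueError as exc:
                    raise MalformedRecordError(str(exc), lineno) from exc
                if start < 0 or end <= start:
                    raise MalformedRecordError(
                        f"bad BED coordinates [{start}, {end})", lineno
                    )
                strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
                parts = f[3].split(te_id_delimiter)
                if len(parts) != 3 or not all(parts):
                    raise MalformedRecordError(
                        f"TE name {f[3]!r} is not a name/family/class triplet", lineno
                    )
                _add(tuple(parts), GenomicInterval(f[0], start, end, strand))
    if not loci:
        raise EmptyInputError(f"{path}: no TE records")
    return [
        TEFeature(te_name=k[0], te_family=k[1], te_class_raw=k[2], loci=tuple(loci[k]))
        for k in order
    ]


def write_te_annotation(features: Sequence[TEFeature], path: str | Path) -> None:
    """Write TE loci as BED6 with the triplet id in the name column."""
    with open(path, "w") as fh:
        for te in features:
            for iv in te.loci:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{te.te_id}\t0\t{iv.strand}\n"
                )


def write_intervals_bed(
    intervals: Sequence[GenomicInterval], path: str | Path, name_prefix: str = "iv"
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name_prefix}{i}\t0\t{iv.strand}\n"
            )


def read_intervals_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise MalformedRecordError("BED record needs >= 3 fields", lineno)
            start, end = int(f[1]), int(f[2])
            if start < 0 or end <= start:
                raise MalformedRecordError(
                    f"bad BED coordinates [{start}, {end})", lineno
                )
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            out.append(GenomicInterval(f[0], start, end, strand))
    return out


# ---------------------------------------------------------------------------
# Hashing / manifests


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
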