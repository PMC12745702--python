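"""Shared data model for the TE-escape analysis pipeline.

All genomic coordinates are 0-based, half-open (BED convention). Formats
using other conventions (GTF: 1-based, closed) are converted at the I/O
boundary so that interval arithmetic never mixes conventions.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

VALID_STRANDS = ("+", "-", ".")

#: TEtranscripts-style subfamily identifier: name:family:class.
TE_ID_PATTERN = re.compile(r"^[^:\s]+:[^:\s]+:[^:\s]+$")


class TeescapeError(Exception):
    """Base class for all package errors."""


class FormatError(TeescapeError):
    """A file did not conform to its declared format."""


class EmptyInputError(TeescapeError):
    """An input that must be non-empty was empty."""


class MalformedRecordError(FormatError):
    """A single record failed validation; carries its 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ConfigError(TeescapeError):
    """An invalid or infeasible configuration."""


class UniverseMismatchError(TeescapeError):
    """Two ranked lists do not share the same feature universe."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be non-negative, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def as_key(self) -> tuple[str, int, int]:
        """Strand-insensitive identity used to de-duplicate loci."""
        return (self.chrom, self.start, self.end)


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap in bp between two intervals: 0 when overlapping or abutting
    such that no base separates them; infinity across chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


@dataclass(frozen=True)
class GeneModel:
    """A canonical gene: body interval plus its transcription start site."""

    gene_id: str
    gene_symbol: str
    body: GenomicInterval
    tss: int

    def __post_init__(self):
        if not (self.body.start <= self.tss <= self.body.end):
            raise ValueError(
                f"tss {self.tss} outside gene body "
                f"[{self.body.start}, {self.body.end}] for {self.gene_id}"
            )


@dataclass(frozen=True)
class TEFeature:
    """A TE subfamily (RepeatMasker name/family/class) and its genomic loci.

    Subfamilies with no resolved locus are legal but are excluded from
    locus-based stages (annotation, Hi-C proximity).
    """

    te_name: str
    te_family: str
    te_class_raw: str
    loci: tuple[GenomicInterval, ...] = ()

    @property
    def te_id(self) -> str:
        return f"{self.te_name}:{self.te_family}:{self.te_class_raw}"


@dataclass
class ContactPair:
    """A Hi-C contact between two anchors, labeled by cell type.

    Anchors are normalized so anchor_a <= anchor_b by (chrom, start, end).
    ``support`` is a read/contact count; sparse droplet data defaults to 1.
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    cell_type: str = ""
    support: int = 1

    def __post_init__(self):
        if self.support < 1:
            raise ValueError("support must be a positive integer")
        ka = (self.anchor_a.chrom, self.anchor_a.start, self.anchor_a.end)
        kb = (self.anchor_b.chrom, self.anchor_b.start, self.anchor_b.end)
        if ka > kb:
            self.anchor_a, self.anchor_b = self.anchor_b, self.anchor_a

    @property
    def anchors(self) -> tuple[GenomicInterval, GenomicInterval]:
        return (self.anchor_a, self.anchor_b)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT-style), all drawn from one identifier namespace."""

    sets: Mapping[str, frozenset[str]]
    namespace: str = "symbol"

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def filtered(
        self,
        universe: Iterable[str],
        min_size: int,
        max_size: int,
    ) -> "GeneSetCollection":
        """Intersect every set with ``universe`` and keep those whose
        surviving size falls within [min_size, max_size]."""
        uni = frozenset(universe)
        kept = {}
        for name, members in self.sets.items():
            inter = members & uni
            if min_size <= len(inter) <= max_size:
                kept[name] = inter
        return GeneSetCollection(sets=kept, namespace=self.namespace)


def is_te_feature_id(feature_id: str, delimiter: str = ":") -> bool:
    """True when the id follows the quantifier's name/family/class triplet
    convention (colon-separated by default)."""
    if delimiter == ":":
        return bool(TE_ID_PATTERN.match(feature_id))
    parts = feature_id.split(delimiter)
    return len(parts) == 3 and all(p and not p.isspace() for p in parts)


def parse_te_id(feature_id: str, delimiter: str = ":") -> tuple[str, str, str]:
    """Split a subfamily id into (name, family, class)."""
    parts = feature_id.split(delimiter)
    if len(parts) != 3 or not all(parts):
        raise ValueError(
            f"{feature_id!r} is not a name{delimiter}family{delimiter}class triplet"
        )
    return parts[0], parts[1], parts[2]
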