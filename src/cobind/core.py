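"""Core genomic data containers.

All coordinates are 0-based half-open throughout the package; the format
readers in :mod:`cobind.io` are the only place 1-based arithmetic appears.
Peaks carry an absolute summit coordinate (the base of maximal estimated
enrichment) because every downstream operation — co-occupancy matching,
feature annotation, mark-at-promoter tests — is summit-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "GeneModel",
    "GenomeAnnotation",
]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called enrichment interval with an absolute summit coordinate.

    Peaks are treated as unstranded by all co-occupancy operations; the
    strand field of the underlying interval is carried but ignored.
    """

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.score < 0:
            raise ValueError(f"negative score {self.score}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class PeakSet:
    """An ordered collection of peaks, sorted by (chrom, summit).

    Peak names must be unique within a set; tolerant deduplication for
    file ingestion lives in the readers, not here.
    """

    def __init__(self, label: str, peaks: Iterable[Peak]):
        self.label = label
        self.peaks = sorted(peaks, key=lambda p: (p.chrom, p.summit, p.name))
        names = [p.name for p in self.peaks]
        if len(set(names)) != len(names):
            seen: set[str] = set()
            dupes = sorted({n for n in names if n in seen or seen.add(n)})
            raise ValueError(f"duplicate peak names in set {label!r}: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out

    def __repr__(self) -> str:
        return f"PeakSet({self.label!r}, n={len(self)})"


@dataclass(frozen=True)
class GeneModel:
    """Gene identity, stranded span, TSS, and exon structure.

    The TSS is derived from strand: interval.start on '+', interval.end-1
    on '-'. Exons must be sorted, non-overlapping and contained in the span.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = self.interval.start
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")
            if ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class GenomeAnnotation:
    """Gene models plus optional enhancer intervals and chromosome sizes.

    When chrom_sizes is not supplied it is inferred as the maximal feature
    end per chromosome.
    """

    genes: list[GeneModel] = field(default_factory=list)
    enhancers: list[GenomicInterval] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            sizes: dict[str, int] = {}
            for g in self.genes:
                sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.interval.end)
            for e in self.enhancers:
                sizes[e.chrom] = max(sizes.get(e.chrom, 0), e.end)
            self.chrom_sizes = sizes
        else:
            for g in self.genes:
                lim = self.chrom_sizes.get(g.chrom)
                if lim is not None and g.interval.end > lim:
                    raise ValueError(
                        f"gene {g.gene_id} extends past chromosome {g.chrom} ({lim} bp)"
                    )
            for e in self.enhancers:
                lim = self.chrom_sizes.get(e.chrom)
                if lim is not None and e.end > lim:
                    raise ValueError(f"enhancer {e} extends past chromosome end")

    @property
    def gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes}

    def genes_by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out
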