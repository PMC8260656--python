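"""Assign peaks to genomic feature classes and target genes.

Each peak is classified by its summit position into one of five classes —
promoter, enhancer, exon, intron, intergenic — with a signed distance to
the linked gene's TSS (negative = upstream in gene orientation). When a
summit falls in several feature types at once the configured priority
order resolves it (most specific regulatory class first by default);
within one class the gene with the smallest |TSS distance| wins, then the
lexicographically smallest gene_id.

The promoter window extends ``promoter_up`` bp upstream and
``promoter_down`` bp downstream of the TSS in gene orientation, inclusive
at both ends. Enhancers are externally supplied intervals; an enhancer
peak is linked to the nearest TSS within ``enhancer_link_radius`` bp, or
to no gene if none is that close.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .core import GeneModel, GenomeAnnotation, Peak, PeakSet

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("promoter", "enhancer", "exon", "intron", "intergenic")

__all__ = [
    "FEATURE_CLASSES",
    "AnnotationConfig",
    "FeatureAssignment",
    "AnnotationIndex",
    "annotate_peak",
    "annotate_set",
    "assign_target_genes",
    "promoter_window",
]


@dataclass(frozen=True)
class AnnotationConfig:
    promoter_up: int = 2000
    promoter_down: int = 500
    feature_priority: tuple[str, ...] = ("promoter", "enhancer", "exon", "intron", "intergenic")
    enhancer_link_radius: int = 50_000

    def __post_init__(self) -> None:
        if self.promoter_up < 0 or self.promoter_down < 0:
            raise ValueError("promoter window extents must be non-negative")
        if sorted(self.feature_priority) != sorted(FEATURE_CLASSES):
            raise ValueError(
                f"feature_priority must permute {FEATURE_CLASSES}, "
                f"got {self.feature_priority}"
            )
        if self.enhancer_link_radius < 0:
            raise ValueError("enhancer_link_radius must be non-negative")


@dataclass(frozen=True)
class FeatureAssignment:
    peak_name: str
    feature: str
    gene_id: str | None = None
    tss_distance: int | None = None

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature!r}")
        if (self.gene_id is None) != (self.tss_distance is None):
            raise ValueError("gene_id and tss_distance must be present together")
        if self.feature == "intergenic" and self.gene_id is not None:
            raise ValueError("intergenic assignments carry no gene")


def promoter_window(gene: GeneModel, cfg: AnnotationConfig) -> tuple[int, int]:
    """Half-open genomic span of summits whose signed TSS distance lies in
    [-promoter_up, +promoter_down), in gene orientation (upstream edge
    inclusive, downstream edge exclusive)."""
    if gene.strand == "+":
        lo = gene.tss - cfg.promoter_up
        hi = gene.tss + cfg.promoter_down
    else:
        lo = gene.tss - cfg.promoter_down + 1
        hi = gene.tss + cfg.promoter_up + 1
    return max(lo, 0), hi


def signed_tss_distance(summit: int, gene: GeneModel) -> int:
    """Negative upstream of the TSS, positive downstream, in gene orientation."""
    if gene.strand == "+":
        return summit - gene.tss
    return gene.tss - summit


class AnnotationIndex:
    """Interval-tree index over promoters, enhancers, exons and gene spans,
    built once per (annotation, config) pair and shared across peaks."""

    def __init__(self, ann: GenomeAnnotation, cfg: AnnotationConfig):
        self.ann = ann
        self.cfg = cfg
        self._promoters: dict[str, IntervalTree] = {}
        self._exons: dict[str, IntervalTree] = {}
        self._spans: dict[str, IntervalTree] = {}
        self._enhancers: dict[str, IntervalTree] = {}
        self._tss: dict[str, list[tuple[int, str]]] = {}
        genes_by_id = {}
        for g in ann.genes:
            genes_by_id[g.gene_id] = g
            lo, hi = promoter_window(g, cfg)
            self._promoters.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g)
            self._spans.setdefault(g.chrom, IntervalTree()).addi(
                g.interval.start, g.interval.end, g
            )
            for ex in g.exons:
                self._exons.setdefault(g.chrom, IntervalTree()).addi(
                    ex.start, ex.end, g
                )
            self._tss.setdefault(g.chrom, []).append((g.tss, g.gene_id))
        for positions in self._tss.values():
            positions.sort()
        for i, e in enumerate(ann.enhancers):
            self._enhancers.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, i)
        self.genes_by_id = genes_by_id
        self._warned_chroms: set[str] = set()

    # -- candidate collection per class -----------------------------------

    def _gene_candidates(self, chrom: str, summit: int, tree_map) -> list[GeneModel]:
        tree = tree_map.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(summit)]

    def _nearest_tss(self, chrom: str, summit: int) -> tuple[str, int] | None:
        """Nearest gene by |TSS - summit| within the enhancer link radius."""
        positions = self._tss.get(chrom)
        if not positions:
            return None
        i = bisect_left(positions, (summit, ""))
        best: tuple[int, str] | None = None
        for j in (i - 1, i):
            if 0 <= j < len(positions):
                tss, gid = positions[j]
                key = (abs(tss - summit), gid)
                if best is None or key < best:
                    best = key
        assert best is not None
        if best[0] > self.cfg.enhancer_link_radius:
            return None
        return best[1], best[0]

    def classify(self, peak: Peak) -> FeatureAssignment:
        chrom, summit = peak.chrom, peak.summit
        known = (
            chrom in self._spans or chrom in self._promoters or chrom in self._enhancers
        )
        if not known and chrom not in self._warned_chroms:
            self._warned_chroms.add(chrom)
            logger.warning(
                "chromosome %s absent from annotation; peaks there are intergenic",
                chrom,
            )
        candidates: dict[str, list[tuple[int, str]]] = {}

        for g in self._gene_candidates(chrom, summit, self._promoters):
            d = signed_tss_distance(summit, g)
            candidates.setdefault("promoter", []).append((d, g.gene_id))

        enh_tree = self._enhancers.get(chrom)
        if enh_tree is not None and enh_tree.at(summit):
            candidates["enhancer"] = []

        exon_genes = {g.gene_id for g in self._gene_candidates(chrom, summit, self._exons)}
        for g in self._gene_candidates(chrom, summit, self._spans):
            d = signed_tss_distance(summit, g)
            cls = "exon" if g.gene_id in exon_genes else "intron"
            candidates.setdefault(cls, []).append((d, g.gene_id))

        for cls in self.cfg.feature_priority:
            if cls == "intergenic":
                break
            if cls not in candidates:
                continue
            if cls == "enhancer":
                link = self._nearest_tss(chrom, summit)
                if link is None:
                    return FeatureAssignment(peak.name, "enhancer")
                gid = link[0]
                gene = self.genes_by_id[gid]
                return FeatureAssignment(
                    peak.name, "enhancer", gid, signed_tss_distance(summit, gene)
                )
            d, gid = min(candidates[cls], key=lambda t: (abs(t[0]), t[1]))
            return FeatureAssignment(peak.name, cls, gid, d)
        return FeatureAssignment(peak.name, "intergenic")


def annotate_peak(
    peak: Peak,
    ann: GenomeAnnotation,
    cfg: AnnotationConfig | None = None,
    index: AnnotationIndex | None = None,
) -> FeatureAssignment:
    """Classify a single peak; pass a prebuilt :class:`AnnotationIndex`
    when annotating many peaks against the same annotation."""
    if index is None:
        index = AnnotationIndex(ann, cfg or AnnotationConfig())
    return index.classify(peak)


def annotate_set(
    peaks: PeakSet,
    ann: GenomeAnnotation,
    cfg: AnnotationConfig | None = None,
) -> tuple[list[FeatureAssignment], dict[str, dict[str, float]]]:
    """Classify every peak and tabulate the class distribution.

    Returns the assignments plus {'counts': {...}, 'fractions': {...}}
    over the five classes; fractions sum to 1 for non-empty input and are
    all None for an empty set.
    """
    index = AnnotationIndex(ann, cfg or AnnotationConfig())
    assignments = [index.classify(p) for p in peaks]
    counts = Counter(a.feature for a in assignments)
    n = len(assignments)
    if n == 0:
        logger.warning("annotate_set: empty peak set, distribution undefined")
        dist = {
            "counts": {c: 0 for c in FEATURE_CLASSES},
            "fractions": {c: None for c in FEATURE_CLASSES},
        }
    else:
        dist = {
            "counts": {c: counts.get(c, 0) for c in FEATURE_CLASSES},
            "fractions": {c: counts.get(c, 0) / n for c in FEATURE_CLASSES},
        }
    return assignments, dist


def assign_target_genes(assignments: list[FeatureAssignment]) -> set[str]:
    """Distinct genes with at least one non-intergenic, gene-linked peak."""
    return {
        a.gene_id
        for a in assignments
        if a.feature != "intergenic" and a.gene_id is not None
    }
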