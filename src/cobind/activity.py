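"""Histone-mark profiles and active/inactive classification of target genes.

A target gene "bears" a histone mark when at least one mark-peak summit
falls inside the gene's promoter window — the same summit-in-window
semantics used by the peak annotator. A target is transcriptionally
active when its expression value meets a configurable cutoff; genes
absent from the expression table are counted inactive (conservative) and
logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .annotate import AnnotationConfig, promoter_window
from .cooccupancy import round_half_up
from .core import GenomeAnnotation, PeakSet

logger = logging.getLogger(__name__)

__all__ = ["ActivityReport", "mark_profile", "classify_activity"]


@dataclass(frozen=True)
class ActivityReport:
    n_genes: int
    n_active: int
    mark_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_active > self.n_genes:
            raise ValueError("n_active exceeds n_genes")

    @property
    def fraction_active(self) -> float:
        return self.n_active / self.n_genes if self.n_genes else 0.0

    @property
    def percent_active(self) -> float:
        """Whole-percent display value (half-up)."""
        return round_half_up(100 * self.fraction_active, 0)


def mark_profile(
    targets: set[str],
    marks: dict[str, PeakSet],
    ann: GenomeAnnotation,
    cfg: AnnotationConfig | None = None,
) -> dict[str, float]:
    """Fraction of target genes bearing each mark in their promoter window.

    Target ids missing from the annotation are excluded with a warning.
    """
    cfg = cfg or AnnotationConfig()
    genes = {g.gene_id: g for g in ann.genes}
    missing = sorted(t for t in targets if t not in genes)
    if missing:
        logger.warning(
            "mark_profile: %d target genes absent from annotation, excluded "
            "(e.g. %s)", len(missing), missing[:3],
        )
    kept = [genes[t] for t in sorted(targets) if t in genes]
    if not kept:
        return {label: 0.0 for label in marks}
    windows = {g.gene_id: (g.chrom, *promoter_window(g, cfg)) for g in kept}
    out: dict[str, float] = {}
    for label, peakset in marks.items():
        summits = peakset.by_chrom()
        n_marked = 0
        for chrom, lo, hi in windows.values():
            peaks = summits.get(chrom, [])
            # peaks are sorted by summit; linear scan is fine at gene counts
            if any(lo <= p.summit < hi for p in peaks):
                n_marked += 1
        out[label] = n_marked / len(kept)
    return out


def classify_activity(
    targets: set[str],
    expr: pd.DataFrame,
    threshold: float = 1.0,
    marks: dict[str, float] | None = None,
) -> ActivityReport:
    """Classify target genes as active (expression >= threshold) or inactive.

    ``expr`` must have gene_id and value columns (one row per gene). The
    target collection is treated as a set: duplicates and ordering do not
    affect the result. An optional precomputed mark profile is attached to
    the report.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    target_set = set(targets)
    if not target_set:
        raise ValueError("classify_activity: no target genes to classify")
    values = dict(zip(expr["gene_id"], expr["value"]))
    missing = sorted(t for t in target_set if t not in values)
    if missing:
        logger.warning(
            "classify_activity: %d targets missing from expression table, "
            "counted inactive (e.g. %s)", len(missing), missing[:3],
        )
    n_active = sum(1 for t in target_set if values.get(t, 0.0) >= threshold)
    return ActivityReport(
        n_genes=len(target_set), n_active=n_active, mark_fractions=dict(marks or {})
    )
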