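"""Summit-proximity co-occupancy between two ChIP-seq peak sets.

Two factors are scored as co-occupying a genomic site when their peak
summits fall within a fixed window of each other (1 kb by default, the
convention for joint transcription-factor/cofactor binding). Matching is
one-to-one: all same-chromosome summit pairs within the window are ranked
by increasing distance (ties by coordinates) and accepted greedily while
both peaks are free, which yields a single deterministic co-occupied-site
count that can be expressed as a fraction of either input set.

A separate existence-style partition (:func:`partition_proximal`) splits a
cofactor set into anchor-proximal and distal subsets, e.g. to feed motif
discovery; unlike the matching it is many-to-one.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .core import Peak, PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "CoOccupiedSite",
    "CoOccupancyResult",
    "colocalize",
    "distance_fractions",
    "summarize_fractions",
    "partition_proximal",
    "peak_gene_overlap",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 -> 0.1), for reported percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CoOccupiedSite:
    """A matched summit pair interpreted as one jointly bound site."""

    peak_a: Peak
    peak_b: Peak
    distance: int

    def __post_init__(self) -> None:
        if self.peak_a.chrom != self.peak_b.chrom:
            raise ValueError("co-occupied site spans two chromosomes")
        if self.distance != abs(self.peak_a.summit - self.peak_b.summit):
            raise ValueError("distance inconsistent with summits")


@dataclass
class CoOccupancyResult:
    """Matched sites plus the matched fraction of each input set.

    A single matched count serves as numerator against both set sizes,
    so frac_a and frac_b share len(sites).
    """

    sites: list[CoOccupiedSite]
    window: int
    n_a: int
    n_b: int
    label_a: str = "A"
    label_b: str = "B"

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def frac_a(self) -> float:
        return len(self.sites) / self.n_a if self.n_a else 0.0

    @property
    def frac_b(self) -> float:
        return len(self.sites) / self.n_b if self.n_b else 0.0

    @property
    def distances(self) -> list[int]:
        return [s.distance for s in self.sites]


def _candidate_pairs(
    a_peaks: list[Peak], b_peaks: list[Peak], window: int
) -> list[tuple[int, int, int, int, int]]:
    """All same-chromosome pairs with |summit_a - summit_b| <= window.

    Sweep over B against the sorted A summits with a bisected window, so
    the cost is O((n_a + n_b) log n_a + k) for k candidates, never all-pairs.
    Returns sortable tuples (distance, summit_a, summit_b, ia, ib).
    """
    a_summits = [p.summit for p in a_peaks]
    out = []
    for ib, pb in enumerate(b_peaks):
        lo = bisect_left(a_summits, pb.summit - window)
        hi = bisect_right(a_summits, pb.summit + window)
        for ia in range(lo, hi):
            out.append(
                (abs(a_summits[ia] - pb.summit), a_summits[ia], pb.summit, ia, ib)
            )
    return out


def colocalize(set_a: PeakSet, set_b: PeakSet, window: int = 1000) -> CoOccupancyResult:
    """Greedy one-to-one matching of summits within ``window`` (inclusive).

    Candidate pairs are sorted by (distance, summit_a, summit_b) and
    accepted when both peaks are still unmatched, deterministically.
    Chromosomes present in only one set simply contribute no matches.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    a_by_chrom = set_a.by_chrom()
    b_by_chrom = set_b.by_chrom()
    only = set(a_by_chrom) ^ set(b_by_chrom)
    if only:
        logger.info(
            "chromosomes present in one set only (no matches there): %s",
            ", ".join(sorted(only)),
        )
    sites: list[CoOccupiedSite] = []
    for chrom in sorted(set(a_by_chrom) & set(b_by_chrom)):
        a_peaks = a_by_chrom[chrom]
        b_peaks = b_by_chrom[chrom]
        cands = _candidate_pairs(a_peaks, b_peaks, window)
        cands.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        for dist, _sa, _sb, ia, ib in cands:
            if ia in used_a or ib in used_b:
                continue
            used_a.add(ia)
            used_b.add(ib)
            sites.append(CoOccupiedSite(a_peaks[ia], b_peaks[ib], dist))
    sites.sort(key=lambda s: (s.peak_a.chrom, s.peak_a.summit, s.peak_b.summit))
    return CoOccupancyResult(
        sites, window, len(set_a), len(set_b), set_a.label, set_b.label
    )


def distance_fractions(
    result: CoOccupancyResult, thresholds: list[int]
) -> dict[int, float | None]:
    """Empirical CDF of summit distances at the given thresholds.

    Fractions are monotone in the threshold and reach 1 at the matching
    window. With no sites every fraction is undefined (None), not zero.
    """
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    if sorted(thresholds) != list(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    if not result.sites:
        logger.warning("distance_fractions: empty result, fractions undefined")
        return {t: None for t in thresholds}
    dists = result.distances
    n = len(dists)
    return {t: sum(d <= t for d in dists) / n for t in thresholds}


@dataclass(frozen=True)
class FractionSummary:
    n_matched: int
    n_a: int
    n_b: int
    frac_a: float = field(init=False)
    frac_b: float = field(init=False)
    percent_a: float = field(init=False)
    percent_b: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "frac_a", self.n_matched / self.n_a)
        object.__setattr__(self, "frac_b", self.n_matched / self.n_b)
        object.__setattr__(self, "percent_a", round_half_up(100 * self.frac_a, 1))
        object.__setattr__(self, "percent_b", round_half_up(100 * self.frac_b, 1))


def summarize_fractions(n_matched: int, n_a: int, n_b: int) -> FractionSummary:
    """Matched count as a percentage of each set (one-decimal, half-up);
    raw fractions are retained unrounded on the returned summary."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("set sizes must be positive")
    if not (0 <= n_matched <= min(n_a, n_b)):
        raise ValueError(
            f"matched count {n_matched} outside [0, min({n_a}, {n_b})]"
        )
    return FractionSummary(n_matched, n_a, n_b)


def partition_proximal(
    cofactor: PeakSet, anchor: PeakSet, window: int = 1000
) -> tuple[PeakSet, PeakSet]:
    """Split ``cofactor`` by whether any anchor summit lies within ``window``.

    This is an existence test (many cofactor peaks may share one anchor),
    distinct from the one-to-one matching in :func:`colocalize`; the two
    returned sets are disjoint and cover the input.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    anchor_summits = {
        chrom: [p.summit for p in peaks] for chrom, peaks in anchor.by_chrom().items()
    }
    proximal, distal = [], []
    for p in cofactor:
        summits = anchor_summits.get(p.chrom)
        if summits:
            lo = bisect_left(summits, p.summit - window)
            hi = bisect_right(summits, p.summit + window)
            if hi > lo:
                proximal.append(p)
                continue
        distal.append(p)
    return (
        PeakSet(f"{cofactor.label}_proximal", proximal),
        PeakSet(f"{cofactor.label}_distal", distal),
    )


def peak_gene_overlap(
    sets: dict[str, set[str]],
) -> dict[tuple[str, str], dict[str, float]]:
    """Pairwise intersection counts and coverage fractions for 2-3 gene
    sets (Venn-style). Keys are label pairs in input order."""
    if not 2 <= len(sets) <= 3:
        raise ValueError("peak_gene_overlap supports 2 or 3 sets")
    labels = list(sets)
    out: dict[tuple[str, str], dict[str, float]] = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            inter = len(sets[la] & sets[lb])
            out[(la, lb)] = {
                "intersection": inter,
                "frac_of_first": inter / len(sets[la]) if sets[la] else 0.0,
                "frac_of_second": inter / len(sets[lb]) if sets[lb] else 0.0,
            }
    if len(labels) == 3:
        out[tuple(labels)] = {  # type: ignore[index]
            "intersection": len(sets[labels[0]] & sets[labels[1]] & sets[labels[2]])
        }
    return out
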