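"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the library's sweep/interval-tree code paths:
matching enumerates all peak pairs, annotation linearly scans every
feature, and the hypergeometric tail is computed by exhaustive
enumeration with exact rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np

from cobind.annotate import FEATURE_CLASSES
from cobind.core import GeneModel, GenomeAnnotation, Peak


def brute_force_greedy_match(a_peaks, b_peaks, window):
    """All-pairs greedy one-to-one matching by increasing distance.

    Returns the set of (a_name, b_name, distance) triples. Candidate
    pairs come from a dense pairwise distance matrix (all pairs, no
    sweep), sorted by (distance, summit_a, summit_b) per chromosome.
    """
    matches = set()
    chroms = {p.chrom for p in a_peaks} & {p.chrom for p in b_peaks}
    for chrom in sorted(chroms):
        ca = [p for p in a_peaks if p.chrom == chrom]
        cb = [p for p in b_peaks if p.chrom == chrom]
        sa = np.array([p.summit for p in ca])
        sb = np.array([p.summit for p in cb])
        dist = np.abs(sa[:, None] - sb[None, :])
        ia, ib = np.nonzero(dist <= window)
        cands = sorted(
            (int(dist[i, j]), int(sa[i]), int(sb[j]), int(i), int(j))
            for i, j in zip(ia, ib)
        )
        used_a, used_b = set(), set()
        for d, _, _, i, j in cands:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            matches.add((ca[i].name, cb[j].name, d))
    return matches


def naive_signed_tss_distance(summit: int, gene: GeneModel) -> int:
    return summit - gene.tss if gene.strand == "+" else gene.tss - summit


def naive_annotate(peak: Peak, ann: GenomeAnnotation, cfg):
    """Linear-scan classification mirroring the documented rules."""
    summit, chrom = peak.summit, peak.chrom
    candidates: dict[str, list[tuple[int, str]]] = {}
    for g in ann.genes:
        if g.chrom != chrom:
            continue
        d = naive_signed_tss_distance(summit, g)
        if -cfg.promoter_up <= d < cfg.promoter_down:
            candidates.setdefault("promoter", []).append((d, g.gene_id))
        if g.interval.start <= summit < g.interval.end:
            in_exon = any(e.start <= summit < e.end for e in g.exons)
            candidates.setdefault("exon" if in_exon else "intron", []).append(
                (d, g.gene_id)
            )
    if any(
        e.chrom == chrom and e.start <= summit < e.end for e in ann.enhancers
    ):
        candidates["enhancer"] = []

    for cls in cfg.feature_priority:
        if cls == "intergenic":
            break
        if cls not in candidates:
            continue
        if cls == "enhancer":
            linked = [
                (abs(g.tss - summit), g.gene_id, g)
                for g in ann.genes
                if g.chrom == chrom and abs(g.tss - summit) <= cfg.enhancer_link_radius
            ]
            if not linked:
                return ("enhancer", None, None)
            _, gid, gene = min(linked, key=lambda t: (t[0], t[1]))
            return ("enhancer", gid, naive_signed_tss_distance(summit, gene))
        d, gid = min(candidates[cls], key=lambda t: (abs(t[0]), t[1]))
        return (cls, gid, d)
    return ("intergenic", None, None)


assert set(FEATURE_CLASSES) == {"promoter", "enhancer", "exon", "intron", "intergenic"}


def hypergeom_upper_tail_exact(k: int, universe: int, n1: int, n2: int) -> Fraction:
    """P(|draw of size n2| intersects a fixed n1-set in >= k) by exhaustive
    enumeration of all C(universe, n2) draws, as an exact rational."""
    items = range(universe)
    fixed = set(range(n1))
    hits = sum(
        1 for draw in combinations(items, n2) if len(fixed & set(draw)) >= k
    )
    from math import comb

    return Fraction(hits, comb(universe, n2))
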