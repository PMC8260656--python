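"""Synthetic genomes, peak sets, expression, and DE tables with planted truth.

Every pipeline stage is exercised against data whose generating process is
known exactly:

* a genome annotation with non-overlapping gene spans (random strand,
  2-6 exons) and intergenic enhancers,
* two peak sets where a fraction ``rho`` of set B summits is planted
  within a truncated-Laplace offset of a matched set A summit and the
  rest are uniform (so the recoverable co-localization fraction is
  rho plus an analytic Poisson chance term),
* an expression table where a fraction of genes is active, with
  activating/repressive histone-mark peaks planted in promoters at a
  configurable concordance,
* wild-type and mutant DE tables where the mutant fold changes are an
  attenuated, noisy copy of the wild-type ones (mut = slope * wt + noise)
  and a spiked subset is modulated by construction.

All generators are deterministic given ``SimConfig.seed``: each draws
from its own RNG stream derived from (seed, stage offset), so regenerating
one stage never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import AnnotationConfig, promoter_window
from .core import GeneModel, GenomeAnnotation, GenomicInterval, Peak, PeakSet

__all__ = [
    "SimConfig",
    "gen_annotation",
    "gen_cooccupancy_peaks",
    "gen_expression",
    "gen_de_tables",
    "chance_match_rate",
    "expected_matched_fraction",
    "truncated_laplace_cdf",
    "simulate_to_dir",
    "CapacityError",
]

# per-stage RNG stream offsets (spawned as default_rng([seed, offset]))
_STREAM_ANNOTATION = 1
_STREAM_PEAKS = 2
_STREAM_EXPRESSION = 3
_STREAM_DE = 4

# significance boundary of the monotone |log2FC| -> adjusted-p map: genes
# at |log2FC| == _LFC_SIG_CUT sit exactly at adj_p == 0.05
_LFC_SIG_CUT = 1.2
_SPIKE_MARGIN = 0.1


class CapacityError(RuntimeError):
    """The requested features do not fit in the simulated genome."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the scale of a two-factor ChIP-seq comparison: a
    100 Mb single-chromosome genome, 5000 anchor (TF) and 2000 cofactor
    peaks with a quarter of the cofactor summits planted near anchors at
    a 100 bp Laplace offset scale inside the 1 kb scoring window, two
    thirds of genes transcriptionally active with 0.9 mark concordance,
    and a mutant transcriptional response attenuated to a 0.44 slope.
    """

    genome_length: int = 100_000_000  # bp per chromosome
    n_chroms: int = 1
    n_genes: int = 2000
    n_enhancers: int = 300
    n_peaks_a: int = 5000
    n_peaks_b: int = 2000
    rho: float = 0.25
    offset_scale: float = 100.0
    window: int = 1000
    active_fraction: float = 0.66
    attenuation: float = 0.44
    noise_sd: float = 0.3
    mark_prob: float = 0.9
    expr_threshold: float = 1.0
    frac_modulated: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must lie in [0, 1]")
        if self.offset_scale <= 0:
            raise ValueError("offset_scale must be positive")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if min(self.genome_length, self.n_chroms) <= 0:
            raise ValueError("genome dimensions must be positive")
        if min(self.n_peaks_a, self.n_peaks_b) <= 0:
            raise ValueError("peak counts must be positive")
        if self.n_genes < 0 or self.n_enhancers < 0:
            raise ValueError("feature counts must be non-negative")
        if not 0 <= self.active_fraction <= 1:
            raise ValueError("active_fraction must lie in [0, 1]")
        if not 0 <= self.mark_prob <= 1:
            raise ValueError("mark_prob must lie in [0, 1]")
        if not math.isfinite(self.attenuation):
            raise ValueError("attenuation must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.frac_modulated <= 1:
            raise ValueError("frac_modulated must lie in [0, 1]")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def total_genome(self) -> int:
        return self.n_chroms * self.genome_length

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# annotation


def _place_nonoverlapping(
    rng: np.random.Generator, lengths: np.ndarray, chrom_len: int
) -> np.ndarray:
    """Start coordinates giving non-overlapping spans in genomic order.

    The free space left over after summing the spans is split uniformly at
    random into gaps before each span (a stick-breaking placement), so any
    feasible arrangement is reachable and placement never has to retry.
    """
    total = int(lengths.sum())
    slack = chrom_len - total
    if slack < 0:
        raise CapacityError(
            f"features of total length {total} bp do not fit in {chrom_len} bp"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=len(lengths)))
    return cuts + np.concatenate([[0], np.cumsum(lengths[:-1])])


def gen_annotation(cfg: SimConfig, ann_cfg: AnnotationConfig | None = None) -> GenomeAnnotation:
    """Random gene models and intergenic enhancers; deterministic per seed.

    Genes are placed without overlap (uniform stick-breaking), each with a
    random strand and 2-6 exons cut from its span. Enhancers (200-1000 bp)
    are rejection-sampled into space that overlaps neither gene spans nor
    the resolved promoter windows of ``ann_cfg``.
    """
    ann_cfg = ann_cfg or AnnotationConfig()
    rng = cfg.rng(_STREAM_ANNOTATION)
    chrom_sizes = {c: cfg.genome_length for c in cfg.chrom_names}

    # spread genes over chromosomes proportionally to length (equal here)
    per_chrom = rng.multinomial(cfg.n_genes, [1 / cfg.n_chroms] * cfg.n_chroms)
    genes: list[GeneModel] = []
    gidx = 0
    for chrom, n_on_chrom in zip(cfg.chrom_names, per_chrom):
        if n_on_chrom == 0:
            continue
        lengths = rng.integers(2000, 20001, size=n_on_chrom)
        starts = _place_nonoverlapping(rng, lengths, cfg.genome_length)
        for start, length in zip(starts, lengths):
            start, length = int(start), int(length)
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 7))
            cuts = np.sort(rng.choice(length + 1, size=2 * n_exons, replace=False))
            exons = tuple(
                GenomicInterval(chrom, start + int(cuts[2 * i]), start + int(cuts[2 * i + 1]), strand=strand)
                for i in range(n_exons)
                if cuts[2 * i] < cuts[2 * i + 1]
            )
            genes.append(
                GeneModel(
                    f"gene_{gidx:05d}",
                    GenomicInterval(chrom, start, start + length, strand=strand),
                    exons,
                )
            )
            gidx += 1

    raw: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chrom_names}
    for g in genes:
        raw[g.chrom].append((g.interval.start, g.interval.end))
        lo, hi = promoter_window(g, ann_cfg)
        raw[g.chrom].append((lo, min(hi, cfg.genome_length)))
    forbidden: dict[str, tuple[list[int], list[int]]] = {}
    for c, spans in raw.items():
        merged: list[list[int]] = []
        for s, e in sorted(spans):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        forbidden[c] = ([s for s, _ in merged], [e for _, e in merged])

    def clear(chrom: str, lo: int, hi: int) -> bool:
        from bisect import bisect_right

        starts, ends = forbidden[chrom]
        # merged spans are disjoint: only the last span starting before hi
        # can reach into [lo, hi)
        j = bisect_right(starts, hi - 1) - 1
        return j < 0 or ends[j] <= lo

    enhancers: list[GenomicInterval] = []
    max_tries = 200 * max(cfg.n_enhancers, 1)
    tries = 0
    while len(enhancers) < cfg.n_enhancers:
        if tries >= max_tries:
            raise CapacityError(
                f"placed only {len(enhancers)}/{cfg.n_enhancers} enhancers "
                f"after {max_tries} attempts"
            )
        tries += 1
        chrom = cfg.chrom_names[int(rng.integers(cfg.n_chroms))]
        length = int(rng.integers(200, 1001))
        start = int(rng.integers(0, cfg.genome_length - length + 1))
        if clear(chrom, start, start + length):
            enhancers.append(GenomicInterval(chrom, start, start + length))
    enhancers.sort(key=lambda e: (e.chrom, e.start))
    return GenomeAnnotation(genes=genes, enhancers=enhancers, chrom_sizes=chrom_sizes)


# ---------------------------------------------------------------------------
# peak sets with planted co-localization


def _truncated_laplace(
    rng: np.random.Generator, scale: float, trunc: float, size: int
) -> np.ndarray:
    """Laplace(0, scale) offsets resampled until |offset| <= trunc."""
    out = rng.laplace(0.0, scale, size=size)
    bad = np.abs(out) > trunc
    while bad.any():
        out[bad] = rng.laplace(0.0, scale, size=int(bad.sum()))
        bad = np.abs(out) > trunc
    return out


def _make_peaks(
    rng: np.random.Generator,
    label: str,
    chroms: list[str],
    summits: np.ndarray,
    chrom_len: int,
) -> list[Peak]:
    left = rng.integers(75, 251, size=len(summits))
    right = rng.integers(75, 251, size=len(summits))
    scores = rng.lognormal(2.0, 1.0, size=len(summits))
    peaks = []
    for i, (chrom, summit) in enumerate(zip(chroms, summits)):
        start = max(0, int(summit) - int(left[i]))
        end = min(chrom_len, int(summit) + int(right[i]) + 1)
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, end),
                summit=int(summit),
                score=float(scores[i]),
                name=f"{label}_{i:05d}",
            )
        )
    return peaks


def gen_cooccupancy_peaks(
    cfg: SimConfig, ann: GenomeAnnotation
) -> tuple[PeakSet, PeakSet, list[dict]]:
    """Two peak sets with a planted co-localized fraction of set B.

    Set A summits are uniform over the genome. round(rho * n_b) set B
    summits are placed at distinct A summits plus a Laplace(0,
    offset_scale) offset truncated to the scoring window (so every
    planted pair is recoverable at that window); the remainder are
    uniform. Returns (A, B, planted pairs with names and distances).
    """
    rng = cfg.rng(_STREAM_PEAKS)
    chrom_names = list(ann.chrom_sizes) or cfg.chrom_names
    chrom_len = cfg.genome_length

    def uniform_sites(n: int) -> tuple[list[str], np.ndarray]:
        ci = rng.integers(0, len(chrom_names), size=n)
        pos = rng.integers(0, chrom_len, size=n)
        return [chrom_names[i] for i in ci], pos

    a_chroms, a_pos = uniform_sites(cfg.n_peaks_a)
    a_peaks = _make_peaks(rng, "A", a_chroms, a_pos, chrom_len)

    n_planted = int(round(cfg.rho * cfg.n_peaks_b))
    if n_planted > cfg.n_peaks_a:
        raise ValueError("cannot plant more pairs than anchor peaks")
    anchor_idx = rng.choice(cfg.n_peaks_a, size=n_planted, replace=False)
    offsets = np.rint(
        _truncated_laplace(rng, cfg.offset_scale, cfg.window, n_planted)
    ).astype(int)
    b_chroms: list[str] = []
    b_pos_list: list[int] = []
    planted_anchor: list[int] = []
    for ai, off in zip(anchor_idx, offsets):
        pos = int(np.clip(a_pos[ai] + off, 0, chrom_len - 1))
        b_chroms.append(a_chroms[ai])
        b_pos_list.append(pos)
        planted_anchor.append(int(ai))
    extra_chroms, extra_pos = uniform_sites(cfg.n_peaks_b - n_planted)
    b_chroms.extend(extra_chroms)
    b_pos_list.extend(int(p) for p in extra_pos)
    b_peaks = _make_peaks(rng, "B", b_chroms, np.array(b_pos_list, dtype=int), chrom_len)

    planted = [
        {
            "a_name": a_peaks[ai].name,
            "b_name": b_peaks[bi].name,
            "distance": abs(a_peaks[ai].summit - b_peaks[bi].summit),
        }
        for bi, ai in enumerate(planted_anchor)
    ]
    return PeakSet("A", a_peaks), PeakSet("B", b_peaks), planted


def chance_match_rate(cfg: SimConfig) -> float:
    """Poisson probability that a uniform summit has >= 1 anchor summit
    within the window: 1 - exp(-n_A * 2w / G)."""
    return 1.0 - math.exp(-cfg.n_peaks_a * 2 * cfg.window / cfg.total_genome)


def expected_matched_fraction(cfg: SimConfig) -> float:
    """Expected co-localized fraction of set B: the planted fraction plus
    the chance rate applied to the non-planted remainder."""
    return cfg.rho + (1 - cfg.rho) * chance_match_rate(cfg)


def truncated_laplace_cdf(x: float, scale: float, trunc: float) -> float:
    """P(|offset| <= x) for a Laplace(0, scale) truncated to [-trunc, trunc]."""
    if not 0 <= x <= trunc:
        raise ValueError("x must lie in [0, trunc]")
    return (1 - math.exp(-x / scale)) / (1 - math.exp(-trunc / scale))


# ---------------------------------------------------------------------------
# expression and histone marks

ACTIVATING_MARK = "H3K4me3"
REPRESSIVE_MARK = "H3K27me3"


def gen_expression(
    cfg: SimConfig,
    ann: GenomeAnnotation,
    ann_cfg: AnnotationConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, PeakSet], dict[str, bool]]:
    """Expression values and promoter histone-mark peaks per gene.

    Each gene is independently active with probability ``active_fraction``;
    active genes draw a log-normal value strictly above ``expr_threshold``,
    inactive ones a uniform value strictly below it. Active genes receive
    an activating-mark promoter peak with probability ``mark_prob``,
    inactive genes a repressive-mark peak likewise. Returns the table, the
    mark peak sets, and the planted truth {gene_id: active}.
    """
    ann_cfg = ann_cfg or AnnotationConfig()
    rng = cfg.rng(_STREAM_EXPRESSION)
    rows = []
    truth: dict[str, bool] = {}
    act_peaks: list[Peak] = []
    rep_peaks: list[Peak] = []
    for g in ann.genes:
        active = bool(rng.random() < cfg.active_fraction)
        truth[g.gene_id] = active
        if active:
            value = cfg.expr_threshold * (1.0 + rng.lognormal(0.0, 1.0))
        else:
            value = rng.uniform(0.0, cfg.expr_threshold * 0.999)
        rows.append({"gene_id": g.gene_id, "value": value})
        if rng.random() < cfg.mark_prob:
            lo, hi = promoter_window(g, ann_cfg)
            chrom_len = ann.chrom_sizes.get(g.chrom, cfg.genome_length)
            hi = min(hi, chrom_len)
            summit = int(rng.integers(lo, hi))
            start = max(0, summit - 150)
            end = min(chrom_len, summit + 151)
            peak = Peak(
                GenomicInterval(g.chrom, start, end),
                summit=summit,
                score=float(rng.lognormal(2.0, 0.5)),
                name=f"{'act' if active else 'rep'}_{g.gene_id}",
            )
            (act_peaks if active else rep_peaks).append(peak)
    marks = {
        ACTIVATING_MARK: PeakSet(ACTIVATING_MARK, act_peaks),
        REPRESSIVE_MARK: PeakSet(REPRESSIVE_MARK, rep_peaks),
    }
    return pd.DataFrame(rows), marks, truth


# ---------------------------------------------------------------------------
# differential-expression tables


def _monotone_adj_p(log2fc: np.ndarray) -> np.ndarray:
    """Strictly decreasing map |log2FC| -> adjusted p with p = 0.05 exactly
    at the significance boundary |log2FC| = _LFC_SIG_CUT."""
    return np.minimum(1.0, np.exp(-np.abs(log2fc) * math.log(20.0) / _LFC_SIG_CUT))


def gen_de_tables(
    cfg: SimConfig, ann: GenomeAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Wild-type and mutant DE tables with a planted attenuation slope.

    Wild-type log2 fold changes are Normal(0, 1.2) background (truncated
    below the significance boundary so the planted modulated set is
    exactly the filter-passing set) plus a spiked modulated subset strictly
    above it. Mutant log2FC = attenuation * WT + Normal(0, noise_sd).
    Adjusted p follows a monotone decreasing map of |log2FC|. Returns
    (wt, mut, planted modulated gene ids).
    """
    rng = cfg.rng(_STREAM_DE)
    gene_ids = [g.gene_id for g in ann.genes]
    n = len(gene_ids)
    if n == 0:
        raise ValueError("annotation has no genes to build DE tables from")
    n_mod = int(round(cfg.frac_modulated * n))
    mod_idx = set(int(i) for i in rng.choice(n, size=n_mod, replace=False))

    wt = np.empty(n)
    background = rng.normal(0.0, 1.2, size=n)
    bad = np.abs(background) >= _LFC_SIG_CUT
    while bad.any():
        background[bad] = rng.normal(0.0, 1.2, size=int(bad.sum()))
        bad = np.abs(background) >= _LFC_SIG_CUT
    wt[:] = background
    for i in sorted(mod_idx):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        wt[i] = sign * (_LFC_SIG_CUT + _SPIKE_MARGIN + rng.exponential(0.5))

    mut = cfg.attenuation * wt + rng.normal(0.0, cfg.noise_sd, size=n)
    wt_df = pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": wt, "adj_p": _monotone_adj_p(wt)}
    )
    mut_df = pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": mut, "adj_p": _monotone_adj_p(mut)}
    )
    planted = {gene_ids[i] for i in sorted(mod_idx)}
    return wt_df, mut_df, planted


# ---------------------------------------------------------------------------
# file emission


def simulate_to_dir(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate every synthetic input and write it under ``out_dir`` in the
    pipeline's file formats; returns the path of each artifact."""
    from . import io as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = gen_annotation(cfg)
    set_a, set_b, planted = gen_cooccupancy_peaks(cfg, ann)
    expr, marks, truth = gen_expression(cfg, ann)
    wt, mut, modulated = gen_de_tables(cfg, ann)

    paths = {
        "genes": out / "genes.tsv",
        "enhancers": out / "enhancers.bed",
        "peaks_a": out / "peaks_a.narrowPeak",
        "peaks_b": out / "peaks_b.narrowPeak",
        "expression": out / "expression.tsv",
        "de_wt": out / "de_wt.tsv",
        "de_mut": out / "de_mut.tsv",
        "truth": out / "truth.json",
    }
    iio.write_gene_annotation_tsv(ann, paths["genes"])
    iio.write_bed(ann.enhancers, paths["enhancers"])
    iio.write_narrowpeak(set_a, paths["peaks_a"])
    iio.write_narrowpeak(set_b, paths["peaks_b"])
    for label, peakset in marks.items():
        p = out / f"mark_{label}.bed"
        iio.write_bed(peakset, p)
        paths[f"mark_{label}"] = p
    iio.write_expression_table(expr, paths["expression"])
    iio.write_de_table(wt, paths["de_wt"])
    iio.write_de_table(mut, paths["de_mut"])

    import json

    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "planted_pairs": planted,
                "active_genes": sorted(g for g, a in truth.items() if a),
                "modulated_genes": sorted(modulated),
                "config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return paths
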