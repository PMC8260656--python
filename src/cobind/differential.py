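"""Differential-expression filtering, overlap statistics, and signatures.

Model fitting (limma/DESeq-style) is upstream: the inputs here are tables
of per-gene log2 fold changes with adjusted p-values. This module applies
the modulated-gene filter (|log2FC| above a cutoff at significant
adjusted p, strict inequalities), tests the overlap of two modulated sets
against a hypergeometric null, regresses one contrast's fold changes on
another's to quantify global attenuation, and extracts a top-k signature
of targets deregulated in a cohort contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialRecord",
    "SignatureResult",
    "de_filter",
    "overlap_test",
    "attenuation_slope",
    "extract_signature",
    "direction_split",
]

DE_COLUMNS = ("gene_id", "log2fc", "adj_p")


@dataclass(frozen=True)
class DifferentialRecord:
    gene_id: str
    log2fc: float
    adj_p: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2fc):
            raise ValueError(f"{self.gene_id}: non-finite log2fc")
        if not 0 <= self.adj_p <= 1:
            raise ValueError(f"{self.gene_id}: adj_p outside [0, 1]")


def _as_frame(table: pd.DataFrame | list[DifferentialRecord]) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        missing = [c for c in DE_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"DE table missing columns {missing}")
        return table
    return pd.DataFrame(
        [(r.gene_id, r.log2fc, r.adj_p) for r in table], columns=list(DE_COLUMNS)
    )


def de_filter(
    table: pd.DataFrame | list[DifferentialRecord],
    lfc_min: float = 0.37,
    p_max: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Up- and down-modulated gene sets at strict thresholds.

    up = {log2fc > lfc_min and adj_p < p_max}; down mirrors with
    log2fc < -lfc_min. Both inequalities are strict, so boundary genes
    (log2fc == lfc_min or adj_p == p_max) are excluded.
    """
    if lfc_min < 0 or p_max <= 0:
        raise ValueError("thresholds must be positive")
    df = _as_frame(table)
    sig = df["adj_p"] < p_max
    up = set(df.loc[sig & (df["log2fc"] > lfc_min), "gene_id"])
    down = set(df.loc[sig & (df["log2fc"] < -lfc_min), "gene_id"])
    return up, down


def overlap_test(
    set1: set[str], set2: set[str], universe: int
) -> tuple[int, float]:
    """Observed intersection and upper-tail hypergeometric probability.

    P(X >= k) for X ~ Hypergeom(universe, |set1|, |set2|): the chance of
    at least the observed overlap when set2 is drawn at random from the
    universe. Disjoint sets give p = 1 (the tail includes k = 0).
    """
    if universe < len(set1 | set2):
        raise ValueError("universe smaller than the union of the two sets")
    k = len(set1 & set2)
    p = float(stats.hypergeom.sf(k - 1, universe, len(set1), len(set2)))
    return k, min(p, 1.0)


def attenuation_slope(
    wt: pd.DataFrame,
    mut: pd.DataFrame,
    modulated_only: bool = False,
    lfc_min: float = 0.37,
    p_max: float = 0.05,
) -> tuple[float, float, int]:
    """OLS slope of mutant log2FC on wild-type log2FC over shared genes.

    A slope below 1 indicates a globally attenuated transcriptional
    response of the mutant. With ``modulated_only`` the regression is
    restricted to genes passing the modulation filter in either contrast.
    Returns (slope, intercept, n matched genes); requires >= 3 shared genes.
    """
    wt_df, mut_df = _as_frame(wt), _as_frame(mut)
    merged = wt_df.merge(mut_df, on="gene_id", suffixes=("_wt", "_mut"))
    if modulated_only:
        up_w, dn_w = de_filter(wt_df, lfc_min, p_max)
        up_m, dn_m = de_filter(mut_df, lfc_min, p_max)
        keep = up_w | dn_w | up_m | dn_m
        merged = merged[merged["gene_id"].isin(keep)]
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} shared genes; need at least 3")
    fit = stats.linregress(merged["log2fc_wt"], merged["log2fc_mut"])
    return float(fit.slope), float(fit.intercept), len(merged)


@dataclass(frozen=True)
class SignatureResult:
    """Ordered signature genes with per-gene direction and provenance."""

    genes: tuple[tuple[str, str], ...]  # (gene_id, 'up'|'down'|'zero')
    k: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genes in signature")
        if len(self.genes) > self.k:
            raise ValueError("signature longer than requested k")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.genes]


def extract_signature(
    cohort_de: pd.DataFrame,
    target_set: set[str],
    p_cutoff: float = 0.1,
    k: int = 50,
    p_kind: str = "adjusted",
) -> SignatureResult:
    """Top-k cohort-deregulated genes among a target set.

    The cohort DE table is filtered to p < p_cutoff (adjusted p by
    default; ``p_kind='raw'`` uses a 'p' column instead), intersected with
    the target set, ranked by p ascending with ties broken by |log2fc|
    descending then gene_id, and truncated to k. Direction is the sign of
    log2fc. Fewer than k survivors are returned in full with a warning.
    """
    if not 0 < p_cutoff <= 1:
        raise ValueError("p_cutoff must be in (0, 1]")
    if k <= 0:
        raise ValueError("k must be positive")
    if p_kind not in ("adjusted", "raw"):
        raise ValueError("p_kind must be 'adjusted' or 'raw'")
    df = _as_frame(cohort_de)
    p_col = "adj_p" if p_kind == "adjusted" else "p"
    if p_col not in df.columns:
        raise ValueError(f"DE table lacks column {p_col!r} for p_kind={p_kind!r}")
    surv = df[(df[p_col] < p_cutoff) & df["gene_id"].isin(target_set)].copy()
    surv = surv.sort_values(
        by=[p_col, "log2fc", "gene_id"],
        ascending=[True, True, True],
        key=lambda s: -s.abs() if s.name == "log2fc" else s,
    )
    if len(surv) < k:
        logger.warning(
            "extract_signature: only %d qualifying genes for k=%d", len(surv), k
        )
    top = surv.head(k)
    genes = tuple(
        (row.gene_id, "up" if row.log2fc > 0 else ("down" if row.log2fc < 0 else "zero"))
        for row in top.itertuples(index=False)
    )
    return SignatureResult(
        genes=genes,
        k=k,
        provenance={
            "p_cutoff": p_cutoff,
            "p_kind": p_kind,
            "n_cohort": len(df),
            "n_targets": len(target_set),
            "n_qualifying": len(surv),
        },
    )


@dataclass(frozen=True)
class DirectionSplit:
    n_up: int
    n_down: int
    n_zero: int

    @property
    def frac_up(self) -> float:
        n = self.n_up + self.n_down
        return self.n_up / n if n else 0.0

    @property
    def frac_down(self) -> float:
        n = self.n_up + self.n_down
        return self.n_down / n if n else 0.0


def direction_split(log2fc: pd.Series | list[float]) -> DirectionSplit:
    """Fractions of up- and down-regulated genes by sign of log2FC.

    Fractions are over the non-zero entries; exact zeros are counted
    separately and reported, not folded into either direction.
    """
    values = np.asarray(log2fc, dtype=float)
    if values.size == 0:
        raise ValueError("direction_split: empty input")
    if not np.isfinite(values).all():
        raise ValueError("direction_split: non-finite log2fc values")
    return DirectionSplit(
        n_up=int((values > 0).sum()),
        n_down=int((values < 0).sum()),
        n_zero=int((values == 0).sum()),
    )
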