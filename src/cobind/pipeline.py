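"""End-to-end orchestration: simulate/load -> colocalize -> annotate ->
classify -> differential -> signature, emitting one machine-readable report.

The report is a plain dict serialized as sorted, indented JSON, so two
runs with the same configuration are byte-identical. Numeric headline
fields carry both the raw value and the rounded display value used in
prose (e.g. one-decimal percentages).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as iio
from .activity import classify_activity, mark_profile
from .annotate import AnnotationConfig, annotate_set, assign_target_genes
from .cooccupancy import (
    colocalize,
    distance_fractions,
    round_half_up,
    summarize_fractions,
)
from .core import GenomicInterval, Peak, PeakSet
from .differential import (
    attenuation_slope,
    de_filter,
    direction_split,
    extract_signature,
    overlap_test,
)
from .simulate import (
    SimConfig,
    gen_annotation,
    gen_cooccupancy_peaks,
    gen_de_tables,
    gen_expression,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = ["RunConfig", "StageError", "run_pipeline", "report_to_json", "save_report"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    With ``sim`` set, all inputs are generated; otherwise ``inputs`` must
    provide file paths (peaks_a, peaks_b, genes [+ genes_dialect],
    optionally enhancers, expression, marks as {label: path}, de_wt,
    de_mut). Stages without inputs are skipped.
    """

    sim: SimConfig | None = None
    inputs: dict = field(default_factory=dict)
    window: int = 1000
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    expr_threshold: float = 1.0
    lfc_min: float = 0.37
    p_max: float = 0.05
    signature_p_cutoff: float = 0.1
    signature_k: int = 50
    cdf_thresholds: tuple[int, ...] = (20, 200, 1000)

    def validate(self) -> None:
        if self.sim is None:
            for key in ("peaks_a", "peaks_b"):
                path = self.inputs.get(key)
                if not path:
                    raise ValueError(f"no simulation config and no input {key!r}")
                if not Path(path).exists():
                    raise FileNotFoundError(f"input {key!r}: {path}")


def _site_peaks(result) -> PeakSet:
    """One representative peak per co-occupied site: summit at the midpoint
    of the two summits, interval spanning both peaks."""
    peaks = []
    for i, s in enumerate(result.sites):
        lo = min(s.peak_a.interval.start, s.peak_b.interval.start)
        hi = max(s.peak_a.interval.end, s.peak_b.interval.end)
        mid = (s.peak_a.summit + s.peak_b.summit) // 2
        peaks.append(
            Peak(
                GenomicInterval(s.peak_a.chrom, lo, hi),
                summit=mid,
                score=(s.peak_a.score + s.peak_b.score) / 2,
                name=f"site_{i:05d}",
            )
        )
    return PeakSet("cooccupied_sites", peaks)


def _load_inputs(cfg: RunConfig):
    inp = cfg.inputs
    set_a = iio.read_narrowpeak(inp["peaks_a"], label="A")
    set_b = iio.read_narrowpeak(inp["peaks_b"], label="B")
    ann = None
    if inp.get("genes"):
        enhancers = (
            iio.read_bed(inp["enhancers"]) if inp.get("enhancers") else None
        )
        ann = iio.read_gene_annotation(
            inp["genes"],
            dialect=inp.get("genes_dialect", "tsv"),
            enhancers=enhancers,
        )
    expr = iio.read_expression_table(inp["expression"]) if inp.get("expression") else None
    marks = {
        label: iio.read_bed(path, label=label, as_peaks=True)
        for label, path in (inp.get("marks") or {}).items()
    }
    de_wt = iio.read_de_table(inp["de_wt"]) if inp.get("de_wt") else None
    de_mut = iio.read_de_table(inp["de_mut"]) if inp.get("de_mut") else None
    return set_a, set_b, ann, expr, marks, de_wt, de_mut


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every configured stage and return the report document."""
    cfg.validate()
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": {
            "window": cfg.window,
            "expr_threshold": cfg.expr_threshold,
            "lfc_min": cfg.lfc_min,
            "p_max": cfg.p_max,
            "signature_p_cutoff": cfg.signature_p_cutoff,
            "signature_k": cfg.signature_k,
            "simulated": cfg.sim is not None,
            "seed": cfg.sim.seed if cfg.sim else None,
        },
    }

    try:
        if cfg.sim is not None:
            ann = gen_annotation(cfg.sim, cfg.annotation)
            set_a, set_b, _planted = gen_cooccupancy_peaks(cfg.sim, ann)
            expr, marks, _truth = gen_expression(cfg.sim, ann, cfg.annotation)
            de_wt, de_mut, _modulated = gen_de_tables(cfg.sim, ann)
        else:
            set_a, set_b, ann, expr, marks, de_wt, de_mut = _load_inputs(cfg)
    except Exception as exc:  # noqa: BLE001
        raise StageError("inputs", exc) from exc
    report["inputs"] = {
        "n_peaks_a": len(set_a),
        "n_peaks_b": len(set_b),
        "n_genes": len(ann.genes) if ann else 0,
        "n_enhancers": len(ann.enhancers) if ann else 0,
    }

    try:
        result = colocalize(set_a, set_b, cfg.window)
        summary = summarize_fractions(result.n_sites, result.n_a, result.n_b)
        cdf = distance_fractions(result, sorted(set(cfg.cdf_thresholds)))
        report["cooccupancy"] = {
            "window": cfg.window,
            "n_sites": result.n_sites,
            "frac_a_raw": summary.frac_a,
            "frac_b_raw": summary.frac_b,
            "percent_a": summary.percent_a,
            "percent_b": summary.percent_b,
            "distance_cdf": {str(t): cdf[t] for t in cdf},
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("cooccupancy", exc) from exc

    targets: set[str] = set()
    if ann is not None:
        try:
            sites = _site_peaks(result)
            assignments, dist = annotate_set(sites, ann, cfg.annotation)
            targets = assign_target_genes(assignments)
            report["annotation"] = {
                "class_counts": dist["counts"],
                "class_fractions": dist["fractions"],
                "n_target_genes": len(targets),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("annotation", exc) from exc

    if ann is not None and expr is not None and targets:
        try:
            profile = mark_profile(targets, marks, ann, cfg.annotation)
            activity = classify_activity(
                targets, expr, cfg.expr_threshold, marks=profile
            )
            report["activity"] = {
                "n_targets": activity.n_genes,
                "n_active": activity.n_active,
                "fraction_active_raw": activity.fraction_active,
                "percent_active": activity.percent_active,
                "mark_fractions": activity.mark_fractions,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("activity", exc) from exc

    if de_wt is not None and de_mut is not None:
        try:
            up_wt, dn_wt = de_filter(de_wt, cfg.lfc_min, cfg.p_max)
            up_mut, dn_mut = de_filter(de_mut, cfg.lfc_min, cfg.p_max)
            universe = len(set(de_wt["gene_id"]) | set(de_mut["gene_id"]))
            k_overlap, p_overlap = overlap_test(
                up_wt | dn_wt, up_mut | dn_mut, universe
            )
            slope, intercept, n_shared = attenuation_slope(de_wt, de_mut)
            report["differential"] = {
                "n_modulated_wt": len(up_wt | dn_wt),
                "n_modulated_mut": len(up_mut | dn_mut),
                "overlap": k_overlap,
                "overlap_p": p_overlap,
                "attenuation_slope_raw": slope,
                "attenuation_slope": round_half_up(slope, 2),
                "attenuation_intercept": intercept,
                "n_shared_genes": n_shared,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("differential", exc) from exc

    if de_wt is not None and targets:
        try:
            sig = extract_signature(
                de_wt, targets, cfg.signature_p_cutoff, cfg.signature_k
            )
            lfc = dict(zip(de_wt["gene_id"], de_wt["log2fc"]))
            split = direction_split([lfc[g] for g in sig.gene_ids]) if sig.genes else None
            report["signature"] = {
                "k": sig.k,
                "n_genes": len(sig.genes),
                "genes": [list(g) for g in sig.genes],
                "provenance": sig.provenance,
                "frac_up": split.frac_up if split else None,
                "frac_down": split.frac_down if split else None,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("signature", exc) from exc

    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True) + "\n"


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(report_to_json(report))


def save_plots(report: dict, result, out_dir: str | Path) -> list[Path]:
    """Distance histogram and feature-class bar chart for one run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(result.distances, bins=40, color="#4878a8")
    ax.set_xlabel("summit distance (bp)")
    ax.set_ylabel("co-occupied sites")
    fig.tight_layout()
    p = out / "distance_histogram.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    if "annotation" in report:
        counts = report["annotation"]["class_counts"]
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.bar(list(counts), list(counts.values()), color="#a85448")
        ax.set_ylabel("co-occupied sites")
        fig.tight_layout()
        p = out / "class_distribution.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written


def run_config_from_yaml(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file with optional sections
    ``sim``, ``annotation``, ``inputs`` and top-level scalar overrides."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "sim" in doc and doc["sim"] is not None:
        kwargs["sim"] = SimConfig(**doc["sim"])
    if "annotation" in doc and doc["annotation"] is not None:
        ann = doc["annotation"]
        if "feature_priority" in ann:
            ann["feature_priority"] = tuple(ann["feature_priority"])
        kwargs["annotation"] = AnnotationConfig(**ann)
    if "inputs" in doc and doc["inputs"] is not None:
        kwargs["inputs"] = dict(doc["inputs"])
    scalars = {
        f.name
        for f in dataclasses.fields(RunConfig)
        if f.name not in ("sim", "annotation", "inputs")
    }
    for key, val in doc.items():
        if key in scalars:
            kwargs[key] = tuple(val) if key == "cdf_thresholds" else val
    return RunConfig(**kwargs)
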