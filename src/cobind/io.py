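"""Readers and writers for the interval and table formats the pipeline touches.

Supported formats: ENCODE narrowPeak (10 columns), BED6, a restricted GTF
dialect (gene/exon feature lines with a gene_id attribute), a tabular
gene-model dialect, and plain TSV expression / differential-expression
tables. GTF coordinates (1-based inclusive) are converted to the package's
0-based half-open convention at this boundary and nowhere else.

Readers are tolerant where the damage is local (duplicate peak names get an
ordinal suffix and a logged warning) and strict where it is structural
(malformed coordinates raise :class:`FormatError` naming the line). Every
reader logs counts of accepted and rejected records.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import GeneModel, GenomeAnnotation, GenomicInterval, Peak, PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bed",
    "write_bed",
    "read_gene_annotation",
    "write_gene_annotation_tsv",
    "read_expression_table",
    "write_expression_table",
    "read_de_table",
    "write_de_table",
]


class FormatError(ValueError):
    """A file violated its format contract; the message names the line."""


def _dedupe_names(names: list[str], path: str) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    n_dupes = 0
    for name in names:
        if name in seen:
            seen[name] += 1
            n_dupes += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    if n_dupes:
        logger.warning("%s: %d duplicate peak names auto-suffixed", path, n_dupes)
    return out


def read_narrowpeak(path: str | Path, label: str | None = None) -> PeakSet:
    """Read an ENCODE narrowPeak file into a :class:`PeakSet`.

    Column 10 is the summit offset from peak start; -1 means unknown, in
    which case the summit falls back to the interval midpoint (floored).
    The peak score is taken from the signalValue column (7).
    """
    path = Path(path)
    label = label or path.stem
    names: list[str] = []
    rows: list[tuple[str, int, int, float, int, str]] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{lineno}: expected 10 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
                signal = float(fields[6])
                offset = int(fields[9])
            except ValueError as exc:
                n_rejected += 1
                logger.warning("%s:%d: rejected malformed row (%s)", path, lineno, exc)
                continue
            if start < 0 or end <= start:
                n_rejected += 1
                logger.warning(
                    "%s:%d: rejected row with invalid interval %d-%d",
                    path, lineno, start, end,
                )
                continue
            if offset != -1 and not (0 <= offset < end - start):
                raise FormatError(
                    f"{path}:{lineno}: summit offset {offset} outside "
                    f"[-1, {end - start})"
                )
            summit = start + offset if offset != -1 else (start + end) // 2
            names.append(name)
            rows.append((chrom, start, end, signal, summit, strand))
    names = _dedupe_names(names, str(path))
    peaks = [
        Peak(GenomicInterval(c, s, e, strand=st), summit=sm, score=sig, name=nm)
        for (c, s, e, sig, sm, st), nm in zip(rows, names)
    ]
    logger.info("%s: accepted %d peaks, rejected %d rows", path, len(peaks), n_rejected)
    return PeakSet(label, peaks)


def write_narrowpeak(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as narrowPeak; roundtrips through read_narrowpeak."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        p.name,
                        "0",
                        iv.strand,
                        repr(p.score),
                        "-1",
                        "-1",
                        str(p.summit - iv.start),
                    ]
                )
                + "\n"
            )


def write_bed(items: PeakSet | Iterable[GenomicInterval], path: str | Path) -> None:
    """Write peaks (BED6, summit carried in the name as ``name|summit``) or
    plain intervals (BED6 with dot names). An empty collection yields an
    empty file."""
    with open(path, "w") as fh:
        if isinstance(items, PeakSet):
            for p in items:
                iv = p.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}|{p.summit}"
                    f"\t{p.score:g}\t{iv.strand}\n"
                )
        else:
            for iv in items:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_bed(
    path: str | Path, label: str | None = None, as_peaks: bool = False
) -> PeakSet | list[GenomicInterval]:
    """Read BED3+ intervals; with as_peaks=True reconstruct peaks, taking
    the summit from a ``name|summit`` name when present, else the midpoint."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    names: list[str] = []
    summits: list[int | None] = []
    scores: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: invalid interval {start}-{end}")
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
            intervals.append(GenomicInterval(fields[0], start, end, strand=strand))
            name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
            summit: int | None = None
            if "|" in name:
                base, _, tail = name.rpartition("|")
                if tail.isdigit():
                    name, summit = base, int(tail)
            names.append(name)
            summits.append(summit)
            try:
                scores.append(float(fields[4]) if len(fields) > 4 else 0.0)
            except ValueError:
                scores.append(0.0)
    if not as_peaks:
        return intervals
    names = _dedupe_names(names, str(path))
    peaks = [
        Peak(
            iv,
            summit=sm if sm is not None else (iv.start + iv.end) // 2,
            score=max(sc, 0.0),
            name=nm,
        )
        for iv, sm, sc, nm in zip(intervals, summits, scores, names)
    ]
    return PeakSet(label or path.stem, peaks)


# ---------------------------------------------------------------------------
# gene annotation


def _parse_gtf_attrs(attr_field: str) -> dict[str, str]:
    attrs = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def _read_gtf(path: Path) -> list[GeneModel]:
    gene_spans: dict[str, GenomicInterval] = {}
    exon_map: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature not in ("gene", "exon"):
                continue
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            # GTF is 1-based inclusive; convert here, once.
            iv = GenomicInterval(chrom, start1 - 1, end1, strand=strand)
            attrs = _parse_gtf_attrs(attrs_s)
            gid = attrs.get("gene_id")
            if not gid:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            if feature == "gene":
                if gid in gene_spans:
                    raise FormatError(f"{path}:{lineno}: duplicate gene {gid}")
                gene_spans[gid] = iv
                order.append(gid)
            else:
                exon_map.setdefault(gid, []).append(iv)
    genes = []
    for gid in order:
        span = gene_spans[gid]
        exons = tuple(sorted(exon_map.get(gid, []), key=lambda e: e.start))
        for ex in exons:
            if ex.start < span.start or ex.end > span.end or ex.chrom != span.chrom:
                raise FormatError(f"{path}: exon of {gid} outside gene span")
        genes.append(GeneModel(gid, span, exons))
    return genes


TSV_GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "exon_starts", "exon_ends"]


def _read_gene_tsv(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TSV_GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise FormatError(f"{path}: gene {row.gene_id}: unknown strand {row.strand!r}")
        span = GenomicInterval(row.chrom, int(row.start), int(row.end), strand=row.strand)
        starts = [int(x) for x in str(row.exon_starts).split(",") if x not in ("", "nan")]
        ends = [int(x) for x in str(row.exon_ends).split(",") if x not in ("", "nan")]
        if len(starts) != len(ends):
            raise FormatError(f"{path}: gene {row.gene_id}: exon_starts/ends mismatch")
        exons = tuple(
            GenomicInterval(row.chrom, s, e, strand=row.strand)
            for s, e in zip(starts, ends)
        )
        try:
            genes.append(GeneModel(row.gene_id, span, exons))
        except ValueError as exc:
            raise FormatError(f"{path}: gene {row.gene_id}: {exc}") from exc
    return genes


def read_gene_annotation(
    path: str | Path,
    dialect: str = "gtf",
    enhancers: Sequence[GenomicInterval] | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> GenomeAnnotation:
    """Read gene models from a GTF subset (gene/exon lines) or the TSV
    dialect and return a :class:`GenomeAnnotation`."""
    path = Path(path)
    if dialect == "gtf":
        genes = _read_gtf(path)
    elif dialect == "tsv":
        genes = _read_gene_tsv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'gtf' or 'tsv')")
    logger.info("%s: read %d gene models", path, len(genes))
    return GenomeAnnotation(
        genes=genes,
        enhancers=list(enhancers or []),
        chrom_sizes=dict(chrom_sizes or {}),
    )


def write_gene_annotation_tsv(ann: GenomeAnnotation, path: str | Path) -> None:
    rows = []
    for g in ann.genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.interval.start,
                "end": g.interval.end,
                "strand": g.strand,
                "exon_starts": ",".join(str(e.start) for e in g.exons),
                "exon_ends": ",".join(str(e.end) for e in g.exons),
            }
        )
    pd.DataFrame(rows, columns=TSV_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression and differential-expression tables


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene_id, value (one record per gene, value >= 0)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated gene_id entries")
    if (df["value"] < 0).any():
        raise FormatError(f"{path}: negative expression values")
    return df[["gene_id", "value"]]


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["gene_id", "value"]].to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene_id, log2fc, adj_p (optional raw p column)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "log2fc", "adj_p"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    bad = df[(df["adj_p"] < 0) | (df["adj_p"] > 1)]
    if len(bad):
        raise FormatError(f"{path}: adj_p outside [0, 1] for {len(bad)} rows")
    return df


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("gene_id", "log2fc", "p", "adj_p") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)
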