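from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from cobind.core import GeneModel, GenomeAnnotation, GenomicInterval, Peak, PeakSet

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_peak(summit, chrom="chr1", half=250, name=None, score=1.0, strand="."):
    start = max(0, summit - half)
    return Peak(
        GenomicInterval(chrom, start, summit + half + 1, strand=strand),
        summit=summit,
        score=score,
        name=name or f"{chrom}:{summit}",
    )


def make_peakset(label, summits, chrom="chr1"):
    return PeakSet(
        label,
        [make_peak(s, chrom=chrom, name=f"{label}_{i}") for i, s in enumerate(summits)],
    )


@pytest.fixture
def toy_sets():
    """The 5x4 worked example: 3 matches at distances {800, 100, 1000}."""
    set_a = make_peakset("A", [100, 5000, 10000, 20000, 30000])
    set_b = make_peakset("B", [900, 5100, 19000, 32000])
    return set_a, set_b


@pytest.fixture
def toy_gene():
    """+ strand gene, TSS 10000, exons [10000,10200) and [10800,11200)."""
    iv = GenomicInterval("chr1", 10000, 12000, strand="+")
    exons = (
        GenomicInterval("chr1", 10000, 10200, strand="+"),
        GenomicInterval("chr1", 10800, 11200, strand="+"),
    )
    return GeneModel("GENE1", iv, exons)


@pytest.fixture
def toy_annotation(toy_gene):
    return GenomeAnnotation(genes=[toy_gene], chrom_sizes={"chr1": 100_000})
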