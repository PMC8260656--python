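"""Feature classification by summit: windows, priority, sign conventions."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import naive_annotate
from cobind.annotate import (
    AnnotationConfig,
    AnnotationIndex,
    FeatureAssignment,
    annotate_peak,
    annotate_set,
    assign_target_genes,
    promoter_window,
)
from cobind.core import GeneModel, GenomeAnnotation, GenomicInterval
from cobind.simulate import SimConfig, gen_annotation
from conftest import make_peak, make_peakset


class TestAnnotatePeak:
    @pytest.mark.parametrize(
        "summit, feature, dist",
        [
            (9000, "promoter", -1000),
            (10900, "exon", 900),
            (10500, "intron", 500),
            (50000, "intergenic", None),
            (10000, "promoter", 0),  # exactly at the TSS
        ],
    )
    def test_plus_strand_gene_cases(self, toy_annotation, summit, feature, dist):
        a = annotate_peak(make_peak(summit), toy_annotation)
        assert a.feature == feature
        assert a.tss_distance == dist

    def test_minus_strand_sign_mirrors(self):
        gene = GeneModel(
            "NEG", GenomicInterval("chr1", 20000, 24000, strand="-"),
            (GenomicInterval("chr1", 20000, 24000, strand="-"),),
        )
        ann = GenomeAnnotation(genes=[gene], chrom_sizes={"chr1": 100_000})
        # 1 kb downstream of the TSS (toward gene body) on the minus strand
        a = annotate_peak(make_peak(23999 - 1000), ann)
        assert a.feature == "exon" and a.tss_distance == 1000
        # 500 bp upstream (greater coordinate than TSS)
        b = annotate_peak(make_peak(23999 + 500), ann)
        assert b.feature == "promoter" and b.tss_distance == -500

    def test_promoter_beats_exon_of_other_gene(self, toy_gene):
        other = GeneModel(
            "GENE2", GenomicInterval("chr1", 8000, 9500, strand="+"),
            (GenomicInterval("chr1", 8000, 9500, strand="+"),),
        )
        ann = GenomeAnnotation(genes=[toy_gene, other], chrom_sizes={"chr1": 100_000})
        a = annotate_peak(make_peak(9000), ann)  # GENE1 promoter + GENE2 exon
        assert (a.feature, a.gene_id) == ("promoter", "GENE1")

    def test_priority_order_is_configurable(self, toy_gene):
        other = GeneModel(
            "GENE2", GenomicInterval("chr1", 8000, 9500, strand="+"),
            (GenomicInterval("chr1", 8000, 9500, strand="+"),),
        )
        ann = GenomeAnnotation(genes=[toy_gene, other], chrom_sizes={"chr1": 100_000})
        cfg = AnnotationConfig(
            feature_priority=("exon", "intron", "promoter", "enhancer", "intergenic")
        )
        a = annotate_peak(make_peak(9000), ann, cfg)
        assert (a.feature, a.gene_id) == ("exon", "GENE2")

    def test_tie_broken_by_smallest_tss_distance_then_gene_id(self):
        g1 = GeneModel("B_GENE", GenomicInterval("chr1", 10000, 15000, strand="+"))
        g2 = GeneModel("A_GENE", GenomicInterval("chr1", 9000, 14000, strand="-"))
        ann = GenomeAnnotation(genes=[g1, g2], chrom_sizes={"chr1": 100_000})
        # summit 11000: promoter of neither; intron of both.
        # |d| to B_GENE TSS (10000) = 1000; to A_GENE TSS (13999) = 2999.
        a = annotate_peak(make_peak(11000), ann)
        assert (a.feature, a.gene_id, a.tss_distance) == ("intron", "B_GENE", 1000)

    def test_enhancer_links_nearest_gene_within_radius(self, toy_gene):
        enh = GenomicInterval("chr1", 39500, 40500)
        ann = GenomeAnnotation(
            genes=[toy_gene], enhancers=[enh], chrom_sizes={"chr1": 200_000}
        )
        a = annotate_peak(make_peak(40000), ann)  # 30 kb from TSS 10000
        assert (a.feature, a.gene_id) == ("enhancer", "GENE1")
        assert a.tss_distance == 30000

    def test_enhancer_with_no_gene_in_radius_is_unlinked(self):
        enh = GenomicInterval("chr1", 39500, 40500)
        ann = GenomeAnnotation(genes=[], enhancers=[enh], chrom_sizes={"chr1": 200_000})
        a = annotate_peak(make_peak(40000), ann)
        assert (a.feature, a.gene_id, a.tss_distance) == ("enhancer", None, None)

    def test_unknown_chromosome_is_intergenic_with_warning(self, toy_annotation, caplog):
        with caplog.at_level("WARNING"):
            a = annotate_peak(make_peak(500, chrom="chrUn"), toy_annotation)
        assert a.feature == "intergenic"
        assert any("absent from annotation" in r.message for r in caplog.records)

    @given(
        tss=st.integers(10_000, 90_000),
        offset=st.integers(-2000, 499),
        strand=st.sampled_from("+-"),
    )
    def test_sign_convention_inside_promoter(self, tss, offset, strand):
        """A summit at signed offset d from the TSS reports tss_distance d."""
        if strand == "+":
            iv = GenomicInterval("chr1", tss, tss + 5000, strand="+")
        else:
            iv = GenomicInterval("chr1", tss - 4999, tss + 1, strand="-")
        gene = GeneModel("G", iv)
        ann = GenomeAnnotation(genes=[gene], chrom_sizes={"chr1": 200_000})
        summit = tss + offset if strand == "+" else tss - offset
        a = annotate_peak(make_peak(summit), ann)
        assert a.tss_distance == offset
        if offset < 0:
            assert a.feature == "promoter"  # upstream is promoter-only


class TestAnnotateSet:
    def test_four_peak_fixture_distribution(self, toy_annotation):
        peaks = make_peakset("p", [9000, 10900, 10500, 50000])
        _, dist = annotate_set(peaks, toy_annotation)
        assert dist["fractions"] == {
            "promoter": 0.25, "enhancer": 0.0, "exon": 0.25,
            "intron": 0.25, "intergenic": 0.25,
        }

    def test_all_in_one_promoter(self, toy_annotation):
        peaks = make_peakset("p", [9000, 9100, 9200])
        _, dist = annotate_set(peaks, toy_annotation)
        assert dist["fractions"]["promoter"] == 1.0

    def test_empty_set_flagged_undefined(self, toy_annotation, caplog):
        with caplog.at_level("WARNING"):
            _, dist = annotate_set(make_peakset("p", []), toy_annotation)
        assert all(v is None for v in dist["fractions"].values())

    @pytest.mark.parametrize("seed", range(20))
    def test_tree_annotation_equals_linear_scan_oracle(self, seed):
        cfg = SimConfig(
            genome_length=2_000_000, n_genes=30, n_enhancers=10,
            n_peaks_a=10, n_peaks_b=10, seed=seed,
        )
        ann = gen_annotation(cfg)
        acfg = AnnotationConfig()
        rng = np.random.default_rng(seed)
        peaks = make_peakset("p", sorted(rng.choice(2_000_000, 100, replace=False).tolist()))
        assignments, dist = annotate_set(peaks, ann, acfg)
        assert len(assignments) == 100
        assert sum(dist["fractions"].values()) == pytest.approx(1.0)
        for p, a in zip(peaks, assignments):
            feature, gid, d = naive_annotate(p, ann, acfg)
            assert (a.feature, a.gene_id, a.tss_distance) == (feature, gid, d), p.summit


class TestAssignTargetGenes:
    def test_no_peaks_no_targets(self):
        assert assign_target_genes([]) == set()

    def test_gene_hit_twice_counted_once(self, toy_annotation):
        peaks = make_peakset("p", [9000, 10500])  # promoter + intron of GENE1
        assignments, _ = annotate_set(peaks, toy_annotation)
        assert assign_target_genes(assignments) == {"GENE1"}

    def test_linked_enhancer_contributes_gene(self, toy_gene):
        enh = GenomicInterval("chr1", 39500, 40500)
        ann = GenomeAnnotation(
            genes=[toy_gene], enhancers=[enh], chrom_sizes={"chr1": 200_000}
        )
        assignments, _ = annotate_set(make_peakset("p", [40000]), ann)
        assert assign_target_genes(assignments) == {"GENE1"}

    def test_unlinked_and_intergenic_excluded(self):
        assignments = [
            FeatureAssignment("p1", "intergenic"),
            FeatureAssignment("p2", "enhancer"),
        ]
        assert assign_target_genes(assignments) == set()


def test_promoter_window_orientation():
    cfg = AnnotationConfig(promoter_up=2000, promoter_down=500)
    plus = GeneModel("P", GenomicInterval("chr1", 10000, 12000, strand="+"))
    assert promoter_window(plus, cfg) == (8000, 10500)
    minus = GeneModel("M", GenomicInterval("chr1", 10000, 12000, strand="-"))
    # TSS 11999: summits with tss-summit in [-2000, 500) are (11499, 14000]
    assert promoter_window(minus, cfg) == (11500, 14000)


def test_annotation_index_reused_across_peaks(toy_annotation):
    index = AnnotationIndex(toy_annotation, AnnotationConfig())
    a1 = annotate_peak(make_peak(9000), toy_annotation, index=index)
    a2 = annotate_peak(make_peak(10500), toy_annotation, index=index)
    assert (a1.feature, a2.feature) == ("promoter", "intron")
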