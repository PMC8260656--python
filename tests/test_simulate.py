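"""Generator correctness: determinism, planted structure, ground truth."""

from __future__ import annotations

import filecmp

import numpy as np
import pytest

from cobind.core import GenomeAnnotation
from cobind.differential import attenuation_slope, de_filter
from cobind.simulate import (
    CapacityError,
    SimConfig,
    gen_annotation,
    gen_cooccupancy_peaks,
    gen_de_tables,
    gen_expression,
    simulate_to_dir,
)

SMALL = dict(
    genome_length=2_000_000,
    n_genes=50,
    n_enhancers=20,
    n_peaks_a=200,
    n_peaks_b=100,
)


class TestAnnotationGenerator:
    def test_gene_spans_never_overlap_brute_force(self):
        cfg = SimConfig(genome_length=10_000_000, n_genes=100, n_enhancers=0, seed=3)
        ann = gen_annotation(cfg)
        assert len(ann.genes) == 100
        spans = [(g.chrom, g.interval.start, g.interval.end) for g in ann.genes]
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                ci, si, ei = spans[i]
                cj, sj, ej = spans[j]
                assert ci != cj or ei <= sj or ej <= si

    def test_no_genes_gives_enhancers_only(self):
        ann = gen_annotation(SimConfig(**{**SMALL, "n_genes": 0}, seed=0))
        assert ann.genes == [] and len(ann.enhancers) == 20

    def test_deterministic_given_seed(self):
        a1 = gen_annotation(SimConfig(**SMALL, seed=7))
        a2 = gen_annotation(SimConfig(**SMALL, seed=7))
        assert a1.genes == a2.genes and a1.enhancers == a2.enhancers

    def test_enhancers_avoid_genes_and_promoters(self):
        from cobind.annotate import AnnotationConfig, promoter_window

        cfg = SimConfig(**SMALL, seed=1)
        acfg = AnnotationConfig()
        ann = gen_annotation(cfg, acfg)
        forbidden = []
        for g in ann.genes:
            forbidden.append((g.chrom, g.interval.start, g.interval.end))
            lo, hi = promoter_window(g, acfg)
            forbidden.append((g.chrom, lo, hi))
        for e in ann.enhancers:
            for chrom, lo, hi in forbidden:
                assert e.chrom != chrom or e.end <= lo or hi <= e.start

    def test_infeasible_gene_load_raises_capacity_error(self):
        with pytest.raises(CapacityError):
            gen_annotation(
                SimConfig(genome_length=50_000, n_genes=100, n_enhancers=0, seed=0)
            )

    def test_exon_counts_in_range(self):
        ann = gen_annotation(SimConfig(**SMALL, seed=2))
        assert all(2 <= len(g.exons) <= 6 for g in ann.genes)


class TestPeakGenerator:
    def test_rho_one_tiny_scale_summits_coincide(self):
        cfg = SimConfig(**SMALL, rho=1.0, offset_scale=1e-9, seed=0)
        ann = gen_annotation(cfg)
        _, _, planted = gen_cooccupancy_peaks(cfg, ann)
        assert len(planted) == cfg.n_peaks_b
        assert all(p["distance"] == 0 for p in planted)

    @pytest.mark.parametrize("seed", range(3))
    def test_planted_pairs_within_window(self, seed):
        cfg = SimConfig(**SMALL, rho=0.5, seed=seed)
        ann = gen_annotation(cfg)
        set_a, set_b, planted = gen_cooccupancy_peaks(cfg, ann)
        assert len(planted) == round(cfg.rho * cfg.n_peaks_b)
        a_by_name = {p.name: p for p in set_a}
        b_by_name = {p.name: p for p in set_b}
        for pair in planted:
            pa, pb = a_by_name[pair["a_name"]], b_by_name[pair["b_name"]]
            assert pa.chrom == pb.chrom
            assert abs(pa.summit - pb.summit) == pair["distance"] <= cfg.window

    def test_summits_inside_intervals_and_names_unique(self):
        cfg = SimConfig(**SMALL, seed=5)
        ann = gen_annotation(cfg)
        set_a, set_b, _ = gen_cooccupancy_peaks(cfg, ann)
        for ps in (set_a, set_b):
            assert all(p.interval.contains(p.summit) for p in ps)


class TestExpressionGenerator:
    def test_active_fraction_one_all_above_threshold(self):
        cfg = SimConfig(**SMALL, active_fraction=1.0, seed=0)
        ann = gen_annotation(cfg)
        expr, _, truth = gen_expression(cfg, ann)
        assert all(truth.values())
        assert (expr["value"] >= cfg.expr_threshold).all()

    def test_values_separate_exactly_at_threshold(self):
        cfg = SimConfig(**SMALL, seed=1)
        ann = gen_annotation(cfg)
        expr, _, truth = gen_expression(cfg, ann)
        values = dict(zip(expr["gene_id"], expr["value"]))
        for gid, active in truth.items():
            assert (values[gid] >= cfg.expr_threshold) == active

    def test_mark_expression_concordance_near_planted_probability(self):
        cfg = SimConfig(
            genome_length=100_000_000, n_genes=2000, n_enhancers=0,
            n_peaks_a=10, n_peaks_b=10, mark_prob=0.9, seed=2,
        )
        ann = gen_annotation(cfg)
        _, marks, truth = gen_expression(cfg, ann)
        n_active = sum(truth.values())
        n_inactive = len(truth) - n_active
        act_frac = len(marks["H3K4me3"]) / n_active
        rep_frac = len(marks["H3K27me3"]) / n_inactive
        se = 3 * np.sqrt(0.9 * 0.1 / min(n_active, n_inactive))
        assert abs(act_frac - 0.9) < se
        assert abs(rep_frac - 0.9) < se

    def test_marks_land_in_promoter_windows(self):
        from cobind.annotate import promoter_window, AnnotationConfig

        cfg = SimConfig(**SMALL, seed=3)
        ann = gen_annotation(cfg)
        _, marks, _ = gen_expression(cfg, ann)
        windows = {
            g.gene_id: (g.chrom, *promoter_window(g, AnnotationConfig()))
            for g in ann.genes
        }
        for ps in marks.values():
            for p in ps:
                gid = p.name.split("_", 1)[1]
                chrom, lo, hi = windows[gid]
                assert p.chrom == chrom and lo <= p.summit < hi


class TestDETableGenerator:
    def test_attenuation_one_noiseless_tables_identical(self):
        cfg = SimConfig(**SMALL, attenuation=1.0, noise_sd=0.0, seed=0)
        ann = gen_annotation(cfg)
        wt, mut, _ = gen_de_tables(cfg, ann)
        assert np.array_equal(wt["log2fc"].values, mut["log2fc"].values)

    def test_planted_modulated_set_recovered_exactly(self):
        cfg = SimConfig(**SMALL, noise_sd=0.0, seed=1)
        ann = gen_annotation(cfg)
        wt, _, modulated = gen_de_tables(cfg, ann)
        up, down = de_filter(wt, 0.37, 0.05)
        assert up | down == modulated
        assert len(modulated) == round(cfg.frac_modulated * len(ann.genes))

    def test_adj_p_monotone_in_abs_lfc(self):
        cfg = SimConfig(**SMALL, seed=2)
        ann = gen_annotation(cfg)
        wt, _, _ = gen_de_tables(cfg, ann)
        df = wt.assign(mag=wt["log2fc"].abs()).sort_values("mag")
        assert (df["adj_p"].diff().dropna() <= 1e-12).all()

    def test_ols_recovers_planted_slope(self):
        cfg = SimConfig(
            genome_length=100_000_000, n_genes=5000, n_enhancers=0,
            n_peaks_a=10, n_peaks_b=10, attenuation=0.44, noise_sd=0.3, seed=0,
        )
        ann = gen_annotation(cfg)
        wt, mut, _ = gen_de_tables(cfg, ann)
        slope, _, n = attenuation_slope(wt, mut)
        assert n == 5000
        assert slope == pytest.approx(0.44, abs=0.05)


class TestFileEmission:
    def test_byte_identical_across_runs(self, tmp_path):
        cfg = SimConfig(**SMALL, seed=9)
        p1 = simulate_to_dir(cfg, tmp_path / "run1")
        p2 = simulate_to_dir(cfg, tmp_path / "run2")
        assert set(p1) == set(p2)
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_emitted_files_load_back(self, tmp_path):
        from cobind import io as iio

        cfg = SimConfig(**SMALL, seed=4)
        paths = simulate_to_dir(cfg, tmp_path / "sim")
        assert len(iio.read_narrowpeak(paths["peaks_a"])) == cfg.n_peaks_a
        ann = iio.read_gene_annotation(paths["genes"], dialect="tsv")
        assert len(ann.genes) == cfg.n_genes
        assert len(iio.read_expression_table(paths["expression"])) == cfg.n_genes
        assert len(iio.read_de_table(paths["de_wt"])) == cfg.n_genes


def test_chance_rate_matches_poisson_formula():
    from math import exp

    from cobind.simulate import chance_match_rate, expected_matched_fraction

    cfg = SimConfig(rho=0.25)
    expected = 1 - exp(-cfg.n_peaks_a * 2 * cfg.window / cfg.total_genome)
    assert chance_match_rate(cfg) == pytest.approx(expected)
    assert expected_matched_fraction(cfg) == pytest.approx(
        0.25 + 0.75 * expected
    )


def test_peaks_only_need_chrom_sizes_from_annotation():
    cfg = SimConfig(n_peaks_a=100, n_peaks_b=50, seed=0)
    ann = GenomeAnnotation(chrom_sizes={"chr1": cfg.genome_length})
    set_a, set_b, _ = gen_cooccupancy_peaks(cfg, ann)
    assert len(set_a) == 100 and len(set_b) == 50
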