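# cobind

Co-occupancy analysis of two ChIP-seq peak sets: summit-window matching of a
transcription factor against a cofactor, genomic annotation of the co-occupied
sites, histone-mark / expression-based classification of the target genes, and
the downstream differential-expression filtering, overlap and signature
procedures. A synthetic-data generator plants ground truth for every stage, so
the whole pipeline is testable without any external download.

## The problem

When a transcription factor (e.g. ERG) and a chromatin cofactor (e.g. EZH2)
bind chromatin together, their called peaks land at nearly the same genomic
positions. Given two peak sets with per-peak summits, `cobind` answers:

* **Where do the two factors co-occupy the genome?** Two peaks form a
  co-occupied site when their summits lie within a window *w* (default
  ≤ 1 kb). Matching is one-to-one: candidate pairs are ranked by summit
  distance and accepted greedily, giving a single deterministic site count
  *n* that is reported as a percentage of each set, 100·*n*/*n*_A and
  100·*n*/*n*_B. The concentration of summit distances is summarized by the
  empirical CDF at chosen thresholds (20, 200, 1000 bp).
* **What does each site hit?** Each peak (or site) is classified by its
  summit into promoter / enhancer / exon / intron / intergenic, with a signed
  distance to the linked gene's TSS; distinct genes with a non-intergenic hit
  form the co-occupied target-gene set.
* **Are the targets transcriptionally active?** A target is active when its
  expression value passes a cutoff, and per-mark fractions report how many
  targets carry activating (H3K4me3-like) vs repressive (H3K27me3-like)
  promoter marks.
* **How do two transcriptional responses compare?** Modulated genes are
  selected at |log2FC| > 0.37 and adjusted p < 0.05 (strict), the overlap of
  two modulated sets is scored with an upper-tail hypergeometric test, the
  global attenuation of one response relative to another is the OLS slope of
  the paired log2 fold changes, and a top-*k* signature (default *k* = 50 at
  cohort p < 0.1) extracts the most significantly deregulated targets.

## Worked example

The published-count worked example and a fully simulated run:

```python
from cobind import SimConfig, RunConfig, run_pipeline
from cobind.cooccupancy import summarize_fractions

# 3567 co-occupied sites against 48,274 TF and 14,780 cofactor peaks
s = summarize_fractions(3567, 48274, 14780)
print(s.percent_a, s.percent_b)          # 7.4 24.1

report = run_pipeline(RunConfig(sim=SimConfig(seed=0)))
co = report["cooccupancy"]
print(co["n_sites"], co["percent_a"], co["percent_b"])
```

prints

```
7.4 24.1
622 12.4 31.1
```

7.4 / 24.1 are the co-occupied sites as a percentage of each peak set
(one-decimal, half-up). The simulated run plants a co-localized fraction of
0.25 for 2000 cofactor peaks against 5000 anchors on 100 Mb; the recovered
fraction 0.311 is the planted 0.25 plus the analytic chance of a uniform
summit landing within 1 kb of an anchor (≈ 0.095 of the remainder). The same
report carries the distance CDF (74.6% of sites within 200 bp under the
default 100 bp Laplace offset scale), the feature-class distribution, 149
target genes of which 62% are active (planted: 66%), and the attenuation
slope 0.44 (planted: 0.44).

The same stages are exposed on the command line:

```bash
cobind simulate --seed 0 --out-dir sim/
cobind colocalize --a sim/peaks_a.narrowPeak --b sim/peaks_b.narrowPeak \
    --window 1000 --out sites.tsv
cobind run --out report.json        # full simulated pipeline
cobind report report.json
```

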