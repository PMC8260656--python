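# Methods

## Co-occupancy model

Two peak sets A (anchor transcription factor, size n_A) and B (cofactor,
size n_B) are compared through their summits — the single-base position of
maximal estimated enrichment that MACS-style callers report as an offset in
narrowPeak column 10. A pair (a, b) on the same chromosome is a candidate
co-occupied site when |summit_a − summit_b| ≤ w, with w = 1000 bp by default
and the boundary inclusive.

Because a printed site count must be a single number that can serve as a
numerator against both set sizes, matching is **one-to-one**: candidates are
sorted by (distance, summit_a, summit_b) and accepted greedily while both
peaks are unmatched. This is deterministic, order-independent, and checkable
against an all-pairs oracle; the test suite verifies exact site-for-site
agreement between the sorted-sweep implementation (O((n_A+n_B) log n_A + k)
for k candidates) and the brute-force matcher on hundreds of random
instances. Matched percentages are reported half-up at one decimal; raw
fractions are kept unrounded alongside.

The **proximal/distal partition** used to feed motif analysis is a
different operation: a cofactor peak is proximal when *any* anchor summit
lies within w (an existence test, many-to-one). A partition of one set must
cover it, which a one-to-one matching does not; the two operations are
deliberately separate functions.

Summit-distance concentration is summarized as an empirical CDF evaluated
at thresholds (default 20, 200, 1000 bp). The CDF is monotone and reaches 1
at the matching window; for an empty result the fractions are reported as
undefined rather than zero.

## Annotation model

Peaks are classified by **summit position**, not interval overlap: the
summit is the point estimate of the binding site, and a point query gives
every peak exactly one class, so class fractions always sum to 1. Feature
classes are promoter, enhancer, exon, intron, intergenic.

* Promoter: signed TSS distance d ∈ [−promoter_up, promoter_down) in gene
  orientation, defaults −2000/+500 bp — a common promoter convention,
  surfaced in `AnnotationConfig` so reanalyses can match other choices.
  d = summit − TSS on + genes and TSS − summit on − genes, so upstream is
  always negative.
* Exon / intron: summit inside the gene span, in or out of an exon of that
  gene.
* Enhancer: supplied intervals (enhancer calls come from external chromatin
  data and are inputs, not inferences); an enhancer peak links to the
  nearest TSS within 50 kb, or to no gene.
* Conflicts are resolved by a configurable priority, default
  promoter > enhancer > exon > intron > intergenic (most specific regulatory
  class first); ties inside a class go to the smallest |TSS distance|, then
  lexicographic gene id, making annotation a deterministic function of its
  inputs. The interval-tree index is validated against a linear-scan oracle.

Target genes are the distinct genes with ≥ 1 non-intergenic, gene-linked
assignment. A gene "bears" a histone mark when a mark-peak summit falls in
its promoter window (same semantics as annotation); a target is **active**
when its expression value is ≥ a cutoff (default 1.0 in the unit of the
supplied table — the upstream RNA-seq processing behind a published
active/inactive split is rarely stated, so the cutoff is config-exposed
rather than hidden). Genes missing from the expression table count as
inactive, with a logged warning.

## Differential-expression procedures

DE model fitting is upstream; inputs are per-gene log2FC with adjusted p.

* Modulated genes: |log2FC| > 0.37 and adjusted p < 0.05, both strict, as
  thresholds of this form are conventionally printed; boundary behaviour is
  pinned by tests.
* Overlap of two modulated sets: upper-tail hypergeometric probability
  P(X ≥ k) over a stated gene universe — the standard test for gene-set
  overlap, verified against exhaustive enumeration with exact rational
  arithmetic for universes ≤ 15.
* Attenuation: OLS slope of mutant on wild-type log2FC over shared genes
  (optionally restricted to genes modulated in either contrast). A slope
  < 1 means a globally weakened response.
* Signature: cohort DE filtered to p < 0.1 (adjusted by default; a raw-p
  switch exists because published cutoffs often leave this ambiguous),
  intersected with the target set, ranked by p with ties broken by |log2FC|
  descending then gene id, truncated to k = 50. The tie-break chain makes
  the signature a deterministic function of its inputs.

## Synthetic cohort

The generator's defaults are the package's study conditions: one 100 Mb
chromosome, 2000 genes, 300 enhancers, n_A = 5000 anchor and n_B = 2000
cofactor peaks, planted co-localized fraction ρ = 0.25, Laplace offset scale
100 bp inside the 1 kb window, active fraction 0.66 with 0.9 mark
concordance, attenuation slope 0.44 with residual s.d. 0.3, and 10% of
genes modulated. Each stage draws from its own RNG stream derived from
(seed, stage offset), so outputs are byte-identical across runs and
regenerating one stage never shifts another.

* **Genes** are placed without overlap by stick-breaking: the slack left
  after summing the span lengths is split uniformly into gaps, which always
  succeeds when the spans fit (a `CapacityError` otherwise) and samples
  arrangements uniformly enough for these purposes. Spans are 2–20 kb with
  2–6 exons cut at sorted random positions; enhancers (200–1000 bp) are
  rejection-sampled into space free of gene spans and resolved promoter
  windows.
* **Peaks**: A summits uniform; ⌈ρ·n_B⌉ B summits sit at distinct A summits
  plus a Laplace(0, 100 bp) offset truncated (by resampling) to ±w, so every
  planted pair is recoverable at window w; the rest are uniform. Intervals
  extend 75–250 bp on each side of the summit. The Laplace law concentrates
  offsets near zero the way jointly bound factors do, with one parameter.
* **Chance co-localization** follows the Poisson approximation: a uniform
  summit has probability c = 1 − exp(−n_A·2w/G) of an anchor within w. The
  expected matched fraction of B is ρ + (1−ρ)·c — the chance term applies
  only to the non-planted remainder, since a planted peak cannot also
  chance-match. The Poisson rate describes the existence test exactly; the
  one-to-one matched count is bounded by it and falls short only by rare
  anchor collisions, which the tests bound explicitly.
* **Expression**: genes are independently active with the configured
  probability; active values are strictly above the cutoff (lognormal),
  inactive strictly below (uniform), so classification recovers the planted
  states exactly and the only error in the recovered active fraction is
  binomial sampling. Marks are planted at 0.9 concordance with state.
* **DE tables**: wild-type log2FC is Normal(0, 1.2) background truncated at
  the significance boundary of the monotone p map (|log2FC| < 1.2, where
  adj p = exp(−|log2FC|·ln 20 / 1.2) crosses 0.05), with a spiked modulated
  subset strictly above it — the truncation is what makes the planted
  modulated set *exactly* the filter-passing set, at the cost of clipped
  background tails. Mutant log2FC = slope·WT + Normal(0, noise_sd), so OLS
  on the shared genes is unbiased for the planted slope.

What the generator does **not** emulate: read-level noise, GC/mappability
bias, peak-width/signal correlation, correlated gene activity along the
genome, and realistic p-value distributions from a fitted model. Passing
recovery tests therefore demonstrates the correctness of the matching,
annotation, classification and regression machinery under known truth — not
robustness to the artifacts of real ChIP-seq or microarray data.

## Numerical choices and degenerate inputs

* Reported percentages use decimal half-up rounding (one decimal for set
  percentages, whole percent for the active fraction) to match how such
  numbers are conventionally printed; raw values are always retained.
* Summit fallback for narrowPeak offset −1: interval midpoint, floored.
* Duplicate peak names are auto-suffixed with an ordinal and logged;
  structural format violations (bad coordinates, out-of-range summit
  offsets) raise errors naming the line.
* Empty peak sets, empty DE tables and empty signatures are valid results;
  empty *target* sets for activity classification are an error (there is
  nothing to classify), and undefined fractions are reported as null, never
  as 0.
* Problem sizes in the test and acceptance runs (50-seed recovery at
  n_B = 2000, 5000-gene regression, 20-genome annotation oracle sweeps) were
  chosen so each statistical envelope (3 s.e.) is a few-fold smaller than
  the tolerance it checks while the full suite stays fast.

## Known limitations

* One-to-one greedy matching is a documented choice; the deduplication rule
  behind any particular published site count is typically unstated, so exact
  counts from reprocessed public data may differ at the margin.
* Enhancer–gene linkage is nearest-TSS within a radius; no loop/Hi-C-aware
  linking.
* The annotator classifies by summit only; peaks spanning a feature boundary
  contribute their summit's class alone.
* The DE generator's truncated background trades tail realism for exact
  planted recovery; slope recovery is unaffected, but the table's |log2FC|
  distribution is not what a fitted model would produce.
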