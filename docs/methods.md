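# Methods

This note documents the models, estimators, and numerical choices behind
`germreset`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and input model

All internal coordinates are 0-based, half-open. Readers convert from the
1-based conventions of exchange formats (Bismark coverage) at the
boundary; nothing downstream reasons about offsets. Per-CpG calls are
assumed strand-collapsed: counts from both strands of a CpG dyad are
summed onto the plus-strand cytosine. PBAT libraries are strand-
asymmetric, and per-site levels in this field are reported per CpG site,
so collapsing is the right default; duplicate positions in an input file
are treated as corruption and rejected rather than silently merged.

## Region methylation estimator

The methylation level of any interval is coverage-weighted:

    level = sum(meth_i) / sum(meth_i + unmeth_i)

over the CpGs *i* inside the interval whose depth reaches `min_depth`
(default 5×). CpGs below the depth cutoff are excluded from numerator and
denominator alike, mirroring the "≥ 5×" language of the filters rather
than entering unweighted. An interval is *missing* (never zero) when it
holds fewer than `min_cpgs` CpGs (default 5) or when fewer than
`min_covered_frac` (default 20%) of its CpGs reach the depth cutoff. The
coverage-weighted form is robust at the low, uneven depth of low-input
bisulfite libraries; when all depths are equal it reduces exactly to the
mean of per-CpG levels (property-tested).

Tiles are sliding 1 kb windows at a 500 bp step — "overlapping 1 kb
tiles" with the conventional half-overlap, since the step is otherwise
unspecified. A short terminal window is appended (and flagged) only when
the last full window does not already reach the chromosome end. Repeat
bookkeeping per tile records overlap bp and a repeat-free flag (no
annotated repeat within 1 kb).

Promoters default to TSS −1,000/+500 bp, strand-aware; the definition is
configurable because every coupling analysis inherits it. Promoter CpG
classes use the observed/expected CpG ratio over the promoter sequence
(HCP: ratio ≥ 0.75 and GC ≥ 0.55; LCP: ratio < 0.48; else ICP).

## Demethylation dynamics

Distribution summaries (median, quartiles, histogram densities) are
computed over passing tiles only. Pairwise stage comparisons fit ordinary
least squares on the common passing tiles and bin the pairs on a fixed
50×50 grid over [0,1]². Tile dynamics along a stage axis are clustered
with k-means (k-means++ initialisation, 10 restarts, fixed seed,
Euclidean distance, complete-case rows; clusters reported in order of
decreasing centroid mean so labels are reproducible). Samples are
clustered by average-linkage hierarchical clustering on Euclidean
distance over tiles passing in every sample. Display-only columns (e.g.,
a low-coverage blastocyst sample) can be attached to a figure without
entering the distance computation; the clustering API takes an explicit
sample list for exactly this reason.

Cross-species comparison consumes a precomputed 1:1 tile (or gene)
ortholog map; chain-file liftover is deliberately out of scope, since
conservation mapping is an upstream, assembly-specific step. Joined rows
are mapped pairs that pass the coverage filter in every sample of both
species and are repeat-free on both sides.

## Escapee caller

Demethylation escapees are regions retaining ≥ 30% methylation inside a
globally hypomethylated methylome. The caller:

1. pools the supplied tracks and computes the genome-wide background rate
   (spike-in excluded); a warning is raised if the background itself
   exceeds the 30% threshold, since the test is designed for
   hypomethylated genomes;
2. tests each 1 kb / 500 bp window's pooled counts one-sided against the
   background (binomial), BH-corrects across testable windows, and keeps
   windows with q < 0.01 *and* coverage-weighted level ≥ 0.30 — the mean
   filter is the stated criterion and dominates behaviour;
3. merges candidate windows within 1 kb;
4. refines merged boundaries to the outermost position where the local
   3-CpG, depth-filtered pooled level still reaches half the call
   threshold. Window merging overshoots the true edge by up to a window;
   the half-threshold on a 3-CpG smooth separates a hypomethylated flank
   (~3%) from a boundary window mixing flank and region (~30%+) sharply,
   and the full ≥ 30% mean filter is re-asserted on the refined region;
5. keeps a merged region only if its coverage-weighted mean is ≥ 0.30 in
   the pooled data and in every "required" individual track, mirroring
   calling on individual and pooled methylomes.

Both the raw-window and merged median region sizes are reported, since
printed medians in the literature may refer to either. The binomial/BH
window test is this package's own, documented choice of
"significance" — simple, count-based, and subordinate to the explicit
30% filter.

Classification: repeat_rich (repeat overlap ≥ 10% of region length),
repeat_poor (< 10%); repeat_free additionally requires no repeat within
1 kb — so repeat_free ⊆ repeat_poor and rich/poor partition the set
(invariant-tested). Feature annotation labels each escapee with every
overlapping class (enhancer, CGI, promoter, gene body) or intergenic.
Inter-individual variation uses the sample (n−1) standard deviation —
appropriate at n = 4 individuals — after requiring ≥ 10 CpGs and ≥ 20%
of CpGs at 5× in *all* individuals and ≥ 40% methylation in at least one.
Gene assignment requires a qualifying escapee to overlap the TSS–TES
span; homolog overlap between two species' escapee-gene sets is tested
against the ortholog universe with the hypergeometric upper tail
P(X ≥ k) (exact-enumeration-verified for small universes). Annotation
enrichment places length-matched random regions uniformly per chromosome
(no GC matching by default) and reports observed/expected overlap
fraction with an add-one empirical p.

## Differential expression and coupling

Size factors are median-of-ratios over features positive in all samples.
The DE statistic is a negative-binomial Wald test on normalized group
means: per-gene method-of-moments dispersion pooled across the two
groups (floor 0.01), *moderated* toward the across-gene median with a
prior weight of 6 df, delta-method standard error on log(mean + 1), and
a Student-t reference with df = pooled residual df + prior df − 1.
The moderation and the t reference are the package's own calibration of
the statistic: with n = 2–3 per group, the raw per-gene moment estimate
is far too noisy to test against (null simulations give ~1.5% rejections
with a t(n−2) reference and ~17% with a normal one), whereas the
moderated form holds the nominal 5% level (observed 4–6% on 2,000-gene
NB nulls at 2 vs 2) and detects an 8-fold change at mean 100, dispersion
0.1, 3 vs 3 with ~99% power at q < 0.05. Fold changes use pseudocount 1,
so zero counts stay finite; p-value thresholds in the coupling
classification are raw p (as printed in the figure legends this package
mirrors), with BH q reported alongside.

Coupling quadrants restrict to genes with > 20% promoter methylation in
either sample and log2 normalized counts > 3 in either sample, then
cross the DE call (|log2FC| > 2, p < 0.05) with the sign of the promoter
methylation change. The KRAB-ZFP panel is the same classification
restricted to flagged genes, plus hierarchical clustering of their
expression; it reports how many KRAB-ZFPs are upregulated in the target
sample and how many of those had a methylated promoter in the reference.
Genes and repeat loci share one code path — the feature table is
agnostic — so the repeat-locus quadrants (up / down / low-expressed at
log2 counts < 0) reuse the same thresholds.

## Motif scanning

PWMs are 4×L base-probability matrices scored as log-odds against a
uniform background with a small pseudocount; the hit threshold defaults
to 80% of the maximum achievable score, which is scale-free. Both strands
are scanned (reverse-complemented matrix in plus coordinates) and hits
deduplicate by (position, strand). The default panel carries a
consensus-derived ZFP57-style hexamer (TGCCGC, 0.91 on consensus bases);
real analyses should supply measured matrices via the 4×L TSV format.
Enrichment is hit density (hits/kb) in the regions over the mean density
of length-matched random placements; per-class reports exclude classes
with ≤ 700 member copies.

## Synthetic study generator

The generator is first-class, tested code that realises the statistical
structure the analysis assumes:

* **Genome**: one 10 Mb autosome, a 5 Mb X, and a 48,502 bp unmethylated
  spike-in contig. CpG sites at mean 100 bp spacing with 10 bp-spaced
  clusters at CpG islands; optional random sequence with "CG" planted at
  every CpG site. Features (genes with promoters/CGIs, repeat loci of ten
  families with age ranks, a 22-ICR panel, enhancers, escapees of all
  three classes) are laid out non-overlapping across the chromosome with
  randomized gaps, and every plant is recorded in the ground-truth
  ledger.
* **Methylome model**: a latent methylation field piecewise-constant on
  5 kb blocks, Beta-distributed around the stage's latent mean
  (concentration 8); planted features override the field; per-CpG levels
  are Beta around the local mean (concentration 60); depth is
  negative-binomial (mean 8×, shape 4); methylated counts are binomial
  with a 0.4% non-conversion admixture; the spike contig is unmethylated
  apart from non-conversion.
* **Median calibration**: published stage values (ESC 80%, soma 82%,
  Wk5.5 16%, Wk7 4.5%, Wk9 5%, sperm 87%, ICM ~37%) are medians of
  *coverage-filtered tiles*, not raw means, so the generator bisects each
  stage's latent mean until the simulated filtered-tile median hits the
  configured value. The simulator draws all randomness as quantile
  transforms of per-substream uniforms, and the bisection evaluates the
  very same draws, so the realized median matches the target up to the
  solver tolerance at any seed. Benchmark configurations whose stage
  values are plain means set `calibrate_medians=False`.
* **Planted structure**: escapees at 50% mean methylation in hPGC stages
  (with per-individual jitter, sd 0.10, for the variation analysis) and
  fate-typed gamete/blastocyst levels; 6 of 22 ICRs retained > 20% at
  Wk5.5 with 2 evaders persisting through Wk7–Wk9; 30 Xi-methylated
  X-CGI promoters partially methylated (50%) in female ESC/soma and
  hypomethylated in female germline stages; repeat families with
  germline retention declining in evolutionary age (SVA heterogeneous
  U(0.05, 0.95) — half the loci above 30%; L1HS low, as the youngest-L1
  exception).
* **Expression**: NB counts with lognormal library factors; germline
  genes multiply their mean 8-fold where the planted promoter schedule
  drops below 20% methylation; 7 KRAB-ZFPs are germline-high, 6 of them
  with ESC-methylated promoters; SVA locus log2 mean decreases with
  planted locus methylation at slope −0.5 log2 units per unit
  methylation (with base mean 2⁹ and dispersion 0.02 this yields the
  moderate negative methylation-expression correlation, r ≈ −0.5);
  everything else is independent of methylation.
* **Species mirror**: a second genome built from the same plan with a
  different seed and prefixed chromosome/gene names; gene orthologs pair
  by (class, within-class placement order), tiles pair by coordinates,
  and 5 of the 8 escapee-host genes are shared so the homolog-overlap
  test has planted signal.

What the generator does **not** emulate: real sequence evolution of
repeat families (repeats are coordinates with attributes, not diverged
sequences), read-level artifacts (mapping bias, M-bias, duplicate reads),
context-dependent non-CpG methylation, allele-specific methylation, and
the long-range autocorrelation structure of real methylomes beyond the
5 kb block field. Passing tests therefore demonstrate that the
estimators, filters, and callers recover planted truth under the assumed
beta-binomial/NB model at realistic depth — not that they are robust to
alignment-level artifacts of real libraries.

## Problem sizes and determinism

Default analyses run on the 10 Mb + 5 Mb genome (~170k CpGs, ~30k tiles)
in seconds per stage on one core. The test suite uses a 3 Mb + 1.5 Mb
genome for multi-stage integration tests and a 2 Mb + 1 Mb genome for
the end-to-end pipeline determinism check; the escapee-caller benchmark
runs 25 seeds of a 10 Mb genome with 20 planted 2 kb regions at 50%
methylation on a uniform 3% background at 10× depth, scoring
sensitivity/precision at ≥ 50% reciprocal overlap (0.98/0.98 observed).
All randomness descends from a single root seed through named,
crc32-keyed substreams, so every artifact — including the pipeline's
`summary.json` — is byte-identical under re-run with the same config and
seed. Floats in persisted JSON are rounded to six decimals to keep the
byte-stability guarantee independent of dict ordering and accumulation
quirks.

## Known limitations

* The escapee caller's binomial window test ignores biological
  overdispersion of the background; with very deep data it will flag
  mildly elevated windows that the 30% mean filter then removes. The
  mean filter, not the test, is the effective criterion — by design.
* Boundary refinement resolves region edges to ~1 CpG (~100 bp at the
  default density); at sparse CpG spacing the reported region ends are
  correspondingly uncertain.
* The DE statistic is a calibrated approximation, not a replacement for
  full NB-GLM machinery; with larger group sizes or complex designs use
  a dedicated DE package and feed the resulting table into the coupling
  and repeat-quadrant functions, which only require (log2fc, p,
  max_log2_count).
* Size factors require at least one feature positive in all samples;
  extremely sparse matrices need prefiltering.
* Motif enrichment's uniform background does not match GC or repeat
  composition; interpret folds for GC-rich motifs accordingly.
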