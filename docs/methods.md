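# Methods

## The origin caller

The caller consumes two libraries of fixed-length single-end reads: HL
(replicated, heavy–light DNA) and LL (unreplicated, light–light DNA), as BED
intervals on a genome layout. All coordinates are 0-based half-open.

1. **Window counting.** Reads are assigned to fixed windows (default 100 bp)
   by their 5'-most coordinate. This makes each read count exactly once, so
   window counts sum to the library size; the alternative (overlap counting)
   double-counts boundary reads. The last window of a chromosome may be
   short and is treated like any other.
2. **Normalization.** Each library's counts are scaled to reads-per-million
   of its own total. The constant is immaterial — it cancels in every ratio
   — but per-library scaling is not (see *Score compression* below).
3. **Enrichment filter.** A window passes when log2(HL/LL) ≥ 2 on normalized
   counts. Windows with LL = 0 and HL > 0 pass outright: complete LL
   depletion is the highest-confidence signal, and a pseudocount would cap
   exactly the windows the assay is most certain about. Windows with HL = 0
   never pass.
4. **Island building.** Passing windows ≤ 500 bp apart are merged
   transitively; merged runs ≥ 200 bp become islands.
5. **Scoring and calling.** Both libraries are recounted over each island
   (same 5'-start rule, same totals), renormalized, and scored
   E = HL/(HL+LL). E = 1 when LL = 0; islands with no HL signal are
   discarded. An island is an origin when E ≥ 0.8 — algebraically identical
   to HL/LL ≥ 4 and to log2(HL/LL) ≥ 2 on positive counts, which ties the
   calling cut to the window filter. The threshold is inclusive (≥).
6. **Classing.** Z = (E − mean)/sd (sample sd) over the called set; origins
   are ranked by Z (ties broken by genomic coordinate for determinism) and
   cut into equal-size classes, high/medium/low for the default three, sizes
   differing by at most one.

**Saturation.** Libraries are subsampled without replacement at a set of
fractions (seeded), either jointly or with the LL library fixed, and the
caller re-run. On simulated data the curve saturates at the full call only
when the planted origins are unambiguous; origins sitting at the calling
threshold flicker in and out under subsampling noise, which is the expected
behaviour of a hard threshold, not an artefact.

### Score compression (why pool balance matters)

Because each library is normalized to its own total, every global scale
cancels and the called efficiency depends only on library *compositions*:
E_called = (f/p̄) / (f/p̄ + (1−f)/(1−p̄)), where f is the local replicated
fraction and p̄ the genome-wide mean replicated fraction (plus background).
E_called = f exactly when p̄ = 0.5, and is compressed toward 1 when the
replicated pool is small. This is a property of the scoring scheme itself:
with a sparse origin landscape the score ranks origins correctly but
overstates absolute firing probability. The simulator's reference
configuration therefore plants origins densely enough that p̄ ≈ 0.5, the
regime in which E is an unbiased estimate of f; the parameter-recovery
tests quantify accuracy in that regime and say nothing about absolute
calibration at genome-scale sparsity.

The efficiency of a call is compared against the realized replicated
fraction *over the called interval*: E is definitionally the replicated
share of the island's DNA, so this is the estimand; the single-bp value at
the planted centre differs from it by the shape of the tract-length
distribution, not by any property of the caller (at the defaults the two
agree to ~0.01).

## The simulator

Per nucleus, each planted origin fires independently with probability equal
to its efficiency. A fired origin replicates a tract on each side of its
centre with half-length `core + Exponential(tail)`, where
`core = tract_core_fraction × tract_mean × incubation_scale` (default
fraction 0.88) and the tail supplies the mean's remainder. The deterministic
core reproduces the flat plateau of complete LL depletion observed at
efficient origins; the exponential tail models non-processive fork escape.
`tract_core_fraction = 0` gives a purely memoryless (exponential) tract.
f(x) is the fraction of nuclei covering x at least once (per-nucleus tract
unions are taken before accumulating).

Reads are emitted per bp as Poisson draws:
HL rate = depth·(f·(1−bg) + (1−f)·bg), LL rate the complement, with
bg = 0.005 modelling gradient cross-contamination. Expected HL + LL rate is
`depth` everywhere. Defaults: depth 0.6 reads/bp per library (30× at 50 bp
reads), 400 nuclei, one ~200 kb chromosome with 20 origins at 10 kb spacing,
efficiencies uniform on [0.5, 1], tract_mean 3.4 kb (chosen so that
2·tract_mean·n·ē ≈ half the genome, the pool-balanced regime above). A fixed
seed yields bit-identical truth, reads and sequence.

What the simulator does *not* model: sequence-dependent firing, a
replication-timing program, firing correlations between origins or nuclei,
fragmentation-induced read-length variation, mappability or GC bias in
sequencing. Passing recovery tests therefore demonstrates correctness of
the caller's arithmetic and robustness to Poisson noise and contamination,
not robustness to the full error structure of real libraries.

`generate_sequence` produces a seeded random genome with elevated GC
(default 0.65 vs 0.40 background) inside origin tracts and an optional
planted GC-skew sign switch (C-rich left, G-rich right of each centre), for
exercising the sequence-feature code. `make_feature_benchmark` produces the
regression benchmark: iid standard-normal predictors, a response that is an
additive smooth function (linear, sine, tanh, quadratic terms) of the first
k predictors scaled to an efficiency-like range, plus Gaussian noise.

## Organisation analyses

* **Ini-domains**: origins merged transitively at edge-to-edge gap ≤ 100 kb;
  runs with ≥ 6 members kept; the domain spans first member start to last
  member end. **Clusters**: same gap rule at 30 kb within one efficiency
  class, ≥ 2 members.
* **Inter-origin distances** are midpoint-to-midpoint between consecutive
  same-class origins per chromosome (robust to unequal origin widths);
  summaries report median and IQR.
* **Overlap at tolerance**: interval a counts as intersecting B when some b
  lies within `max_dist` bp (gap of overlapping or touching intervals is 0).
  Counting is per-interval — Venn semantics — so A-only + intersect = |A|.
  Tolerances of 0, 5 and 10 kb are conventional for comparing against
  broad-zone, same-scale and point-like reference sets respectively.
* **Permutation test**: each permutation re-places every A interval
  uniformly on its own chromosome, preserving lengths, rejecting self-
  overlapping placements. p = max(#{perm ≥ obs}, 1)/n_perm — the floor at
  10,000 permutations is 10⁻⁴ — and Z = (obs − mean)/sd. Per-chromosome
  placement conditions on chromosome composition; assembly gaps and
  mappability masks are not modelled (toy genomes have none). With a
  constant permutation distribution the Z-score is reported as signed
  infinity with a warning.
* **Gene orientation**: the first gene wholly left and wholly right of the
  origin midpoint (genes overlapping the midpoint are skipped and logged)
  give divergent (−,+), convergent (+,−) or co-oriented labels. The profile
  reports the fraction of bin bp covered by + and − gene bodies around
  origin midpoints, per class. The control pool is the midpoint between
  consecutive origin midpoints (odd gaps round down); sampling is seeded,
  without replacement when the pool suffices.

## Features and model

* GC content excludes N from numerator and denominator; all-N queries are
  NaN. Skew is computed on the reference strand per origin per bin and
  averaged across origins; bins without informative bases contribute 0 and
  are flagged. Complementing a sequence negates GC skew exactly.
* The scaled coverage matrix maps each region body linearly onto a common
  bin axis (length-weighted mean per destination bin) with fixed-width
  flank bins — scale-regions semantics with 10 nt bins and 5 kb bodies by
  default. Chromosome-edge flank bins are flagged as truncated.
* GC deciles: the genome is segmented into 50 bp windows; decile boundaries
  come from the genome-wide GC distribution; each query interval is
  assigned by its midpoint window. Tied boundaries (near-uniform
  composition) are flagged as degenerate.
* Screening drops constant columns, then the later member of any pair with
  |Pearson r| > 0.85, then columns that do not raise the rank of the
  standardized matrix (exact linear combinations). The procedure is
  order-stable and idempotent.
* PCA standardizes predictors (sample sd) and excludes the response;
  eigenvalues are non-increasing and sum to the predictor count.
* The efficiency model is an RBF-kernel SVR in the kernlab parameterisation
  k(x,y) = exp(−sigma·‖x−y‖²). Defaults: seeded 70/30 split; sigma grid
  from the median pairwise squared-distance heuristic × {0.25, 0.5, 1, 2,
  4}; C grid 2⁻²…2⁸; selection by 10-fold cross-validated RMSE on the
  training set; performance reported as train/test Pearson correlation.
  The insensitivity tube is ε = 0.05, sized for a response on the [0, 1]
  efficiency scale (a 0.1 tube is wider than much of the response's spread
  and visibly caps noiseless recovery). Feature importance is permutation
  importance on the test split: mean increase in RMSE over 20 shuffles per
  feature, floored at 0 — model-agnostic and reproducible under a fixed
  seed.

## Numerical and degenerate-input conventions

Zero-LL windows pass the filter when HL > 0 (no pseudocount). Islands with
zero reads in both libraries are discarded with a warning. Zero efficiency
spread makes all Z-scores 0 and classing falls back to genomic order, with
a warning. Classing ties break by (chromosome, start). Equidistant-control
midpoints round down on odd gaps. Track values must be finite; uncovered bp
contribute 0 to track means. Problem sizes in the test suite (toy genomes
of 0.1–10 Mb, 20-origin simulations, n = 2000 model benchmark) were chosen
as the smallest at which each statistical property is stable.

## Known limitations

The caller reports absolute efficiencies faithfully only in the
pool-balanced regime (see *Score compression*); at genome-scale origin
sparsity the scores are a monotone but compressed transform of firing
probability. The permutation null does not model masked or unmappable
regions. The feature table is generic over user-supplied tracks and does
not fetch public annotation. MACS2-style model-based peak calling,
alignment and deduplication are out of scope; BAM conversion happens
upstream.
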