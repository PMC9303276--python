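# iniseq2

Calling human DNA replication origins — and scoring how efficiently each one
fires — from density-substitution sequencing libraries.

## The problem

In a density-substitution (Meselson–Stahl-style) replication assay, nascent
DNA incorporates a heavy nucleotide analogue, so semi-conservatively
replicated DNA becomes heavy–light (**HL**) while unreplicated DNA stays
light–light (**LL**). After gradient separation and sequencing of both
fractions, a replication origin shows up as a locus where HL reads are
enriched *and* LL reads are depleted — at the strongest origins the LL
fraction is depleted completely, meaning essentially every nucleus replicated
the locus. Because the LL depletion is informative, the LL library cannot be
treated as a conventional input for peak calling; instead both fractions are
combined into an efficiency score.

This package implements the full analysis:

* **`iniseq2.caller`** — the origin caller: reads are counted in 100 bp
  windows, normalized to reads-per-million within each library, windows with
  log2(HL/LL) ≥ 2 are merged (gap ≤ 500 bp) into islands ≥ 200 bp, islands
  are recounted and scored
  **E = HL / (HL + LL)**,
  and an island is called an origin when E ≥ 0.8 (equivalently HL/LL ≥ 4).
  Called origins get efficiency Z-scores and equal-size high/medium/low
  classes. A subsampling saturation analysis is included.
* **`iniseq2.domains`** — higher-order organisation: ini-domains (origins
  merged at ≤ 100 kb, ≥ 6 members), per-class origin clusters (≤ 30 kb),
  inter-origin distances, Venn-style overlap of interval sets at a gap
  tolerance, and a permutation overlap test (10,000 per-chromosome random
  re-placements; p-floor 1/n_perm; Z = (obs − mean)/sd of the permuted
  statistic).
* **`iniseq2.orientation`** — transcriptional orientation of the first gene
  on either side of each origin (convergent / divergent / co-oriented),
  stranded gene-coverage profiles around origins, and a randomized control of
  positions equidistant from neighbouring origins.
* **`iniseq2.features`** — GC content, GC/AT skew profiles ((G−C)/(G+C) in
  100 bp bins around origin centres), deepTools-style scaled coverage
  matrices (10 nt bins, bodies scaled to 5 kb), genome GC-decile fractions
  (50 bp windows), and per-origin feature tables.
* **`iniseq2.model`** — predictor screening (|r| ≤ 0.85 plus a
  linear-dependency rank test), correlation heatmap ordering (single linkage
  on Manhattan distances), PCA of the standardized predictors, RBF-kernel
  support-vector regression of efficiency (70/30 split, sigma and C tuned by
  10-fold cross-validated RMSE) and permutation feature importance.
* **`iniseq2.simulate`** — a ground-truth simulator of the experiment:
  planted origins fire per nucleus with probability equal to their
  efficiency, replicate a core-plus-exponential-tail tract, and seeded
  per-bp Poisson sampling emits the HL/LL libraries together with the
  realized per-bp replicated fraction f(x).

## Worked example

```bash
python examples/01_simulate_and_call.py
```

```
simulated 61381 HL and 62147 LL reads (30x per library)
chrom  start    end      name  efficiency  z_score  class   hl_norm   ll_norm
 chrS  47000  53000  origin_4       0.927    1.051   high 54006.940  4280.174
 chrS  86900  93000  origin_5       0.933    1.172   high 56711.360  4070.993
 chrS 136900 143100  origin_9       0.959    1.667   high 59252.863  2510.177
 chrS 177000 183000 origin_11       0.876    0.105 medium 52394.063  7401.805
 ...
11 of 20 planted origins called (those below the 0.8 efficiency cut are correctly absent)
mean |called E - replicated fraction over the call| = 0.018
```

Each row is a called origin; `efficiency` estimates the fraction of nuclei
that replicated the locus (origin_9 fired in ~96% of nuclei), `z_score` is
its standing within the called set, and `class` the efficiency tertile. The
final line compares every called efficiency against the simulator's known
per-bp replicated fraction: the caller recovers planted efficiencies to
within ~0.02 on average at 30x depth.

The other examples show the organisation analyses
(`02_domains_and_overlap.py`: ini-domains, clusters, permutation test) and
the feature/model pipeline (`03_features_and_model.py`: planted GC-skew
switches and recovery of the informative predictors).

Everything is also available from the shell, e.g.:

```bash
iniseq2 simulate --seed 1 -o sim/
iniseq2 call --hl sim/hl.bed --ll sim/ll.bed --genome sim/chrom.sizes -o origins.tsv
iniseq2 domains --origins origins.tsv -o domains.tsv
iniseq2 permtest -a a.bed -b b.bed --genome sim/chrom.sizes --n-perm 10000 --seed 1 -o perm.tsv
```

BAM input is converted upstream in one line
(`bedtools bamtobed -i reads.bam > reads.bed`); the package itself only
reads text formats.

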