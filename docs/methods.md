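# Methods

## Quantification model

All coordinates are 0-based half-open. The quantification universe is the
union of every sample's peak calls, sorted and merged; intervals that
overlap by ≥ 1 bp *or* abut are collapsed, so the universe is pairwise
disjoint and strictly separated. A sequenced fragment is represented by
its midpoint — the template-span midpoint for proper pairs, the read
midpoint for single-end records — and assigned to the unique peak
containing it, if any. On a disjoint universe this is the only counting
rule that conserves fragments (no read can be counted twice across
adjacent peaks). "Uniquely mapped" is operationalized as: mapped, primary
(not secondary/supplementary), not flagged duplicate, MAPQ ≥ 20
(configurable). Unflagged duplicates are not detected; there is no
deduplication stage. Paired and single-end records may not be mixed
within one sample. RPKM is count / (kb of peak × millions of mapped
reads); FRiP is the in-peak fragment total over the library size.

## Normalization

Two per-sample size-factor schemes, both re-centred to geometric mean 1 so
fold changes are comparable:

- **depth** (default): library size over the geometric mean of library
  sizes. Correct when global occupancy differs between conditions,
  because the in-peak fraction is then a biological signal, not a
  technical artifact.
- **reads_in_peaks**: DESeq2-style median-of-ratios on the peak count
  matrix (per-peak geometric-mean reference; peaks with a zero reference
  excluded). Provided deliberately as the contrast: when FRiP differs it
  equalizes in-peak totals and manufactures fold changes at unchanged
  peaks.

Copy-number segments (IGV `.seg`: tab-delimited, header, 1-based
inclusive coordinates, last column = Segment_Mean = log2(copy/2)) become
per-peak, per-sample copy ratios: the overlap-length-weighted mean of
2^Segment_Mean with uncovered bases neutral at 1.0, floored at 0.05 to
keep deep-deletion factors bounded. The normalization-factor matrix
f = size factor × copy ratio multiplies the NB mean; integer counts are
never rescaled, which keeps the NB likelihood valid (the same reasoning
as DESeq2's `normalizationFactors`).

The matrix pipeline filters peaks with RPKM < 1 in all but one sample
(both thresholds configurable; filtering precedes normalization), then
applies quantile normalization (classic sort–average–remap; ties within a
column receive the mean of the reference values at their tied rank
positions), z-scoring (constant rows map to zero) or log2(x + 1).

## Differential test

Per peak: y_ij ~ NB(mu_ij, alpha_i) with mu_ij = f_ij q_i exp(x_j beta_i),
x the group indicator. At fixed alpha, (log q, beta) is maximized by
expected-information Fisher scoring, vectorized across peaks (steps
clipped to ±5, |beta| capped at 25 natural-log units, ≤ 100 iterations,
tolerance 1e-8; peaks that fail to converge are reported with p = 1, and
peaks with zero counts everywhere are excluded with empty statistics).
Wald z = beta/SE against the standard normal; SE from the inverse Fisher
information (1/I_treat + 1/I_control); BH adjustment over all tested
peaks. No independent filtering and no fold-change shrinkage. Swapping
treat and control negates every log2FC and preserves every p-value.

Dispersion estimation: on factor-normalized counts, the moment estimate
alpha_mom = max((pooled within-group variance − mean)/mean², 1e-8),
capped at 10. Because the pooled variance is chi-square distributed on
d = (samples − 2) degrees of freedom, log(alpha_mom) is median-biased
low; it is debiased by log(d/2) − digamma(d/2) before further use. A
Huber-robust regression of the debiased log dispersion on log base mean
gives the trend; the final dispersion is the geometric interpolation
exp(0.5 log trend + 0.5 log alpha_mom,debiased). Peaks whose moment
estimate sits at the floor (sub-Poisson empirical variance) carry no
information about alpha at these sample sizes and take the trend value
outright rather than being dragged geometrically toward zero. The
debiasing and the floored-peak rule are what keep the test near nominal
at 3–5 replicates per group: under a global NB null (alpha = 0.1, five
per group, 2,000 peaks) the fraction of p < 0.05 is 0.051–0.063 across
seeds, and in the CNV scenario below the corrected amplified-arm fraction
at p < 0.05 is 0.04–0.07.

Two-group Wald contrasts only; multi-factor designs, likelihood-ratio
tests, Cook's-distance outlier handling and bit-for-bit DESeq2
reproduction are out of scope.

## Unsupervised analysis

Sample dissimilarity defaults to 1 − Pearson r (Spearman optional), with
Euclidean, Manhattan, Canberra, binary (Jaccard on the nonzero pattern),
maximum and Minkowski alternatives. Hierarchical clustering uses average
linkage via scipy's agglomerative implementation (deterministic; ties
resolved by its nearest-neighbor-chain order). PCA centers but does not
scale features (flag to scale); scores come from the SVD of the
sample × peak matrix and variance fractions from squared singular
values. Peak k-means (best of 10 restarts, seeded, scikit-learn) relabels
clusters by descending size. All outputs are purely numeric; metadata
only ever annotates plots.

## Enrichment

Each peak maps to the nearest TSS on its chromosome within 100 kb
(midpoint distance; ties by gene id; distance signed by orientation).
Per gene, the assigned peak with the largest |Wald| supplies a signed
score — a declared aggregation rule, chosen so one strong proximal peak
is not diluted by weak distal ones. A single signed ranking feeds the
classic weighted KS pre-ranked GSEA (weight p = 1): hits increment
proportionally to |score|^p over set members, misses decrement 1/(N − m),
ES is the signed maximum deviation. The null permutes gene labels
(nperm = 1000, seeded) — the only permutation available to pre-ranked
input; NES divides ES by the mean |null ES| of matching sign, nominal p
is the matching-sign tail with an add-one correction, and FDR q follows
the standard positive/negative pool-ratio construction. Both tails of
the one signed ranking are reported rather than running separate up/down
lists. Set-size bounds [5, 500] after intersection with the ranking;
leading-edge reporting is not implemented.

## Simulator

The generator draws per-peak, per-sample fragment counts from a
gamma-Poisson (NB) with a mean that encodes the study design, then
optionally materializes files: coordinate-sorted single-end SAM (paired
optional in the model, single-end emitted), per-sample peak BEDs (gained
peaks appear only in the gaining condition's calls), `.seg` files for
CNV samples, a metadata CSV with relative paths, truth TSVs and a
manifest. In-peak midpoints are placed uniformly strictly inside their
peak and background midpoints strictly outside every peak (background
fills the library to exactly the configured fragment count), so midpoint
counting recovers the drawn counts exactly and realized FRiP is sharp —
at 200k fragments the realized value sits within ±0.005 of target.
Everything is deterministic given the seed, byte for byte.

Mean model, shared/gained mode: all conditions carry the shared peaks at
one common per-depth intensity u; the gaining condition carries gained
peaks at intensity g while other conditions see them at a small absolute
basal level (default 3 expected fragments — enhancer-level background,
which is also what makes the median-of-ratios reference well-defined at
those peaks, as it is in real data). u and g are solved from the
per-condition FRiP targets, so shared peaks are exactly null on the
per-depth scale and the FRiP contrast is attributable entirely to gained
occupancy. Archetype mode (time courses) instead renormalizes
per-condition relative profiles to the FRiP target. CNV blocks multiply
the NB mean of overlapping peaks on top of the FRiP-derived baseline —
amplification adds reads — so affected samples run slightly above their
FRiP target, as in real amplified genomes.

Preset study conditions (chosen once, as the designs the scenarios
require; problem sizes also keep the default test run fast):

- **frip_imbalance** — 2 + 2 replicates, 3,000 shared + 12,000 gained
  peaks, FRiP 0.02 vs 0.10 (the ~5× contrast), 40M fragments/sample,
  dispersion 0.002: deep, technical-grade replicate libraries in which
  the null shared-peak log2FC noise (sd ≈ 0.11) sits two orders below the
  ~6-log2 artifact that in-peak scaling induces.
- **cnv_arm** — 3 + 3 replicates, 4,000 peaks, equal FRiP 0.10, one
  6 Mb arm at copy ratio 3 in condition B, zero true signal, 4M
  fragments/sample (≈ 100 fragments/peak), dispersion 0.02 — moderate
  depth where the dispersion estimator is well calibrated at 4 residual
  degrees of freedom.
- **timecourse** — 3 stages × 2 replicates, 1,200 peaks in three
  archetypes (early 1.0/0.45/0.15, middle 0.25/1.0/0.25, late
  0.15/0.45/1.0), FRiP 0.15, 2M fragments/sample, dispersion 0.02.

What the simulator does *not* emulate: GC and mappability bias,
fragment-length distributions, Tn5 offsets, unflagged duplicates, peak
boundary jitter between samples, and background reads inside peak
intervals beyond the configured basal signal. Passing tests therefore
demonstrate the statistical mechanisms — size-factor artifacts, CNV
inflation, archetype structure — not robustness to alignment-level
artifacts of real data.

## Numerical and design choices

- Differential mechanism checks run on the simulator's drawn count
  matrices at full preset depth; emitting 40M-read SAM files is exercised
  at reduced depth, with the exact-recovery invariant (counting the
  emitted SAM reproduces the drawn counts) bridging the two routes.
- Quantile normalization tie policy, the .seg dialect (1-based inclusive,
  Segment_Mean = log2(copy/2)), bookended-peak merging, and the
  filter-before-normalize order are all stated choices where dialects
  genuinely differ; each is a config key or documented constant.
- The dual-cutoff summary grid defaults to padj {0.05, 0.01} ×
  fold change {1.5, 2.0}; both axes are configurable.
- Size factors are validated to geometric mean 1 within 1e-9; copy
  ratios are floored at 0.05; dispersions live in [1e-8, 10].
- The pipeline writes a FAILED marker (with the failing stage's
  exception) on any error and removes it on success; comparisons are
  validated before any counting happens.

## Known limitations

Two-group contrasts only; no spike-in or GC normalization; no blacklist
filtering; CNV segments are consumed, never called; the GSEA FDR uses the
pooled-permutation approximation, which is coarse for very small
collections of sets; the Wald test remains mildly anticonservative below
three replicates per group.
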