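# Methods

## The analysis model

`epitwin` studies inter-individual epigenetic variability in a
monozygotic-twin design. The measured quantity is the array beta value
β ∈ [0, 1] — the fraction of methylated signal at one CpG — for each probe
and sample. The core object is the per-probe difference track
Δβ = β(A) − β(B) between two samples, and the core call is the
inter-individual DMR (iiDMR):

> a maximal run of at least `min_probes` (default 2) consecutive probes in
> the kept, coordinate-sorted probe list, all with the same sign of Δβ,
> each with |Δβ| ≥ `min_delta` (default 0.05), successive members at most
> `max_gap` (default 500) bp apart on one chromosome.

"Adjacent" deliberately means consecutive *among analysed probes*, not
genomic adjacency: an array interrogates a sparse grid and the pairwise
500-bp constraint is what makes the rule decidable without sequence.
Missing values break runs (no evidence of consistency across an unmeasured
probe), thresholding is inclusive (≥) on raw floating values, and a region
is reported once as its maximal run rather than as every qualifying probe
pair; member-probe counts are exposed alongside region counts since either
unit can be meaningful. The caller is verified against a brute-force
enumeration oracle on hundreds of randomized instances.

Around the caller sit four analysis groups:

* **Variability.** rms_intra(probe) = √(mean over pairs of (β_twin1 −
  β_twin2)²); the inter-pair analogue re-pairs individuals across pairs
  (derangement-style — nobody keeps their co-twin) and by default averages
  the mean squared differences over 20 seeded permutations before the root
  (a single permutation is recoverable by setting the count to 1; averaging
  is strictly more stable). The biological-vs-technical test uses the ratio
  of mean iiDMR call counts (co-twin comparisons over technical-replicate
  comparisons) with a label-permutation null over the pooled comparisons —
  the minimal exchangeable null for that design — and the add-one p-value
  estimator (1 + #{null ≥ obs})/(n_perm + 1), which never returns exactly
  zero and reports its resolution 1/(n_perm + 1).
* **Temporal stability.** On the probes shared between the dense and the
  sparse platform, single-probe differences with a strict |Δβ| > 0.05 at
  the later time point are checked for sign agreement with the earlier time
  point. The test is a 1-df goodness-of-fit χ² against equiprobable
  same/opposite direction (the natural exchangeable null; the null
  proportion is a parameter for sensitivity analysis), without continuity
  correction by default since intended n is large. Probes with a missing or
  exactly zero earlier difference are excluded and counted. Note the strict
  > here versus the inclusive ≥ in the caller: the two thresholds are
  configured separately.
* **Integration.** Promoters are TSS ± 1000 bp around a strand-aware
  anchor (minus-strand anchor = interval end − 1). Probes map to the
  nearest TSS within 1 kb, ties broken by smaller anchor coordinate then
  lexicographic id. ChIP scores are whole-fragment overlap counts per probe
  region (half-open intersection, one count per fragment per region),
  normalised as counts-per-10⁷ by library total — the simplest defensible
  normalisation; both scale and method are config-exposed. Binned analyses
  bin probes by Δβ at multiples of the bin width and report per-bin means
  with percentile-bootstrap 95 % intervals (bins with n < 3 are flagged and
  carry no interval). The expression response is log(FPKM_A + 1) −
  log(FPKM_B + 1); the pseudo-count guards FPKM = 0 and a ratio of logs is
  base-invariant up to scale. The expression-shift test is a one-sided
  Wilcoxon rank-sum on log FPKM (DMR genes lower), quantifying a contrast
  usually shown only graphically, alongside the fraction of each gene set
  below 1 FPKM (the conventional low-expression cutoff).
* **Enrichment.** The unit is the probe; "DMR probe" means membership in
  ≥ 1 call. Per category: fraction of universe probes called, with exact
  Clopper–Pearson 95 % intervals (Wilson available via flag) against the
  overall DMR fraction as the background line. Promoter chromatin states
  are a four-way H3K4me3 × H3K27me3 quadrant: a mark is "hi" iff its score
  strictly exceeds a per-mark quantile (default 0.75) of promoter-wide
  scores — a reconstruction, since no threshold rule accompanies public
  ES-cell reference data; the quantile(s) are parameters. Housekeeping
  depletion is a 2×2 χ² without continuity correction. The ageing-DMR
  contrast takes the top-n (default 500) probes by age-correlation score
  (boundary ties broken by probe id) against an equal-sized seeded random
  control set, pooling |Δβ| over all supplied pairwise comparisons per set
  with percentile-bootstrap 95 % intervals on the means.

No multiple-testing correction is applied anywhere; every p-value is raw.
QC removes multi-mapping, SNP-overlapping and sex-chromosome probes before
any analysis; a probe failing several rules is reported once under the
precedence multi_mapped > snp_overlap > sex_chromosome (the kept set itself
is precedence-independent). Readers accept any valid [0, 1] beta matrix and
apply no correction or imputation; "NA"/empty cells stay missing.
Coordinates are 0-based half-open everywhere.

## The synthetic cohort

The generator emulates the statistical structure of the twin design so
every downstream stage can be tested against planted truth.

**Layout.** Probes sit in CGI-like clusters (default 8 probes spaced
60–180 bp) separated by 10 kb, blocked into a few autosomes plus a small
chrX fraction; ~1 % of clusters are flagged multi-mapping and ~2 %
SNP-overlapping, exercising QC. Half the clusters are promoters with a TSS
at the central probe; the sparse platform is the first two probes of every
promoter cluster — a deterministic, promoter-biased strict subset, like a
27K array against a 450K array.

**Baselines and noise.** Cluster baseline betas are bimodal (defaults 0.15
/ 0.85); unmethylated promoters associate with the high-expression tier.
Measurement noise is applied on the logit scale and squashed back, with the
logit sd calibrated *per probe* as σ/(β(1−β)) so that the realized
beta-scale noise is ≈ `tech_noise_sd` (default 0.015) at each probe's own
value rather than only near β = 0.5 — this keeps values in range without
truncation artefacts at the modes and makes the RMS decomposition exact:
null probes have intra-pair RMS √2·σ, probes with planted pair-difference
SD s have √(s² + 2σ²).

**Three planting mechanisms.**

1. *Individual epialleles*: per individual, a fraction `epiallele_rate` of
   eligible promoters receives a coherent shift of `epiallele_delta`
   (default 0.15, directed toward 0.5) over a run of 2–5 consecutive
   probes — straddling the caller's 2-probe minimum by design. A fraction
   `lowexpr_targeting` (default 0.9) lands at low-expression / K4lo
   promoters. Each epiallele persists to the second time point with
   probability `temporal_stability`.
2. *Pair-shared shifts* (`genetic_rate`, `genetic_delta`): runs shared by
   both co-twins of a pair, creating inter-pair but not intra-pair
   differences — the stand-in for genetically determined methylation.
3. *Variable probes* (`variable_probe_rate`, `biological_sd`): scattered
   probes where every individual receives an independent Gaussian
   deviation, giving a continuous per-probe variance component (the pool
   that age-correlation scores can be made to coincide with).

**Coupled molecular layers.** H2A.Z counts per probe come from a
log-linear negative-binomial model (dispersion 0.2) driven by a Gaussian
copula on the beta ranks; the latent correlation is set from the target
Spearman via the bivariate-normal relation ρ_s = (6/π)·asin(r/2) and
inflated slightly to offset count-noise attenuation, and the latent noise
is shared within a cluster so promoter-averaging does not sharpen the
correlation past the configured `meth_chip_coupling` (default −0.6).
H3K4me3/H3K27me3 counts are per promoter, hi/lo count modes (defaults
120/8) keyed to the truth chromatin state, whose distribution couples to
the expression tier (high-expression promoters are mostly K4hi/K27lo,
low-expression mostly K4lo). FPKM values are log-normal within tier with
the tier boundary at 1 FPKM enforced (< 1 low, ≥ 1 high), a per-individual
multiplier, and methylation-gain epialleles depressing the carrier's FPKM.
Housekeeping labels concentrate in the high-expression tier. All
randomness derives from one seed through fixed per-component sub-streams,
so identical configs give byte-identical cohorts.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: realistic genetic architecture (LD, allele
frequencies), cell-type composition and its confounding, probe-specific
chemistry biases (Infinium I/II, background, batch), genomic dependence of
effect sizes, or the empirical effect-size distribution of real epialleles.
Recovery and calibration results show the machinery is correct under its
stated model, not that real cohorts have these signal-to-noise properties.

## Numerical and design choices

* Permutation seeds, counts, bootstrap sizes, bin widths, quantiles and
  thresholds are all explicit parameters with the defaults above; one
  global pipeline seed derives per-stage seeds deterministically.
* The comparison planner defaults to exhaustive cross-pair pairings
  (deterministic, strictly more informative); `representative` mode picks
  one individual per pair per unordered pair of pairs, which on a design
  of two complete pairs plus one singleton co-twin yields the classic five
  pairwise comparisons. Singleton "pairs" are allowed in the sample sheet
  for exactly that design.
* Degenerate inputs error loudly rather than silently: empty kept set,
  < 2 usable twin pairs, constant vectors in rank correlation, all-zero
  ChIP tracks, zero selected probes in the temporal test, degenerate 2×2
  margins.
* An all-constant expression contrast returns p = 1 (no shift detectable)
  rather than an error, since it is a well-defined no-signal case.
* Test and validation problem sizes (20 k probes, 2–30 pairs, 200–300
  permutations/replications per calibration) were chosen as the smallest
  scales at which the planted effects and calibration bands are stable;
  all scale up linearly.

## Known limitations

* The DMR BED round-trip preserves intervals, membership, direction and
  the mean delta, but not the individual per-probe deltas (BED carries a
  single score column); per-probe detail lives in the delta-track TSVs.
* `rms_inter` is a permutation-averaged estimate; with very few pairs the
  space of valid re-pairings is small and the estimate coarse.
* The biological-vs-technical permutation test treats comparisons as
  exchangeable units; comparisons sharing a sample are not independent,
  which the label-permutation null absorbs but a variance-component model
  would handle more efficiently.
* Chromatin-state quadrant boundaries depend on the hi-quantile choice;
  enrichment *directions* are robust to it, exact fractions are not.
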