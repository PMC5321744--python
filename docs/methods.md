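# Methods

## The steady-state turnover model

All quantities are per-gene, steady-state fractions of gene-body
nucleosomes. `D` is the fraction disassembled by transcribing RNAPII, `L`
the fraction lost (disassembled and not immediately reassembled, visible
as reduced histone H3 occupancy), `R` the fraction transiently
disassembled but immediately reassembled; `D = L + R` by definition.

Three genotypes are modelled:

- **wild type** — `D_wt`, `L_wt`, `R_wt`;
- **remodeller-null** (*fft3Δ*) — disassembly and loss scale together:
  `D_fft3 = (1 − x′)·D_wt`, `L_fft3 = (1 − x′)·L_wt`, with
  `x′ ∈ (0, 1]` the remodeller's relative contribution to disassembly;
- **reassembly-null** (FACT mutant *spt16-18*) — reassembly abolished:
  `R_spt16 = 0`, so `L_spt16 = D_spt16 = β·D_wt` with `β > 0` a
  proportionality constant.

The observables are H3 occupancy changes relative to wild type,
`ΔH3_fft3 = L_wt − L_fft3 = x′·L_wt` and
`ΔH3_spt16 = L_wt − L_spt16 = L_wt − β·D_wt`, plus a transcription proxy
(RNAPII occupancy). Eliminating `L_wt` gives the reconstruction

```
D_spt16(x′) = ΔH3_fft3 / x′ − ΔH3_spt16 .
```

The estimator evaluates the Pearson correlation `r(x′)` between
`D_spt16(x′)` and RNAPII occupancy on a grid over (0, 1] and takes the
argmax. Key properties, all covered by tests:

- `r(x′)` is invariant to joint positive rescaling of the two ΔH3 vectors
  and to positive affine transforms of the transcription proxy, and the
  divided form equals the positively rescaled form
  `ΔH3_fft3 − x′·ΔH3_spt16` under Pearson correlation, so the estimator is
  β-agnostic and scale-agnostic (log2 ChIP ratios and linear fraction
  differences are both acceptable inputs as long as each vector is on one
  consistent scale).
- At the true `x′` the reconstruction equals the latent `D_spt16` exactly
  when the observables are noise-free.
- If `L ∝ D` (no gene-to-gene variation in reassembly efficiency),
  `D_spt16(x′)` is an affine function of `D` at every `x′` and `r(x′)` is
  constant: `x′` is then unidentifiable. The estimator reports
  `flatness = max r − min r` and flags the result non-identifiable when
  flatness < `flatness_tol` (default 1e-3); this is a flagged return, not
  an error.

Ties in the argmax break toward the smallest `x′` (the conservative
contribution). Genes missing any observable are dropped once, before the
sweep, so every grid point sees the same universe. The default grid step
is 0.01, matching whole-percent reporting of contribution estimates; the
per-gene `d_estimates` are on an arbitrary scale (proportional to
`x′·D_wt`) and only correlations with them are meaningful.

### Finite-sample behaviour

Two effects, both visible in the acceptance checks, bound what the
estimator can do:

- **Sampling scatter.** The population argmax of `r(x′)` is exactly the
  true `x′`, but near the peak the curve is flat to ~1e-4, so the sample
  argmax inherits the noise of sample cross-moments between `D` and the
  reassembly-heterogeneity component. Under the default generator
  conditions at n = 5000 the noise-free estimate is unbiased with a
  seed-to-seed sd of roughly 0.02–0.07 (larger for larger `x′`, where the
  grid is locally least informative); grid-exact recovery in every seed is
  not a property this estimator has at realistic n. The recovery test
  freezes exactly these pilot-confirmed properties (unbiased mean, scatter
  bounds) rather than exact recovery.
- **Noise attenuation tilt.** Additive measurement noise on `ΔH3_fft3`
  enters the reconstruction as `e/x′`, so its variance falls as `x′`
  grows; on a near-flat curve this tilts the argmax toward 1. With the
  default calibration (median `ΔH3_fft3` signal ≈ 0.02·x′ against
  `sigma_obs` = 0.01) the tilt dominates and the estimate is biased
  upward — most severely for small `x′`. The acceptance script reports the
  measured recovery error so this regime is visible, not hidden.

## The synthetic generator

`generate_cohort` inverts the inference model. Per gene, with one seeded
stream (draw order: transcription, coupling noise, rho, observable noises
in the order ΔH3_fft3 / ΔH3_spt16 / pol / Δpol / exchange, annotation
layout):

1. log2 RNAPII occupancy `P ~ N(0, sigma_T²)` (default sd 1.2, giving
   log2 occupancy ranges of a few units as in yeast ChIP data);
   transcription `T = 2^P`.
2. `D_wt = min(κ·T·exp(N(0, sigma_D²)), d_max)` with κ calibrated so
   `median(D_wt)` equals `d_median` (defaults 0.10 median, 0.90 cap);
   `sigma_D` (0.3) is gene-level coupling noise between transcription and
   disassembly.
3. Reassembly fraction `rho ~ Beta(rho_alpha, rho_beta)` (defaults 8, 2:
   mean 0.8 — most transiently disassembled nucleosomes are restored);
   `L_wt = (1 − rho)·D_wt`, `R_wt = rho·D_wt`, and `D_wt` is then defined
   as `L_wt + R_wt` so conservation is float-exact. `constant_rho=True`
   fixes rho at its Beta mean (the `rho_alpha → ∞` limit), the degenerate
   regime in which `x′` is deliberately unidentifiable; the Beta draw is
   still consumed so the stream stays aligned across modes.
4. Genotype values per the model above; `β` must satisfy `β·d_max ≤ 1` to
   keep fractions in [0, 1].
5. Observables: `ΔH3_fft3 = x′·L_wt + ε`, `ΔH3_spt16 = L_wt − β·D_wt + ε`
   (ε additive, sd `sigma_obs`, default 0.01); observed pol
   `P + N(0, sigma_P²)` (sd 0.2); `Δpol_fft3 = −γ·x′·D_wt + ε` (the
   RNAPII-occupancy cost of losing remodeller-mediated disassembly,
   γ = 1); exchange rate `E = L_wt·exp(N(0, sigma_E²))` (sd 0.4),
   tracking loss as replication-independent H3/H4 incorporation does.

The annotation places genes sequentially on `n_chromosomes` synthetic
chromosomes with lognormal body lengths (median ~1.4 kb, yeast-scale,
minimum 300 bp) and uniform 200–1000 bp intergenic gaps, random strands.
Coordinates are snapped to the coverage bin grid so that rasterized tracks
are exact: each sample's IP signal is the gene-level target (flat,
unit-mean shape over the body — `T` for RNAPII, `1 − L` for H3 per
genotype) on a flat 1.0 intergenic baseline, and the control track is flat
1.0. Gene-level quantification on these tracks therefore recovers the
targets exactly, which the tests assert.

What the generator does **not** emulate: read-level sampling noise and
mappability structure, nucleosome-scale positioning, promoter NDRs, 5′/3′
profile shape, replication or cell-cycle effects, and any global-scaling
(spike-in) issues. Passing tests therefore demonstrate correctness of the
computations and the estimator's statistical behaviour under the stated
model — not performance on real ChIP-seq libraries. The effect sizes and
noise scales are calibrations chosen to give plausible log2 ranges, not
measured values, and all are config-exposed.

## Quantification conventions

- Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
  closed) is converted at the read boundary, BED passes through.
- Coverage lives in fixed-step bins tiling each chromosome from 0;
  bedGraph intervals are rasterized by length-weighted averaging
  (mass-conserving; uncovered positions are 0; overlapping intervals are
  rejected).
- Gene occupancy is `log2((mean IP + pc)/(mean control + pc))` over the
  annotated interval as-is (no flank extension); the mean, not the sum, so
  gene length does not confound occupancy. The pseudocount (default 0.01)
  avoids ±∞ while perturbing typical signals by <1%. There is no depth or
  spike-in normalization — all signals are relative.
- Genes with zero control coverage before the pseudocount, or outside the
  track extent, are excluded per analysis and listed with a reason, never
  silently dropped; the same explicit-exclusion policy applies to missing
  values everywhere (pairwise/rowwise deletion with counts logged, never
  imputation).
- Metagene matrices use scale-regions layout: 500 bp flanks in 10 bp bins
  and 60 body bins by default (yeast-scale genes); body resampling is
  length-weighted (exact on constant signals, fractional boundaries
  handled exactly); minus-strand rows are computed in genomic order and
  reversed so columns always run 5′→3′; each gene weighs equally. The
  `zero` missing policy keeps matrix shape stable across gene sets, `drop`
  removes genes with out-of-range flanks.

## Statistics conventions

- k-means: Lloyd's algorithm, Euclidean, best of `n_init` (default 10)
  seeded initializations by inertia, deterministic given the seed; either
  metagene profile rows or a single gene-level column as feature space
  (recorded in the result); a clustering with fewer populated clusters
  than k is flagged degenerate. Extreme-cluster selection breaks ties
  toward the larger cluster, logged.
- Threshold gene sets use inclusive comparisons (≤, ≥); the universe is
  the set of genes with non-missing values.
- Overlap testing is the one-sided (enrichment) hypergeometric upper tail,
  inclusive (`P[X ≥ k]`); unequal universes are intersected and logged.
- Correlation is the Pearson product-moment r with pairwise deletion and
  `n_used` reported; |r| ≥ 0.4 (inclusive — the convention's strict/
  inclusive wording is contradictory in common usage, inclusive is
  implemented) is summarized as a "meaningful" association.
- Group comparisons use Tukey's HSD on the studentized-range distribution
  (scipy implementation), returning per-pair mean differences and adjusted
  p-values. No multiple-testing correction is applied across separate
  overlap tests (each figure-level question is a single test).

## Problem sizes and determinism

Tests and the acceptance script run cohorts of 120–5,000 genes; the
parameter-recovery checks use n = 5000 with up to 100 seeds, the
identifiability dichotomy 20 seeds at n = 2000, metagene oracle checks 200
randomized ≤1 kb genomes — sizes at which every property above is
measurable in seconds to a couple of minutes on one CPU. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
pipeline outputs contain no timestamps, so a rerun with the same config
and seed is byte-identical (asserted by test).

## Known limitations

- The estimator yields a point estimate only; no uncertainty on `x̂′`.
- Under log2-ratio inputs the linear derivation is a proxy, exact only in
  the small-change limit; the estimator is still scale-consistent but its
  optimum need not coincide with the linear-scale optimum.
- The additive-noise regime documented above biases `x̂′` upward when the
  ΔH3 signal-to-noise ratio is low; interpret `x̂′` near 1 with care.
- Single remodeller, single chaperone: no joint multi-factor model.
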