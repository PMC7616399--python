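# Methods

## Overview

The package quantifies the per-cell dosage response of the metabolome to
whole-genome duplication in a multi-strain diploid/neotetraploid design.
Because WGD enlarges cells, per-biomass fold changes confound dosage with
cell packing; the analysis estimates the tetraploid:diploid relative cell
density per dry mass (rcd_dm) from flow cytometry and gravimetry and uses
it to renormalize fold changes to the per-cell scale.

## Feature filtering

Three passes on raw intensities, audited per step:

1. **Presence** — retain a feature iff at least one strain×ploidy group
   has abundance > 0 (non-missing) in every replicate. Pooled QC samples
   are carried in the table but never enter the evaluation.
2. **Repeatability (RSD)** — per feature, within-group RSD = sd/mean
   (sd with the n−1 denominator), aggregated over groups; the
   ceil(frac·N) highest-scoring features are removed (frac = 0.20).
   Cross-group aggregation is the arithmetic mean by default (median and
   max are configurable); the mean is symmetric in groups so no single
   noisy group dominates. Groups with mean 0 are skipped; a feature with
   zero mean in *every* group cannot survive the presence step, so the
   standalone call raises rather than guessing.
3. **Variability (IQR)** — per-feature interquartile range over all
   biological samples (linear-interpolation quantiles; IQR of {1,2,3,4}
   is 1.5, pinned by a test); the ceil(frac·N) lowest are removed.

Ranking ties break toward the lower feature index (stable sort). Removal
count ceil(frac·N) reproduces the canonical step counts
7,794→6,235→4,988 (ESI−), 4,978→3,982 (ESI+) and 107→85→68 (GC-MS); the
ESI+ third step (3,982→3,186 rather than 3,185) implies data-dependent tie
handling in the original workflow and is documented as a known divergence
rather than forced. Scores are computed on raw intensities because
normalization — log2(x+1) — is applied after filtering.

## Differential abundance

On the filtered, log2-normalized table:

* **Strain contrasts** — equal-variance two-sided t-tests of the cytotype
  means per feature, one contrast per strain; an ordinary t-test replaces
  empirical-Bayes variance moderation, which is adequate at n = 8 per
  group and keeps the test self-contained. Zero-variance features get
  p = 1 with a warning.
* **General contrast** — the ploidy coefficient of an additive
  strain + ploidy linear model, tested with its OLS t-statistic.
* **Multiplicity** — Benjamini–Hochberg within each contrast; a DAF is a
  feature with adjusted p < 0.05. (A VIP > 1 projection criterion used in
  some workflows is intentionally out of scope.)
* **Two-way ANOVA** — balanced fixed-effects strain×ploidy ANOVA per
  feature, vectorised over features via the closed-form balanced sums of
  squares (types I/II/III coincide under balance; unbalanced designs are
  refused rather than silently re-weighted), BH per term, and the
  7-region Venn partition of significant flags.
* **Ploidy-specific calls** — on the raw table: absent (≤ threshold,
  default exactly 0) in every replicate of one cytotype and present in
  every replicate of the other.
* **UpSet counts** — exact-region intersection counts of per-strain DAF
  sets (2^k − 1 cells); the cells sum to the union size by construction.

## Model 1: relative cell density

For sample i of a strain with tetraploid:diploid fresh-mass ratio
rmass_i, the 4C-peak proportion p_4n obeys

    logit(p4n,i) ~ Normal(mu_i, theta)
    mu_i = ln( rcd[strain] * rmass_i + pG2[strain]/(1 - pG2[strain]) )

so odds(p) = rcd·rmass + odds(pG2): the slope is the relative cell
density per fresh mass and the intercept the odds of diploid
G2/endoreduplicated nuclei, pinned by pure-diploid samples (rmass = 0).
Strains are fitted jointly with strain-indexed rcd and pG2 and a shared
logit-scale residual sd theta (per-strain theta behind a flag). Observed
proportions use the continuity correction p̂ = (k + 0.5)/(n + 1), which
is negligible at thousands of nuclei per sample but keeps the logit
finite at 0 or 1.

**Priors** (weakly regularizing, all exposed in `CellDensityPriors`):
rcd ~ Normal(1, 1) truncated to rcd > 0 (centred on "no density change",
sd wide enough to cover any plausible cytotype); pG2 ~ Beta(1.5, 10)
(mild mass near small endoreduplication fractions); theta ~ HalfNormal(1).

**Sampler.** Adaptive random-walk Metropolis-within-Gibbs on
unconstrained transforms (log rcd, logit pG2, log theta) with the
log-Jacobian included: one Gaussian proposal per coordinate per sweep,
per-coordinate scales adapted toward 44% acceptance during warmup only,
so the retained chain is a valid non-adaptive Markov chain. With 2–3
parameters per strain the posterior is low-dimensional and gradient-free
sampling mixes well (bulk ESS ≈ 350–600 of 2,000 retained draws in the
default configuration). Two chains × 2,000 iterations with 1,000 warmup
by default; split R-hat and bulk ESS (via arviz) are reported per
parameter, and R-hat > 1.05 triggers a warning, not an error. Chains
start from a data-driven point (pG2 from the diploid samples' mean
proportion; rcd from the median per-sample odds slope) plus jitter.

## Model 2: dry-mass fraction

Per strain×cytotype, dm ~ Normal(f_dry·m, sigma) with no intercept;
f_dry ~ Uniform(0, 1) and sigma ~ HalfNormal(10 mg). Under a flat prior
the posterior mean of f_dry equals the weighted slope Σ(dm·m)/Σ(m²),
which the acceptance script verifies to within Monte-Carlo error. The
tetraploid:diploid ratio rf_dry = f_dry,4n/f_dry,2n is formed by pairing
posterior draws (the two group posteriors are independent, so pairing is
innocuous).

## Combination and per-cell fold changes

rcd_dm = rcd/rf_dry per strain, formed from every combination of 500 rcd
draws × 500 rf_dry draws (250,000 ratios; a literal reading of
"each combination"). A paired mode (500 one-to-one ratios) is available;
the mean is the same in expectation either way, and only the mean enters
the conversion.

Fold changes per dry mass are computed on the **unfiltered** table after
a pair-presence filter (feature positive in every sample of the strain's
diploid–tetraploid pair), log2 without the +1 offset since positivity is
guaranteed; lfc = mean(log2 | 4n) − mean(log2 | 2n). Then

    FCdm   = 2**lfc
    FCcell = FCdm / mean(rcd_dm draws)

Since division by a positive scalar preserves order,
median(FCcell) = median(FCdm)/mean(rcd_dm) exactly (asserted to machine
precision). Dosage classes: FCcell < 1 overcompensation; FCcell = 1 full
compensation; 1 < FCcell < 2 partial compensation; FCcell = 2 a 1:1
dosage effect; FCcell > 2 positive dosage effect. Summaries report the
three-region proportions with the boundaries folded into the middle
region.

## Synthetic data generator

The generator emulates the study design: four strains (default labels
0013/9242/9316/9346), diploid and tetraploid cytotypes, eight replicates
per strain×cytotype and per platform; eight mixed-ploidy plus five
pure-diploid flow samples per strain; twelve fresh/dry mass pairs per
strain×cytotype with fresh masses log-uniform over 28–909 mg (the range
is config, `fresh_mass_range`; the upper end is interpreted in mg).

* **Feature tables** — log2-scale additive model: per-feature baseline
  ~ Normal(10, 2), strain effects ~ Normal(0, 1), ploidy effect
  ~ Normal(0, 0.5) applied to the tetraploid, interaction ~ Normal(0,
  0.25), residual ~ Normal(0, 0.5); abundance = 2^(sum). The 2n cytotype
  carries the zero level, so a feature's drawn ploidy effect *is* its
  expected log2(4n/2n) shift — the drawn effects are attached to the
  table (`attrs["truth"]`) for moment checks. A fraction of features
  (default 1%) is made structurally ploidy-specific: exactly zero in all
  replicates of one random strain×cytotype and positive in the paired
  one (structural zeros, not left-censoring, matching a qualitative
  present/absent reading).
* **Flow counts** — forward draws from Model 1 with a binomial count
  layer on top (nuclei_per_sample = 5,000): the logit-normal layer
  carries the model's mean structure, the binomial layer yields realistic
  integer counts. Default truth: rcd 0.52–0.68, pG2 0.03–0.08,
  theta = 0.05.
* **Mass pairs** — dm = f_dry·m + Normal(0, 0.5 mg), resampled into
  (0, m). Default truth f_dry ≈ 0.048–0.054 (2n) with a 0.85 tetraploid
  ratio, putting true rcd_dm in the 0.6–0.8 band.

Determinism: every generator draws from a substream keyed on
(config seed, stage label, platform/strain), so outputs are reproducible
per stage and independent across stages.

**What the generator does not emulate** — and hence what passing tests do
not establish about instrument data: no retention-time drift, batch or
injection-order effects, no heteroscedastic intensity-dependent noise, no
correlated features (adducts/isotopologues of one compound), no
left-censoring at the detection limit (absence is structural), no
gating/debris errors in the flow counts, and no 8C (tetraploid G2)
nuclei beyond the intercept correction. Conclusions about real data rest
on the model assumptions, not on these tests.

## Numerical choices and problem sizes

* Removal counts use ceil(frac·N); sort ties break toward the lower
  feature index; quantiles use linear interpolation; sample sds use the
  n−1 denominator throughout.
* Degenerate inputs: zero-variance features get p = 1 with a warning
  (not a spurious detection); odds = 0 in the forward model returns
  p = 0 with a warning (the logit's −∞ limit); strains lacking
  pure-diploid or mixed flow samples produce identifiability warnings,
  not errors.
* Default table sizes in tests and the demo pipeline (a few hundred to a
  few thousand features, 600–2,000 MCMC iterations for smoke tests) are
  chosen so the full suite runs in about three minutes on one CPU while
  keeping every statistical check at its stated power; the recovery
  harness uses the full 2 × 2,000-iteration setting across 20 simulated
  replicates of the study design.
* The filter report's step counts are exact bookkeeping (in/out/ids per
  step) and are asserted to chain consistently.

## Known limitations

* The Metropolis sampler is adequate for the 9–12 parameter posteriors
  here but would mix poorly for strongly correlated high-dimensional
  extensions; an HMC backend would be the natural upgrade.
* The equal-variance t-test forgoes variance-moderation shrinkage; at
  n = 8 per group the efficiency loss is small, but very small designs
  would benefit from moderation.
* pG2 is treated as cytotype-intrinsic and constant across mixed
  samples; frond age or environment could modulate endoreduplication.
* The per-cell conversion divides by the posterior *mean* of rcd_dm;
  propagating the full rcd_dm posterior into FCcell intervals is
  straightforward from the returned draws but not done by default.
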