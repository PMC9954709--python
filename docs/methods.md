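# Methods

## WGD classification

A tumor sample's copy-number state is a set of non-overlapping genomic
segments with integer allele-specific copy numbers (major ≥ minor ≥ 0),
stored 0-based half-open so length arithmetic is `end − start`. Three
length-weighted statistics are computed over the **covered** genome (the sum
of segment lengths), not a fixed reference length: exome-derived profiles
have gaps, and including them would make the denominators depend on capture
design rather than biology.

* `fraction_mcn_ge2` — genome fraction with major allele copy number ≥ 2;
* `tumor_ploidy` — length-weighted mean total copy number per cancer cell;
* `frac_loh` — genome fraction with minor copy number 0.

Two decision rules: **MCN rule**, WGD+ iff `fraction_mcn_ge2 > 0.5`, and
**LOH rule**, WGD+ iff `ploidy > 2.5 − 1.25·frac_loh`. Both are strict
inequalities, so a sample sitting exactly on either boundary is WGD−.
Sex chromosomes are excluded by default (configurable): hemizygous X/Y
would count as LOH in males and bias `frac_loh` by sex. Copy numbers must
be integers; non-integer input is rejected rather than rounded, because a
non-integer allele-specific state indicates an upstream fitting problem.

Segments with integer coordinates make all three statistics ratios of exact
integer sums, so they agree bit-for-bit with a per-base enumeration; the
test suite exploits this for an exact oracle check.

## Clonality and assay routing

The cancer cell fraction of a mutation with biopsy variant allele frequency
`v`, tumor purity `ρ`, locus total copy number `CN` and mutant multiplicity
`m` is `v·(ρ·CN + 2(1−ρ))/(ρ·m)`, clamped to [0, 1] since read-sampling
noise can push the raw value slightly above 1. Multiplicity is estimated by
nearest-integer rounding (half-up) of the unclamped mutant-copies estimate,
clamped to [1, major CN]. Mutations with CCF < 0.9 (strict) are subclonal
and excluded from plasma tracking. Patients whose clonal mutations overlap
a ddPCR assay panel are routed to ddPCR, all others to deep sequencing; the
two assays are modelled with a single detection mechanism downstream, which
is justified when their positivity rates are equivalent.

## ctDNA positivity caller

Background sequencing error at each tracked site is modelled per strand as
beta-binomial with mean `μ` and overdispersion `ρ ∈ [0, 1)`. Fitting uses
the method of moments on per-normal error proportions, with a pseudocount
of 0.5 alt reads per normal so error-free sites keep `μ > 0` (this also
makes the null slightly conservative, which is the right direction for a
detection assay). `ρ` is the excess of the observed variance of proportions
over binomial sampling variance; it is floored at 0, and `ρ = 0` falls back
to the exact binomial tail — the two code paths agree to 10⁻¹⁰ and the
beta-binomial path converges to the binomial one as `ρ → 0`.

A plasma observation is tested per strand with the exact upper tail
P(X ≥ alt); the site statistic is `max(p_fwd, p_rev)` — both strands must be
individually significant (strand-AND), which suppresses strand-specific
artifacts. A strand with zero depth makes the site uninformative (statistic
1, flagged). The sample is positive iff any tracked site has a combined
statistic **strictly** below α = 0.05; no multiple-testing correction is
applied across the ≤ 12 tracked sites by default (the any-site rule is the
assay's decision rule; a Bonferroni option exists). This caller is a
frequentist tail-probability test, not a Bayesian posterior model; only the
decision rule (threshold 0.05, strand-AND, any-site) is treated as the
contract.

## Synthetic cohort generator

The generator exists so every downstream stage can be exercised and the
shedding/limit-of-detection mechanism probed quantitatively. Defaults
emulate a surgical colorectal-cancer cohort: stages I/II/III at 20/48/32%,
WGD prevalence 54%, median tumor diameter 40 mm (per-stage lognormal sizes
with stage I smaller), location 45/32/23% right/left/rectum, 93%
adenocarcinoma, venous invasion and mismatch-repair deficiency rates varying
by stage, and overall ctDNA positivity near 63%.

**Copy-number profiles.** 22 autosomes are cut into Poisson-distributed
pieces and assigned states around a baseline of 2/2 (WGD+, with segmental
losses, LOH and gains) or 1/1 (WGD−, with gains and deletions), with a
per-sample event-intensity scatter. Profiles are resampled until the
realised MCN-rule call matches the requested label (rarely needed), so the
generator's labels are consistent by construction with the MCN rule while
the LOH rule remains free to disagree — the two rules agree on ~94% of
generated profiles (kappa ≈ 0.87), computed, not asserted.

**Shedding model.** Plasma tumor fraction is

```
tf = base · size_mm^e · stage_mult · pT4_mult · (ploidy/2 if ploidy_effect)
     · exp(σ·T),   T ~ Student-t(df)
```

clamped to [0, 0.5], with defaults `base = 4.6e-5` per mm, `e = 1`,
stage multipliers 1 / 1.5 / 3.6, pT4 multiplier 2.5, `σ = 0.75`, `df = 3`.
A fraction (22%) of tumors are additionally attenuated 300-fold
("low shedders"): biologically sequestered tumors whose plasma signal is so
far below the limit of detection that doubling per-cell DNA cannot rescue
it. Two modelling choices deserve comment. The Student-t (rather than
normal) log-scale noise and the low-shedder mixture both encode the
empirical observation that plasma tumor fractions span orders of magnitude
at fixed stage and size; mechanistically they are also what lets the WGD
odds ratio *decay* toward 1 in high-shedding strata — with thin-tailed
noise, a detection threshold produces probit-type dose–response curves
whose odds ratios do not shrink at high baseline positivity. The per-cell
DNA effect enters only through the `ploidy/2` factor, so setting
`ploidy_effect=False` is a clean ablation: the WGD–detection association
then vanishes in every stratum.

**Detection.** Tracked mutations are assumed heterozygous, so the expected
mutant allele fraction is `tf/2` plus the background error (10⁻⁴ per strand
by default); strand counts are binomial at half the effective depth, where
effective depth is raw depth capped by the number of cfDNA genome
equivalents sampled from 8 mL plasma (4000 by default — the physical limit
of detection). The ctDNA label is produced by the actual caller against a
panel of 46 simulated normals, never by thresholding `tf` directly.

Calibration: the shedding scale and stage multipliers were chosen once so
that the default configuration reproduces the qualitative cohort structure —
overall positivity in the low 60s (%), stage positivity increasing I→III,
stage-stratified WGD odds ratios decreasing from ≈2 in stage I to ≈1 in
stage III — rather than fitted to any patient-level data. What passing
simulations show is that the mechanism *suffices* to produce that
structure; they cannot show that real tumors follow this functional form,
that shedding is log-t distributed, or that the low-shedder fraction is
22%. Real data would also carry purity/segmentation noise in the
copy-number profiles and non-exchangeable background errors across plasma
samples, none of which the generator emulates.

**Problem sizes.** Mechanism checks use cohorts of n = 5000 with a pinned
seed (the default seed 0); logistic parameter recovery uses 200 replicates
of n = 5000; null-specificity checks use 10⁴ replicates; rule-agreement
checks use 500 profiles. These sizes keep Monte-Carlo error comfortably
below the effect sizes being asserted.

## Association statistics

Odds ratios are the 2×2 cross-product `ad/bc`; a zero cell triggers the
Haldane–Anscombe 0.5 correction (flagged), and two zero cells sharing a
margin leave the estimate undefined. P-values are two-sided Wald tests on
the log odds ratio. Confidence intervals default to Wald
(`exp(ln OR ± 1.96·SE)`); a profile-likelihood interval is available, which
profiles the intercept of the one-covariate logistic likelihood numerically
and inverts the likelihood-ratio statistic at χ²₁(0.95) — some published
cohort intervals match the profile rather than the Wald construction, so
both are exposed and point estimates are the quantity treated as exact.

The multivariable model of detection is logistic regression (IRLS maximum
likelihood) on WGD, UICC stage (reference I), tumor type (reference
adenocarcinoma), venous invasion, tumor size in continuous mm (per-mm odds
ratio), location (reference right colon) and MMR status (reference
proficient), with complete-case deletion of rows with missing covariates.
Coefficients with |β| > 15 on the log-odds scale are treated as evidence of
perfect separation and reported as an error naming the term, rather than
returned with meaningless standard errors. Cohen's kappa uses
marginal-product expected agreement; when both raters are constant, chance
agreement is 1 and kappa is undefined — the error carries the raw percent
agreement.

## Numerical and interface choices

* Segment TSVs follow the ASCAT output dialect (`sample, chr, startpos,
  endpos, nMajor, nMinor`, 1-based inclusive) and are converted to the
  internal 0-based half-open convention on read and restored on write;
  malformed rows are reported with their line numbers.
* All formats are plain TSV/CSV; integer columns round-trip exactly, reals
  are written with 6 significant digits.
* CLI runs write a `run_info.json` with tool version, config hash and seed;
  a fixed seed reproduces simulated outputs byte-for-byte.
* Ties in multiplicity rounding (x.5) round half-up; CCF clamps to [0, 1];
  tail probabilities at zero observed alt reads are 1 by construction.

## Known limitations

The caller is a simplified stand-in for full Bayesian strand-aware variant
callers and does not model UMI family structure or site-specific error
heterogeneity beyond the per-site beta-binomial. The generator's shedding
law is a modelling choice, exposed in configuration, not an estimate. The
profile generator produces clean integer states; it does not emulate ASCAT
failure modes (low purity, high heterogeneity) that real pipelines must QC
away.
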