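# Methods

## The design being modeled

The package implements a two-stage extreme-endophenotype design for finding
low-frequency coding variants that move CSF biomarkers of Alzheimer's disease.
Stage one sequences pooled DNA from subjects in the tails of the
covariate-adjusted CSF Aβ42/tau/ptau distributions (an "AD-like" pool: low
Aβ42 or high tau/ptau; and its opposite), calling rare variants with a
control-calibrated error model. Stage two genotypes the surviving variants in
the full cohort and tests association with the quantitative biomarkers,
amyloid-deposition status stratified by APOE-ε4, case-control status, and age
at onset.

## Synthetic cohort generator

`synthetic.simulate_cohort` draws, per subject: platform (A emulating a
plate-ELISA series, B a bead-based series), age, sex, CDR, APOE-ε4 dose
(binomial under Hardy–Weinberg on the allele frequency implied by the
configured carrier fraction), and genotypes (binomial(2, MAF), i.e.
Hardy–Weinberg).

Biomarkers are generated on the natural-log scale:
`log value = platform intercept + covariate effects + variant effect + noise`,
exponentiated to pg/mL. Platform intercepts are anchored to the observed
medians (Aβ42 551 vs 155 pg/mL, tau 283 vs 82, ptau 54 vs 29.5), giving the
~10-fold cross-platform scale difference the normalisation step must absorb.
Because downstream standardisation centers but never rescales, a generating
coefficient (default β_tau = 0.14, β_ptau = 0.12, β_Aβ = −0.05 per minor
allele) equals the regression coefficient on the analysis scale. Log-scale
noise SDs (0.4–0.5) reproduce the order-of-magnitude min–max ranges of the
real assays.

**Deposition interaction.** The variant × APOE-ε4 interaction is planted on
the deposition liability, not as a direct tau effect: deposition is Bernoulli
with logit = ln(baseline odds) + ln(OR_ε4)·[ε4+] + ln(OR_both/OR_ε4)·[ε4+ and
carrier] (defaults 4.5 and 18), and raw Aβ42 is then drawn from the platform
log-normal truncated to the matching side of the deposition cutoff
(500/192 pg/mL). With no other liability terms, the stratified 2×2
cross-product ORs equal the configured values in expectation, which is what
the recovery tests check.

**Age at onset.** A latent onset age N(78.2, 8²) shifted −4.3 years for
carriers determines both case status and AAO: a subject is a case when onset
falls within a platform-level margin of their current age, the margin set by
quantile so each platform hits its configured case prevalence (27%/60%).
Carriers of the earlier-onset allele are thereby over-represented among
cases *and* earlier-onset within them — the hazard structure a Kaplan–Meier /
log-rank analysis of carriers vs non-carriers (controls right-censored at
their assessment age) actually has power against. An earlier design that
drew case status independently of genotype produced crossing hazards whose
log-rank contributions cancel almost exactly; the latent-onset coupling is
the package's resolution. A cosmetic consequence is that a few cases carry an
onset age slightly above their recorded age (a retrospective-diagnosis
reading).

**Reads and controls.** Amplicon panels are random ACGT sequences with
annotated variant sites; every panel carries one positive-control amplicon
(default 10 engineered sites at 1 copy per 250) and one 1908-bp variant-free
negative control. 36-bp single-end reads are placed uniformly over valid
start offsets; at a truth site each covering read carries the alternate
allele with probability k/(2N) (engineered frequency for controls); per-cycle
substitution errors are injected independently per base with a default
profile rising linearly 0.001 → 0.005 along the read. Quality strings are a
constant placeholder: the error model is cycle-based, not quality-based. No
indels, PCR duplicates, GC bias or haplotype structure are simulated, so
passing tests say nothing about alignment ambiguity or context-dependent
error in real data.

## Pool caller

The error model is per-cycle: rate_c = (mismatches_c + 0.5)/(bases_c + 1), a
Jeffreys-style floor so a clean control never yields a zero rate, fit only on
bases landing in the first 900 bp of the negative control (the trained prefix
is configurable; specificity is evaluated over the full 1908 bp including the
prefix). A site's expected error is the coverage-weighted mean of the rates
over the cycles observing it, divided by 3 to convert any-mismatch into a
specific alternate base under substitution symmetry. The per-site p-value is
the exact binomial upper tail for the strongest alternate base. Because that
base is the argmax over three alternates, the per-site null rate can be up to
3× the nominal level; the per-alternate tails are individually superuniform
(`per_alt_pvalues`, property-tested), and the selection effect is absorbed by
the control calibration, which sets the cutoff empirically. Ties at the
threshold pass (inclusive comparison), so every positive-control spike is
recovered by construction.

This is a faithful-contract reimplementation of control-calibrated pooled
base calling — error model from the negative control, per-site p-value,
cutoff at the least stringent value recovering all spikes — not a
bit-identical port of any published caller's internals.

Follow-up filters: p ≤ threshold, per-allele coverage n/(2N) ≥ 30,
consequence ∈ {missense, nonsense, splice}, estimated pool MAF < 5%. The
pipeline's default sequencing target is 35× per allele: 30× is the minimum
the per-site filter demands, and at an average of exactly 30× the realized
binomial depth falls below it at half of all sites, so runs are targeted
above the minimum — mirroring how real runs are laned to keep every position
over the floor.

## Statistics

* OLS and logistic fits run through statsmodels (logistic via GLM/IRLS,
  tolerance 1e-8, 100 iterations); separation is flagged (diverging
  coefficients or pinned fitted probabilities), never silently returned.
  Rank-deficient designs raise an error naming the collinear columns, which
  is how a conditional model on a perfectly correlated SNP reports itself.
* Fisher's two-sided p uses the point-probability rule (scipy), which is the
  definition that reproduces the printed interaction-stratum p = 3.5×10⁻³;
  the Pearson χ² carries no continuity correction, matching the printed
  replication-stratum statistic (14.06 on the WU counts). Both are checked
  against full enumeration oracles on all tables with total ≤ 40.
* Odds ratios are cross-products with Woolf intervals at z = 1.96 exactly
  (not Φ⁻¹(0.975) to more digits), the convention under which the printed
  intervals reproduce. A zero cell yields a flagged degenerate OR (0 or ∞)
  with an undefined CI — no silent Haldane correction. One printed upper
  bound (166.8 on the deposition carrier stratum) computes to 166.73 by the
  exact formula and is compared at the printed 0.1 resolution; it reproduces
  exactly only if the reciprocal cells are rounded to three decimals first.
  Covariate-adjusted published ORs (10.7, 9.3, 10.1) do not reproduce from
  raw counts and are stored with zero reproducibility flags; only direction
  is meaningful for them here.
* Meff uses greedy LD pruning (drop a SNP whose r² with any retained SNP
  exceeds 0.8; Meff = retained count); a spectral (simpleM-style) count is
  available as `method="eigen"` with no claim of equivalence. The
  variant-level discovery threshold 7.0×10⁻³ is a configuration default
  (consistent with 0.05 over ~7 tests, the divisor being unstated), not a
  derived constant.
* Ratio phenotypes (tau:Aβ42, ptau:Aβ42) are formed on raw values, then
  log-transformed and platform-centered like the primary phenotypes.
  Extreme-tail ties are broken by value then subject id (deterministic);
  subjects qualifying for both pools are flagged and assigned to neither.
  A value exactly at a deposition cutoff counts as no deposition.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the whole
suite stays in a couple of minutes: calibration simulations use a 114-subject
pool at 30× per allele (≈6,840 reads-bases per site; ~0.5 M reads per run);
recovery studies use 100 seeded cohorts of n = 5,000 (β_tau coverage),
200 cohorts of n = 3,000 (stratum-OR coverage; zero-cell replicates are
excluded and rare), 200 cohorts of n = 700 (pool enrichment at MAF 0.02,
0.5-SD effects) and 100 seeds of n = 5,000 for the conditional analysis
(proxy at r² = 0.68 via a D′ = 1 haplotype construction). The pipeline's toy
default is a ~700-subject cohort with a slimmed panel.

## Known limitations

Single-strand, single-pool calling only (no joint calling, no strand-bias or
base-quality filters); no indels; no population structure, relatedness or
imputation; ORs are unadjusted cross-products (no Mantel–Haenszel or
Breslow–Day); the published pool-size bookkeeping (which pool held 114 vs 98
subjects) is inconsistent across sources, so pool sizes are configuration,
and the simulator takes no side.
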