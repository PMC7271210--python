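# Methods

This note documents the models behind each module, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
numerical and design choices that were genuinely open.

## Fine-mapping

Evidence for association at variant *j* is the Wakefield-style approximate
Bayes factor computed from the estimated effect β_j and its variance
V_j = se_j², against a zero-centred Gaussian prior on allelic effects with
variance ω:

log Λ_j = ½ log(V_j/(V_j+ω)) + ω β_j² / (2 V_j (V_j+ω)).

ω defaults to 0.04 (prior SD 0.2 per allele). That value originates in
log-odds-ratio scale analyses but is conventionally applied unchanged to
quantitative traits; it is exposed as a parameter because the posterior
ranking is insensitive to ω but the absolute Bayes factors are not.

Assuming exactly one causal variant per (conditioned) signal, the posterior
probability of causality is the normalised Bayes factor, computed as
exp(logΛ_j − logsumexp(logΛ)). The 99% credible set takes variants in
descending posterior order until the cumulative posterior reaches the level.
Exact posterior ties are broken by ascending genomic position, then variant
id — an arbitrary but deterministic convention. The module assumes its
input is already conditioned to one signal; multi-signal decomposition
(stepwise conditioning, sum-of-single-effects) is out of scope.

Numerics: all Bayes-factor arithmetic stays in log space; |β|/se up to 100
and far beyond cannot overflow. Rows with missing β or se are dropped with a
warning; non-positive se is an error naming the variant (silent acceptance
would corrupt the posterior).

## Colocalisation

For two traits measured over the identical variant list, the module
enumerates the standard five hypotheses under at-most-one-causal-variant per
trait. Per-variant log Bayes factors for each trait use the fine-mapping
formula with trait-specific prior effect variances w1, w2; the hypothesis
weights are

H0 = 1, H1 = p1·S1, H2 = p2·S2, H3 = p1·p2·(S1·S2 − S12), H4 = p12·S12,

with S1 = Σ e^{la_j}, S2 = Σ e^{lb_j}, S12 = Σ e^{la_j+lb_j}. Priors default
to p1 = p2 = 1e-4, p12 = 1e-5 per variant. The trait prior effect variance
defaults to w = 0.0225 (prior SD 0.15), the conventional quantitative-trait
choice; results are sensitive to it, so it is a first-class parameter.

The decision rule declares **colocalised** when PP3+PP4 ≥ 0.99 and
PP4/PP3 ≥ 5, **distinct** when the sum passes but the ratio fails, and
**ambiguous** otherwise. PP3 = 0 (e.g. a single-variant region, where H3 is
impossible) counts as the ratio being satisfied, since PP4/PP3 → +∞.

Numerics: S1, S2, S12 are computed by log-sum-exp; the H3 difference uses
log1p(−exp(lS12 − lS1 − lS2)) and clamps to zero with a warning if
cancellation drives it negative. Variant alignment is strict by id; no
allele harmonisation is attempted because both tables are expected to come
from the same simulated panel or pre-harmonised files.

## Allelic expression imbalance

The forward model for the allelic-discrimination readout is affine with
Gaussian noise: observed %EA = slope · true %EA + intercept + ε. The
calibration procedure fits an ordinary least-squares line through the
per-level *means* of the standard-curve observations (mix levels 30, 40, 50,
60, 70 %EA, three replicate pairs each by default) and inverts it for
experimental samples. A straight line is the minimal monotone calibration
and is exact for ideal mixing; the fitted slope must exceed a small
threshold (default 0.05) or calibration fails — inverting a flat or
decreasing curve would be meaningless. Estimates are clipped to [0, 100]
with a warning rather than erroring, because single noisy wells near the
boundary are expected in practice.

Imbalance is tested per tissue/fraction group by a two-tailed paired t-test
of %EA in cDNA against the paired gDNA of the same heterozygous subjects.
Calibrated estimates are tested by default (raw observed values behind a
flag); for a strictly affine assay the t statistic is identical either way
since calibration is a common affine map, so the choice only matters for
non-linear deviations. Zero-variance differences are given their limiting
values (t = 0, p = 1 when the mean difference is also zero) instead of the
NaN a naive implementation produces.

Delta-Ct quantification: relative expression = efficiency^(calibrator Ct −
sample Ct), normalised to the geometric mean of the reference genes'
relative expressions (geometric mean is the standard combiner for
multiplicative quantities; with one reference it reduces to the usual
ratio). Amplification efficiency defaults to 2 (perfect doubling per cycle).

## Morphometry and growth

Adipocytes are treated as spheres whose cross-sections are circles:
d_hist = 2√(A/π) from the measured area, the real diameter d = 1.1·d_hist
(fixed histological shrinkage correction, applied after the area→diameter
conversion), V = πd³/6, w = 0.915·V × 10⁻¹² g. Biopsy summaries convert the
median area — not the mean of per-cell weights, which the cube law would
inflate; the median of per-cell weights is reported alongside and agrees up
to median interpolation because the conversion is monotone. Panels under
250 cells trigger a warning (small panels estimate the median poorly).

Matched comparisons use the two-tailed Wilcoxon signed-rank test: zero
differences are dropped before ranking; an all-zero difference vector gives
p = 1 by convention; the exact null distribution is used up to 25 non-zero
pairs and the normal approximation with continuity correction above.

Zebrafish metrics: generalised adiposity = 100 · total adipose-lipid area /
body area; regional fat distribution = abdominal/peripheral depot-area
ratio. A fixed wild-type regression (mass(mg) = 4327.4627 + 0.0004094 ·
body area) converts body area to a mass proxy; it is flagged as valid for
wild-type animals only, since mutant body composition can distort the
area–mass relationship.

Doubling time between two counts is T_d = (t₂−t₁)·log2 / log(q₂/q₁);
negative values (shrinking cultures) are returned with a warning, equal
counts raise. A least-squares alternative (1/slope of log₂ count on time)
uses all timepoints; the two-point formula is the reference behaviour.

## Cohort statistics

The additive model regresses log(trait) on allele dosage plus covariates
(and optionally a conditioning variant's dosage) by OLS; the reported β is
the per-allele effect on the log trait, which makes it invariant to trait
rescaling. Rank-deficient designs raise an error naming the collinear
columns. Missing data are handled by complete-case analysis with a logged
count; sex-stratified analyses reuse the same code path via a `stratify`
argument; an optional Bonferroni multiplier on p is off by default.

Partial Spearman correlation: mid-rank both variables, residualise the
ranks on the covariates by least squares, correlate the residuals, and take
p from t = ρ√((n−2−k)/(1−ρ²)) with n−2−k degrees of freedom. With no
covariates this is the ordinary Spearman correlation, and it is invariant
to strictly monotone transforms of either variable.

## Synthetic data: what it emulates, and what it does not

Genotypes: each individual is two independent haplotypes; within a
haplotype, allele j is 1 when a latent standard-normal AR(1) process (lag
correlation `ld_rho`) falls below Φ⁻¹(f_j), so each variant's frequency is
f_j (drawn uniformly from `maf_range`) and LD decays geometrically with
marker separation. This gives controllable pairwise r² but none of the
block structure, recombination hotspots, allele-frequency spectrum or
coordinates of real genomes. Traits are additive with Gaussian noise —
no dominance, epistasis, or covariate confounding at the region level.

Colocalisation pairs share one genotype panel and differ only in which
causal indices each trait receives; trait noise is independent between
traits, so H4 pairs share a causal variant but not residual correlation.

AEI readouts follow the affine-plus-noise model above with truncation to
[0,100] (truncations counted and warned). Adipocyte areas are log-normal
per group; cell growth is exponential with mean-one multiplicative
log-normal noise (σ² = log(1+cv²)), keeping counts positive and the
expected curve unbiased. Cohort tables draw age uniformly (30–65 y), sex as
a fair coin, percent fat as clipped Gaussian, and code menopause as female
and age ≥ 51 years.

Passing tests therefore demonstrate correctness of the estimators under
these generating models — not robustness to real-data pathologies such as
imputation error, allele flips between studies, batch effects, or
non-log-normal cell-size distributions.

Determinism: every generator seeds `numpy.random.default_rng` from
(config seed, fixed per-generator stream constant), so stages can be re-run
independently and identical configs are bitwise reproducible.

### Default simulation magnitudes

Study-scale effect sizes and sample sizes for the region simulations are
not published quantities, so the defaults are chosen for clear statistical
power at desk scale: regions of 20–50 variants, 1000–5000 individuals,
ld_rho 0.9, per-allele effects 0.15–0.6 trait SD. Scenario-recovery and
calibration checks use 200–2000 replicates; coverage of the 99% credible
set is assessed over 300 regions at moderate power (0.10 SD effects,
n = 2000), where approximate Bayesian coverage — not exact frequentist
coverage — is the claim being checked.

## Known limitations

* Single-causal-variant assumption throughout fine-mapping and per-trait in
  colocalisation; no joint multi-signal modelling.
* The coloc decision rule's ratio is undefined at PP3 = 0 and is defined
  here as satisfied; alternative conventions exist.
* The AR(1) latent-Gaussian LD model understates long-range LD; credible-set
  span statistics on synthetic data should not be compared to real loci.
* The default standard-curve model is a straight line; a monotone
  piecewise-linear interpolation (`estimate_ea_interp`) is available for
  assays with mild non-linearity, but strongly sigmoidal assays are outside
  both models.
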