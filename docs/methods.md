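# Methods

## Scope and data model

`mrpipe` implements two-sample Mendelian randomization entirely on
summary statistics: every SNP is a row of
(id, chromosome, position, effect allele, other allele, effect-allele
frequency, beta, SE, p, N), and the causal analysis consumes
harmonized per-SNP pairs (β̂X, σX, β̂Y, σY). Continuous traits are
assumed standardized (betas in SD units); binary outcomes are on the
log-odds scale with normal sampling error, the standard asymptotic
treatment of biobank logistic-regression GWAS output. No
individual-level genotypes are touched anywhere.

## Instrument selection

Significance filtering is strict (p < threshold; a SNP exactly at the
threshold is excluded). Clumping is the conventional greedy algorithm:
SNPs are visited in ascending p-value (ties broken by chromosome,
position, then id, so the result is deterministic and invariant to
input row order); a SNP is kept iff no already-kept SNP on the same
chromosome within the window (|Δpos| ≤ window·1000 bp) has r² at or
above the cutoff. Pairs absent from the supplied LD matrix are assumed
independent with a warning, since the reference panel an analyst would
use (e.g. 1000 Genomes Europeans) is not shipped.

Per-SNP variance explained uses the standardized-trait approximation
R²j = 2p(1−p)β², summed over instruments;
F = R²(N−k−1)/(k(1−R²)) with N the study sample size (the maximum
per-SNP N when no study-level N is supplied, since summary files often
carry "up to N" values). F ≤ 10 sets a weak-instrument flag.

## Harmonization

Allele alignment tries, in order: identical coding (keep), swapped
alleles (negate the outcome beta, complement its frequency), strand
complement (recode, then the same swap logic). Anything else is
dropped with a reason code; there is no proxy-SNP substitution.
Palindromic SNPs (A/T, C/G) are inherently strand-ambiguous; the
default policy infers orientation by comparing the reported
effect-allele frequencies to 0.5 on both sides and drops SNPs whose
frequency falls inside the ambiguity band (default 0.42–0.58, the
range where sampling noise makes the comparison unreliable). A strict
`drop_all` policy is available. Palindromic SNPs with a missing
frequency on either side are always dropped: orientation is then
unknowable. Indels are never treated as palindromic. For palindromic
SNPs the frequency comparison subsumes the label-based swap logic (a
label swap plus a frequency-disagreement flip reduces to comparing the
two reported frequencies directly), which is how it is implemented.

## Estimators

* **IVW with multiplicative random effects.** Weighted mean of Wald
  ratios with first-order weights β̂X²/σY² (equivalently, WLS of β̂Y on
  β̂X through the origin with weights 1/σY² — the test suite checks
  this equivalence to 1e-10). The fixed-effect SE 1/√Σw is multiplied
  by max(1, √(Q/(n−1))): over-dispersion widens the CI, but the CI
  never narrows below the fixed-effect one. Inference uses exact
  normal quantiles.
* **MR-Egger.** Instruments are first oriented so β̂X ≥ 0 (flipping
  both betas of a SNP leaves its ratio unchanged). WLS with intercept
  and weights 1/σY² (delegated to statsmodels; an independent
  normal-equations oracle backs the tests), residual dispersion
  floored at 1, inference on t with n−2 df — the residual-variance
  estimate has n−2 degrees of freedom, and whether published analyses
  used normal or t quantiles is rarely stated, so the choice here is
  fixed and documented. The intercept estimates average directional
  pleiotropy; its p-value is the pleiotropy test.
* **Weighted median.** Ratios ordered ascending; the estimate
  interpolates the standardized mid-cumulative weight s_j = (Σ_{i≤j}
  w_i − w_j/2)/Σw at 0.5. SE by parametric bootstrap (default 1000
  replicates): each replicate redraws every (β̂X, β̂Y) from normals at
  the observed values with the reported SEs. The bootstrap is seeded
  and reproducible.
* **Cochran's Q** of the ratios around a reference estimate, with
  upper-tail chi-square (n−1) p-value; p < 0.05 is flagged as
  significant heterogeneity.
* **Leave-one-out.** IVW re-fit with each SNP omitted. A SNP is
  influential if its omission flips the sign or moves the estimate by
  more than the omitted-set SE; the omitted-set SE (not the
  full-sample SE) is used because a gross outlier inflates the
  full-sample random-effects SE enough to mask its own influence.
* **Unit rescaling** multiplies beta/SE/CI by a positive factor (e.g.
  ln 1.5 to express an effect per 50% increase of a log-transformed
  exposure); z-scores and p-values are unchanged.

## MR-PRESSO

The global statistic is RSS_obs = Σj wj(β̂Y,j − b₋j β̂X,j)² with b₋j
the leave-one-out IVW slope and wj = 1/σY,j². The null distribution
redraws β̂Y,j* ~ N(b₋j β̂X,j, σY,j²) and β̂X,j* ~ N(β̂X,j, σX,j²) and
recomputes the statistic (including the leave-one-out slopes)
n_sim times; all slopes are computed in closed form so the simulation
is fully vectorized. Per-SNP outlier p-values compare each observed
residual contribution with its simulated distribution, flagged at the
Bonferroni-corrected level over the instruments tested. The corrected
estimate is IVW on unflagged SNPs; the distortion statistic
(b_corrected − b_all)/|b_corrected| is tested two-sidedly against a
null built by deleting random pseudo-outlier sets of the same size.
Monte-Carlo p-values use the add-one correction (r+1)/(n_sim+1), so
the smallest attainable p is 1/(n_sim+1); n_sim defaults to 1000,
which resolves Bonferroni thresholds down to ~0.001. The distortion
p-value is reported as NA exactly when no SNP is flagged. All draws
run off a single seeded generator; identical seeds give identical
flags and p-values.

## Meta-analysis and mediation

Fixed-effect pooling on the log-odds scale with weights 1/σ²;
Q and I² = max(0, (Q−(k−1))/Q)·100 with the 25/50/75 bands
(low/medium/high/extreme). Published per-cohort rows enter through a
CI→SE conversion that uses 1.96 exactly — printed tables are built
with 1.96, and using the exact quantile there would introduce spurious
last-digit drift — while CIs the package computes itself use the
exact normal quantile.

Two-step mediation multiplies the exposure→mediator coefficient (A)
by the mediator→outcome coefficient (B) to form the indirect effect,
and divides by the total effect for the mediated proportion (rounded
to an integer percentage in table output, full precision retained).
The SE of A·B is the first-order delta method √(A²σB² + B²σA²) with no
covariance term: in two-sample MR the two steps come from disjoint
instrument-outcome regressions. The proportion is reported even when
it falls outside [0, 1] or the signs of indirect and total disagree;
an `inconsistent` flag marks those rows instead of hiding them. In
the full pipeline, step B uses the mediator's own genome-wide
significant instruments, not the exposure's — each step is a
univariable MR in its own right.

## Synthetic data generator

The generator simulates summary statistics directly under the
two-sample model: MAF ~ Uniform(maf_range), γj ~ N(γ̄, σγ²),
σX,j = 1/√(2pj(1−pj)N_X), β̂X,j ~ N(γj, σX,j²),
β̂Y,j ~ N(θγj + αj, σY,j²). Pleiotropy modes: none, balanced
(mean-zero α), directional (non-zero mean, InSIDE holds), and
InSIDE-violating (α correlated with γ through a Gaussian copula).
Allele handling mimics cross-consortium files: an exact fraction of
SNPs get palindromic pairs, a fraction of outcome rows are reported on
the opposite strand, a fraction are missing from the outcome, and the
outcome frequency carries small (SD 0.005) cross-cohort noise. The LD
matrix is block-diagonal with r² = ρ^|i−j| inside blocks; LD is
independent of effect sizes, so clumping is exercised structurally
rather than genetically. Blocks are laid out ≥ 20 Mb apart so distinct
loci never interact within a standard clumping window.

Defaults emulate a well-powered anthropometric exposure GWAS against a
biobank binary-outcome GWAS: 30 instruments with mean per-allele
effect 0.03 SD (per-SNP F well above 10 at N = 200,000),
N_outcome = 100,000, 15% palindromic, 10% strand-flipped, 5% missing
in the outcome. These are realistic magnitudes for the settings the
pipeline targets, chosen once and used by all simulation-based tests.

For mediation triples the mediator inherits the exposure effects
scaled by β_EM, and — a deliberate design choice — can receive its own
mediator-specific instruments (exposure effect zero, mediator effect
δj ~ N(δ̄, σδ²), outcome effect β_MO·δj). Without them, every mediator
instrument would act through the exposure and step B would estimate
β_MO + θ_direct/β_EM rather than β_MO; real two-step MR avoids this
precisely because the mediator GWAS contributes its own hits. With
`n_mediator_snps = 0` the generator reduces to the shared-instrument
model. The recorded truth includes θ_total = θ_direct + β_EM·β_MO and
the implied mediated proportion.

What the generator does **not** emulate: realistic allele-frequency
spectra, population stratification, sample overlap between the two
GWAS, winner's-curse selection of instruments, and LD-induced
correlation of effect estimates. Passing tests therefore demonstrate
correctness of the estimators under the stated sampling model, not
robustness to those real-data complications.

## Validation design

* Algebraic oracles: IVW vs WLS-through-origin, Egger vs explicit
  normal equations, weighted median vs a from-definition scan, meta
  vs a brute-force weighted mean (1e-10/1e-12 agreement), clumping vs
  an independent brute-force greedy scan.
* Calibration: under θ = 0 with no pleiotropy, IVW's type-I error at
  α = 0.05 is checked to lie in [0.035, 0.065] over 2000 seeded
  replicates; Q and the MR-PRESSO global p are checked for
  near-uniformity (KS at α = 0.01).
* Recovery: IVW recovers θ, Egger recovers slope and intercept under
  directional pleiotropy with InSIDE (simulated at N_exposure =
  500,000 so regression-dilution attenuation of the Egger slope is
  negligible relative to Monte-Carlo error), and the two-step pipeline
  recovers the mediated proportion — each within 3 Monte-Carlo SEs
  over 200 replicates.
* MR-PRESSO: a planted 10-residual-SD outlier among 30 clean SNPs
  must be flagged in ≥ 95% of replicates at n_sim = 1000.
* Published arithmetic: the four mediated-proportion cells
  (27/25/13/14%) and the three combined ORs (1.02, 1.017, 0.986 with
  their CIs) are reproduced exactly from printed per-cohort inputs.

Replicate counts (2000 for calibration, 200 for recovery, 100–200 for
MR-PRESSO) are the package's chosen desk-scale study sizes: large
enough that Monte-Carlo error is well below the tolerances being
asserted, small enough to keep the whole suite under a minute of
simulation time.

## Numerical choices and edge cases

* Significance filtering is strictly `<`; clumping ties break
  lexicographically; all simulation and bootstrap draws flow from
  explicit seeds (numpy `default_rng`).
* SNPs with β̂X = 0 have undefined ratios and are dropped with a
  warning; estimators raise a typed error below their minimum
  instrument counts (IVW 2, Egger/median/leave-one-out 3, PRESSO 4).
* Empty selection results are legal (logged) so that threshold sweeps
  do not throw; downstream estimators fail loudly instead.
* p-values read from files are validated against |β/σ| under a
  two-sided normal test at 10% relative tolerance — as a warning
  only, because published files round p-values.
* MR-PRESSO raises a degenerate-correction error if every instrument
  is flagged.
* The p-value floor in generated tables is the smallest positive
  double, keeping (0, 1] validity for extremely strong instruments.

## Known limitations

* No multivariable MR, mode-based estimators, or contamination-mixture
  methods; no proxy-SNP lookup or live LD reference queries; no
  genome-build liftover; no VCF-encoded summary statistics.
* First-order Wald-ratio weights throughout (no second-order or
  exposure-uncertainty terms), matching common practice for the
  estimators implemented.
* The mediated-proportion SE is not propagated (only the indirect
  effect's delta-method SE is); ratio-of-estimates uncertainty for
  proportions would need a further delta step or bootstrap.
* Fixed-effect pooling only; with few cohorts a random-effects model
  is poorly identified anyway, but high I² values should temper
  interpretation of the combined CI.
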