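# Methods

This note documents the models, conventions and numerical choices behind
`restaq`, and what the synthetic-data validation does and does not show.

## Rest-activity metrics

Activity arrives as non-negative intensity per fixed epoch (5 s by
default). Raw high-rate streams are resampled to a uniform grid (100 Hz
default, linear interpolation), low-pass filtered with a 4th-order
Butterworth at 20 Hz applied forward and backward (zero phase; the
effective magnitude response is the squared Butterworth response), clipped
at zero, and averaged over half-open epoch intervals `[t, t + epoch_s)`.
Stretches with no samples for more than 1 s are coded missing, and every
epoch whose interval intersects such a gap is masked. Input already at
epoch resolution passes through unchanged (the filter targets machine
noise far above the epoch band), which makes epoching idempotent.

For each midnight-to-midnight day the epochs are aggregated into bins
(1 min default; a bin's value is the mean of its non-missing epochs) and
M10/L5 are the extremal means over all contiguous 10-h/5-h windows,
sliding one bin at a time with no wrap across midnight; the earliest
window wins ties. Relative amplitude is `RA = (M10 − L5)/(M10 + L5)`,
defined as 0 when the day is entirely at zero activity. RA is scale-free:
multiplying a day by any k > 0 leaves it unchanged. A day contributes to
a participant's mean RA only when at least 80% of its epochs are
non-missing and both windows are computable; participants with no valid
day are dropped with a logged reason. Whether partially missing days
should count is not settled by the protocol this mirrors; averaging valid
complete days only is this package's choice.

Comparators: interdaily stability and intradaily variability use the
standard hourly-mean formulations (variance of the mean 24-h profile over
total variance; mean squared successive difference over variance), with
the conventions IS = 1 and IV = 0 for a zero-variance signal. The cosinor
amplitude is the least-squares amplitude of `mesor + A·cos(2π(t−φ)/24)`
fit on the epoch-level series, period fixed at 24 h.

## Participant-level QC

A recording is excluded when (in this fixed attribution order): non-missing
wear time is below 72 h; some hour-of-day bin 0-23 contains no non-missing
epoch anywhere in the recording (hour coverage is pooled across days, not
per day); the device size flag, the calibration flag, or the
daylight-saving overlap flag is set. One reason per participant makes the
report's counts an exact partition of the input. The 72-h rule counts
non-missing wear only; whether missing epochs should count toward the
minimum is ambiguous in the source protocol and is documented here rather
than guessed silently.

## The low-RA phenotype

Cases are participants with mean RA strictly below
`mean(RA) − 2·sd(RA)`, sample SD with the n−1 denominator, computed on
the post-QC analysis sample; a value exactly at the threshold is a
control (configurable). Under a Gaussian RA distribution this yields a
case fraction of Φ(−2) ≈ 2.28%. Binary mood outcomes are case/control/
missing; "don't know"/"prefer not to answer" responses are missing. With
exclusivity on, a case for one lifetime diagnosis is set missing for the
others; a participant who is a case for more than one lifetime diagnosis
cannot be attributed to a single label and is set missing for all of
them — this is the only reading under which the labels are truly
mutually exclusive.

## Association scans

Variant QC keeps variants with imputation INFO ≥ 0.8, MAF ≥ 0.01 (MAF
from mean dosage) and Hardy-Weinberg p ≥ 1e-6. HWE is tested by a plain
1-df chi-square on hard calls (dosages rounded to the nearest genotype),
with a conditional exact test available behind a flag; monomorphic
variants fall to the MAF filter. The filters are order-independent and
idempotent.

The logistic scan fits, per variant, a maximum-likelihood logistic model
of case status on dosage plus covariates via Newton-Raphson/IRLS with
step-halving, warm-started at the covariate-only null fit. Convergence is
declared when the log-likelihood changes by less than 1e-8 (max 50
iterations), after which one extra Newton step polishes the solution to
machine precision — the scan agrees with an independent logistic
implementation to ~1e-15 and with the closed-form 2×2 log-OR/SE to well
below 1e-8. Non-converged or separated fits (|log-OR| > 15 or a
non-positive variance estimate) are reported as missing with a reason
code rather than Firth-corrected, keeping behaviour deterministic. The
in-package IRLS engine exists because a scan runs thousands of fits; a
general-purpose fitter is used as the cross-checking oracle in the test
suite, never silently trusted as the implementation.

The linear scan is exact OLS per variant computed by residualising the
phenotype and all dosages on the covariates (QR-based Frisch-Waugh),
with t-based p-values at n − k − 1 degrees of freedom; it matches a
direct OLS fit to machine precision. Genome-wide significance is labelled
at p < 5e-8.

λ_GC is the median association chi-square over the 1-df null median
0.45494 (chi-squares recovered from p-values by the inverse CDF when
needed). Calibration note: Wald tests for a binary trait with few cases
are mildly median-deflated; with ≈230 cases (2.3% of n = 10,000) the null
scan is calibrated to within the Monte-Carlo noise of a 2000-variant
median (SD ≈ 0.05 per scan), which is why calibration checks average a
few permutation replicates.

SNP heritability uses the single-component LD-score regression
`E[χ²_j] = intercept + (N·h²/M)·ℓ_j`, fit by two-step weighted least
squares: an OLS pass gives a provisional slope, then weights
`1/(2(1 + N·h²ℓ/M)²)` (the sampling variance of the non-central
chi-square mean) give the reported estimate and SE. Constant LD scores
make the slope unidentifiable and raise an error; because this package's
synthetic variants are mutually independent (all ℓ = 1), the scan-level
h² reported with a scan uses the constant-ℓ closed form
`h² = (mean(χ²) − 1)·M/N` with a mean-based SE, while the full regression
is exercised on simulated chi-squares with varying LD scores. Estimates
are deliberately not clipped, so null simulations can straddle zero and
coverage is honest. For a binary trait the estimate is on the observed
scale, not the liability scale.

## Polygenic scores

Scores sum effect-weighted effect-allele dosages over variants passing
each discovery p threshold (5e-8, 5e-5, 0.01, 0.05, 0.1, 0.5). Variants
are matched on (chromosome, position); when ref/alt are swapped relative
to the summary statistics the effect-allele dosage is `2 − dosage`, and
unmatched alleles are skipped with a count. Because discovery weights
come from the *low-RA* scan, a higher score means higher genetic
liability to rhythm disruption. No LD clumping is applied: the synthetic
variants are independent, so clumping would only discard signal; this is
a deliberate omission, not an oversight.

Scored samples are ranked (ties broken by stable sample order) into
quantile groups differing in size by at most one; when fewer distinct
score values exist than requested groups, each distinct value becomes a
group (three scores from a single significant SNP yield tertiles) and the
fallback is recorded. Top vs bottom groups are contrasted with a
logistic (binary outcome, odds ratio) or linear (neuroticism score, beta)
model adjusted for age, sex, Townsend index, array and eight PCs.
Benjamini-Hochberg FDR is applied within each outcome's six-threshold
family; grouping rows by outcome is an interpretation of the usual
reporting layout and is configurable to a single global family. Standard
step-up BH guarantees adjusted ≥ raw p-values.

## Synthetic cohorts

The generator is the package's study-conditions definition, not a
convenience fixture.

* **Actigraphy**: 7 days at 5-s epochs starting at a midnight; a daily
  square wave with a 10-h active block (onset 08:00) over a rest level,
  multiplicative gamma noise with unit mean and configurable CV
  (activity counts are non-negative and right-skewed; the gamma choice
  is a stand-in, not a claim about any particular device), iid epoch
  missingness, and Bernoulli device flags with rates mirroring the
  cohort protocol this emulates (DST 4.6%, size 0.03%, calibration
  0.1%). Transitions are instantaneous by default with an optional
  smoothing half-width. When the active block spans ≥ 10 h and the rest
  block ≥ 5 h the noiseless RA is analytically
  `(active − rest)/(active + rest)`, which anchors exactness tests; a
  per-participant RA target is honoured by solving for the rest level.
* **Genotypes**: independent biallelic variants in HWE, MAF uniform on a
  configurable range, hard genotypes Binomial(2, f), chromosomes 1-22
  with sorted positions, INFO uniform on [0.9, 1].
* **Covariates**: age ~ U(37, 73) (the recruitment range), sex ~
  Bernoulli(0.5), array ~ Bernoulli(0.1), PC1-8 and Townsend standard
  normal.
* **Phenotypes**: the RA liability is `G + c'X + e` with `G` from
  standardised dosages and noise scaled so the realised heritability of
  the covariate-free part equals the target; `mean_ra` maps the liability
  affinely to the observed RA scale (mean 0.87, SD 0.06). The
  *disruption* liability is the negated standardised covariate-free
  liability, and each outcome's liability is
  `ρ·disruption + √(1−ρ²)·ε`, thresholded at its empirical prevalence
  quantile. The correlation parameter is defined against the
  low-RA/disruption direction so that positive ρ makes a higher low-RA
  PRS predict more outcome cases — the orientation the whole analysis is
  built to detect. Neuroticism is an integer 0-12 obtained by rounding a
  rescaled liability (mean 4, SD 3, clipped).

What the simulations do **not** emulate: linkage disequilibrium and
population structure (PCs are pure noise covariates), relatedness,
imputation dosage uncertainty, device physics, non-wear behaviour
patterns, weekday/weekend structure, and the negative skew of real RA
distributions. Passing recovery tests therefore demonstrates the
statistical machinery is correct under its stated assumptions, not that
real-cohort estimates are unbiased.

## Validation sizes

Chosen as the smallest sizes at which the asymptotics under test are in
force: M10/L5 oracle equivalence on 220 random days at four bin sizes; RA
exactness on noiseless square waves (tolerance 1e-12) and bias < 0.01 at
CV 0.5 with 200 participants; null-scan calibration with 2000 variants at
n = 10,000 and 2.3% prevalence averaged over permutation replicates;
planted log-OR 0.4 at MAF 0.3, n = 5000, 100 replicates; h² regression
coverage at h² ∈ {0, 0.25} with 4000 variants and N = 40,000; end-to-end
overlap with h² = 0.3, 500 variants and 20,000 samples split into equal
non-overlapping discovery and target halves (ρ = 0.5 for power, ρ = 0 for
family-wise error, binomial bounds at 20 replicates).
`scripts/acceptance.py` re-runs the same analyses (10 end-to-end
replicates per arm) and reports every measured number.

## Known limitations

* The scan assumes unrelated samples; the kinship-exclusion step of real
  cohorts is represented only as an input-list filter.
* Mixed-model association, imputation, LD-aware heritability and
  cross-trait genetic correlation are out of scope.
* Observed-scale h² for rare binary traits is far below liability-scale
  values; no liability transformation is applied.
* The exact HWE test is provided for completeness but the chi-square
  variant is the default, matching common GWAS tooling.
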