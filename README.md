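# restaq

Rest-activity rhythm quantification and genetic association.

`restaq` implements, end to end, the analysis chain used in large
accelerometer-cohort studies of circadian rest-activity disruption: it
turns raw or epoch-level wrist-accelerometer activity into the
non-parametric **relative amplitude** (RA) statistic, defines a
pathological **low-RA** case/control phenotype, runs covariate-adjusted
additive genetic association scans with standard imputed-variant filters,
and tests **polygenic risk scores** (PRS) for low RA against mood-related
outcomes at multiple discovery thresholds. A first-class synthetic-cohort
generator provides ground truth for every step, so the whole pipeline can
be validated by parameter recovery without access to restricted cohort
data.

It is written for biostatisticians and genetic epidemiologists who want a
small, testable, scriptable implementation of this phenotype-to-PRS
pipeline — for method checks, power exploration, and teaching.

## The statistics at the core

**Relative amplitude.** For each midnight-to-midnight day, M10 is the
mean activity over the most active continuous 10-h window and L5 the mean
over the least active continuous 5-h window (windows slide at 1-min
resolution by default, no wrap across midnight):

    RA = (M10 − L5) / (M10 + L5),   0 ≤ RA ≤ 1.

A participant's RA is the mean over their valid recorded days.
Participants are excluded when wear time is under 72 h, when some
hour-of-day is never covered, or when device flags (poor calibration,
unreliable size, daylight-saving overlap) are set. Interdaily stability,
intradaily variability and the 24-h cosinor amplitude are computed as
comparators.

**Low RA.** Cases are participants whose mean RA is more than two sample
standard deviations below the cohort mean: `RA < mean(RA) − 2·sd(RA)`.

**Association scan.** Per variant j, an additive model of phenotype on
alt-allele dosage g_j plus covariates (sex, age, genotyping array, eight
principal components): maximum-likelihood logistic regression for low RA,
OLS for continuous RA, after filtering variants with INFO < 0.8,
MAF < 0.01 or Hardy-Weinberg p < 1e-6. Scan diagnostics: genomic
inflation λ_GC = median(χ²)/0.45494 and an LD-score-style SNP-heritability
regression E[χ²_j] = 1 + (N·h²/M)·ℓ_j.

**PRS.** score_i = Σ_{j: p_j < t} β̂_j · dosage_ij at thresholds
t ∈ {5e-8, 5e-5, 0.01, 0.05, 0.1, 0.5}; scored samples are split into
quartiles (tertiles when only three distinct scores exist) and the top and
bottom groups contrasted in logistic/linear models adjusted for age, sex,
Townsend deprivation, array and eight PCs, with Benjamini-Hochberg FDR
across each outcome's threshold family.

## Worked example

```python
import numpy as np
import restaq

# a synthetic cohort whose true RA is analytically 2/3
params = restaq.ActigraphyParams(rest_level=20, active_level=100,
                                 noise_cv=0.3, missing_rate=0.02, seed=1)
series, truth = restaq.gen_actigraphy(params, 50)
kept, report = restaq.apply_exclusions(series)
metrics = restaq.cohort_metrics(kept, bin_min=5)
print(report.n_retained, "retained of", report.n_input)
print("mean RA %.4f (true %.4f)" % (metrics["mean_RA"].mean(), params.ra_true))

# a genetic cohort with h2 = 0.3 on the RA liability
g = restaq.gen_genotypes(4000, 300, (0.05, 0.5), seed=2)
cov = restaq.gen_covariates(4000, seed=3)
truth = restaq.make_truth(300, 150, h2=0.3, seed=4)
pheno = restaq.gen_phenotypes(g, truth, cov, seed=5)
labels, thr = restaq.low_ra_cases(pheno["mean_ra"])
qc_g, _ = restaq.variant_qc(g)
res = restaq.logistic_scan(qc_g, labels,
                           cov[["sex", "age", "array"] +
                               [f"PC{i}" for i in range(1, 9)]])
print(res.summary())
```

Output from this exact script:

```
48 retained of 50
mean RA 0.6683 (true 0.6667)
Additive logistic association scan
  samples: 4000    variants tested: 300
  converged fits: 300
  lambda_GC: 1.5115
  h2_SNP (constant-LD): 0.0384 (se 0.0101)
  genome-wide significant (p < 5e-08): 0
```

Two participants fell to the daylight-saving/device flags and the noisy
square-wave cohort recovers the analytic RA of 2/3 to ~2e-3. The scan's
λ_GC is well above 1 because half of these 300 variants truly affect the
liability — genuine polygenic signal inflates the median χ² — while the
rare low-RA phenotype (~2.3% cases) at n = 4000 yields no genome-wide
hits, and the observed-scale heritability estimate of a 2.3%-prevalence
binary trait is, as expected, far below the liability-scale h² of 0.3.
(Permuting the phenotype drives λ_GC back to ≈1; the test suite checks
exactly that calibration.)

The same flow is available from the shell:

```bash
restaq run --config demo.yaml --seed 7     # synth → qc → metrics → phenotype → gwas → prs
restaq qc --activity activity.csv --out qc.tsv
restaq gwas --genotypes g.tsv --pheno-table phenotype.tsv --out sumstats.tsv
restaq prs --sumstats sumstats.tsv --genotypes target.tsv \
           --pheno-table phenotype.tsv --out prs.tsv
```

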