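# Methods

## The design

`duoscore` implements a mother–offspring Mendelian-randomization analysis of
glycaemic exposure and childhood IQ. Genetic variants robustly associated with
fasting glucose and type 2 diabetes (T2D) are combined into weighted genetic
risk scores; the scores serve as instruments for glucose exposure. Because a
child inherits exactly one allele per locus from its mother, maternal and
offspring scores correlate at about 0.5, and a regression of child IQ on the
*maternal* score that adjusts for the *child's own* score isolates the
intrauterine (maternal-environment) pathway from directly inherited genetic
effects. The package provides the variant panel, score construction, genotype
QC, all the regression contrasts, and a seeded synthetic duo-cohort generator
so that the full pipeline is testable without access to individual-level
cohort data.

## The variant panel

The packaged catalogue (`duoscore/data/variant_catalog.tsv`) holds 38 SNPs
typed in children, 35 of which were also typed in mothers (the three *ADIPOQ*
SNPs are child-only). Each record carries major/minor alleles, cohort and CEU
reference minor-allele frequencies, the trait-raising (risk) allele
orientation, and per-allele literature weights. Two panel SNPs are LD proxies
that carry their index variant's weight unchanged: *GCK* rs1799884 for
rs4607517 (r² = 1.0) and *ADCY5* rs2877716 for rs11708067 (r² = 0.8). The
*IGF2BP2* SNP is stored under its canonical id rs4402960 with the variant
spelling rs4402690 kept as an alias. Reference-panel frequencies are stored as
printed and may exceed 0.5 where the minor allele differs between populations;
they are annotations only and enter no computation.

## Genetic risk scores

A score is

    score = ( Σ_i w_i · g_i / W ) · K

with `g_i` the risk-allele count (0/1/2) at SNP i, `w_i` its per-allele
literature effect, `W` the denominator constant and `K` the SNP count, so
complete-data scores live in `[0, 2K]` "weighted allele" units. The
fasting-glucose score (FGGRS) has 16 terms with `W = 0.474` (exactly the sum
of its weights). The T2D score (T2DGRS) has 22 terms with the published
denominator `W = 2.86`, although its printed weights sum to 2.89; both the
published constant (the default) and the self-consistent sum
(`consistent_denominator=True`) are supported, and every build audit reports
the actual weight sum next to the denominator in use.

Under Hardy-Weinberg equilibrium with independent SNPs the score moments are
closed-form: `mean = (K/W) Σ w_i 2p_i` and
`var = (K/W)² Σ w_i² 2p_i(1−p_i)`, with `p_i` the risk-allele frequency
(the MAF when the minor allele is the risk allele, `1 − MAF` otherwise).
Evaluated at the catalogued children's frequencies this gives an FGGRS mean of
17.12 and a T2DGRS mean of 22.64 — matching the observed cohort means (17.1
and 22.6) reported for these scores, which is a strong end-to-end check on the
orientation logic and the panel transcription.

Missing genotypes are handled by an explicit, selectable policy:
`complete_case` (any missing term makes the score missing), `zero_fill`
(missing terms contribute nothing; biases scores toward 0 by a factor of the
completeness rate, a conservative toward-the-null default), and `renormalize`
(per-individual denominator equal to the observed weight). All three agree
exactly on individuals with no missing terms. `zero_fill` is the default.

## Quality control

* **Allele frequencies** are counted directly, with the minor allele
  re-identified if the computed frequency exceeds 0.5.
* **Hardy-Weinberg** testing is the 1-df goodness-of-fit chi-square against
  expected counts from the estimated allele frequency, flagged at the
  reporting threshold p ≤ 0.02. Monomorphic SNPs return p = 1 with a
  degeneracy note rather than failing the pipeline. An exact test is
  deliberately out of scope (the chi-square matches the era-standard tool).
* **Bonferroni** thresholds return both the exact `α/n` and a display value
  rounded to one significant figure (0.05/38 → 0.0013 → 0.001).
* **Principal components** use the standard genotype-PCA construction:
  per-marker mean imputation of missing calls, centring at the mean dosage,
  scaling by √(p(1−p)), thin SVD. Sign indeterminacy is resolved by making
  each component's largest-magnitude loading positive, so results are exactly
  reproducible. Outlier-removal iterations of specialised ancestry tools are
  not reimplemented.

## The synthetic duo cohort

The generator emulates the statistical structure the analysis relies on, not
any particular family's data:

* **Founders** (mothers) are drawn per SNP in HWE at the catalogued MAFs.
  With `n_subpops > 1`, subpopulation frequencies are the panel frequency
  shifted by ±`maf_divergence` (clipped to [0.01, 0.5]), producing a Wahlund
  heterozygote deficit in the pooled sample and a recoverable ancestry axis.
* **Children** receive one maternal allele sampled uniformly from the
  mother's two, plus one paternal allele drawn from the population
  (Bernoulli at the subpopulation frequency). Fathers are not represented as
  individuals. This yields exact Mendelian consistency and the additive
  parent–offspring genotype correlation of 0.5.
* **LD proxies** are built with a haplotype copy scheme for equal-frequency
  pairs: each proxy allele copies the index allele with probability √r², else
  is an independent draw, so the realised allelic r² equals the target.
* **Phenotypes** follow linear models on scores centred at their analytic HWE
  means: fasting glucose (default intercept 4.95 mmol/l, slope 0.02 mmol/l
  per weighted allele of the child FGGRS, residual SD 0.39), HbA1c (4.91 %,
  0.02 %, SD 0.31) and IQ (mean 104.4, SD 16.4, with separate maternal and
  offspring per-weighted-allele effects on a selectable score, default the
  T2DGRS, both 0 by default). The defaults encode the published cohort
  summary statistics and instrument-validation effects; IQ score effects and
  confounder effects are null by default and are opt-in scenario knobs,
  because the corresponding published contrasts are observational rather than
  generative ground truth.
* **Maternal diabetes/glycosuria** is Bernoulli with a logistic dependence on
  the centred maternal T2DGRS; the intercept is solved numerically so the
  realised mean risk equals the configured prevalence (default 0.05 — the
  source cohort does not print one) even when the score slope is non-zero.
  The affected group is split 10/35/55 % across pre-existing diabetes,
  gestational diabetes and glycosuria; categories are mutually exclusive with
  precedence pre-existing > gestational > glycosuria.
* **Missingness** is completely at random at a per-call rate (default 0 —
  recovery scenarios are cleanest with complete data; set it explicitly to
  exercise the score missingness policies and inclusion filters).
* **Confounders** (education, social class, parity, breastfeeding, smoking,
  alcohol before/during pregnancy, iron supplementation, gestational age,
  birthweight, maternal age, interpregnancy interval, infection, child age
  and sex — fifteen covariables in all) are drawn from distributions chosen
  to look like a European birth cohort; none affects any outcome unless a
  scenario switches an effect on.

Everything is generated from a single seeded `numpy` generator in a fixed
order: the same config and seed reproduce the cohort byte for byte.

What the generator does *not* emulate: realistic LD beyond the explicit proxy
pairs, assortative mating, genotyping batch effects, informative missingness,
and real confounder–outcome correlation structure. Passing recovery tests
therefore demonstrate that the estimators are correct under the stated model,
not that the published cohort estimates are reproduced — individual-level
data for those are not public, and the pipeline makes no attempt to imitate
them.

## Statistical contrasts

All regressions are ordinary least squares with conventional standard errors,
listwise deletion, and normal-approximation CIs (`beta ± 1.96·se`); each
result records the n actually used and the covariate list. Single-SNP scans
use the additive minor-allele-count coding (major homozygote baseline), skip
monomorphic SNPs with a logged reason, and attach the Bonferroni display
threshold. The confounder scan tests every exposure–covariable pair, choosing
a Pearson chi-square (uncorrected) for categorical–categorical pairs and an
OLS F-test otherwise, and reports the observed nominal-association count next
to the chance expectation `round_half_away_from_zero(α·n_tests)` — the
rounding rule that maps 570 tests to 29 and 525 to 26 at α = 0.05.
Classification rules: WHO diabetes at fasting glucose ≥ 7.0 mmol/l or HbA1c
≥ 6.5 % (missing measurements never qualify; both missing gives a missing
classification); glycosuria at plasma glucose ≥ 13.9 mmol/l (or 250 mg/dl,
compared in its own unit) on at least two occasions; glucose unit conversion
divides by 18.016 mg/dl per mmol/l.

The study object runs the stages in order — inclusion filters with a
participant-flow ledger, HWE tables and frequency comparison, score
construction and summaries, instrument validation (score vs fasting
glucose/HbA1c, unadjusted and PC-adjusted), offspring exposures vs IQ,
maternal scores vs offspring IQ (unadjusted and offspring-score+PC adjusted),
the maternal diabetes/glycosuria contrast with its full covariate preset
(child age and sex, maternal age, birthweight, gestational age,
breastfeeding), and the confounder scan. PC adjustment defaults to the top 10
components and is reduced with a warning when the background panel cannot
support 10. The report is emitted as plain-text tables and as JSON validated
against a shipped structural schema.

## Numerical and design choices

* Scores are kept at full precision; only reports round.
* Rank deficiency is detected before fitting (QR diagnostics) and reported
  with the collinear column names instead of silently pseudo-inverting.
* The diabetes-model intercept is solved by bisection on the realised mean
  risk over the simulated scores, which is exact for the cohort at hand.
* Monte-Carlo problem sizes in the test-suite recovery checks use the
  published sample sizes (573 and 1037 for instrument validation, 1102 duos
  for the maternal contrast, 6272 for the IQ distribution) with 100–200
  seeded replicates, enough for the 2-MC-SE recovery bands and coverage
  checks while keeping the suite quick.
* The replicate harness reports mean estimate, empirical SE, mean model SE,
  95 % CI coverage and rejection rate per contrast, so type-I error and power
  are inspectable under any scenario.

## Known limitations

* No formal instrumental-variable (ratio/2SLS) estimator is provided: the
  analysis reports score–outcome regressions only, as the design under study
  does.
* The chi-square HWE test is asymptotic; at very small counts the exhaustive
  oracle agreement still holds by construction, but p-values are not exact
  probabilities.
* The LD-proxy scheme assumes equal allele frequencies for the pair; it
  matches the target r² but is not a general two-locus haplotype model.
* Logistic/Cox outcome models, kinship, imputation and genome-wide scans are
  out of scope.
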