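# Methods

`cardioscreen` implements a hypothesis-free screening pipeline for
associations between parental health-claims codes and cardiac malformations
in live-born infants, together with a synthetic claims-cohort generator that
makes every stage testable without access to proprietary insurance data.
This note documents the models, the defaults and why they hold, the numerical
choices, and what the synthetic experiments do and do not establish.

## Synthetic cohort model

Real claims cohorts are governed by latent clinical states: a woman with
diabetes accumulates diabetes diagnoses, insulin dispensings, and sequela
codes, all reflecting one underlying condition.  The generator formalizes
this: each pregnancy carries each configured latent factor independently with
its `carrier_prevalence`; a carrier emits each of the factor's codes
(diagnosis sections or therapeutic detail codes) independently with the
code's emission probability.  Emitted events receive integer day offsets
relative to the last menstrual period (LMP = day 0); about 15% of events are
placed outside the relevant exposure window as distractors so that window
logic is exercised.  Noise codes are outcome-independent with heavy-tailed
(power-law) marginal frequencies, so "most common codes" selection is
non-trivial.

The outcome is modelled per fetus:

    logit P(affected) = b0 + sum_f carrier_f * log_or_f + slope * (age - 31)

and counted at the pregnancy level (a pregnancy is a case if any fetus is
affected).  Twin pregnancies therefore mechanically carry up to twice the
risk even under equal fetal risk; a factor may shift the twin probability
(`multiple_gestation_log_or`) without any direct outcome effect, which is how
the fertility-treatment artefact and its attenuation under the singleton
restriction are reproduced.  The intercepts of both the outcome and the
twin-probability models are calibrated numerically (Brent root-finding on the
realized covariates) so that the marginal rates hit their targets exactly in
expectation.

Default study conditions: pregnancy-level outcome rate 1.3%, father linkage
70.4%, multiple gestation 3.4%, maternal age discretized normal with median
31 and IQR 28-34 (sd = IQR/1.349) truncated to 12-55, eligibility-violation
rate 2% per rule, infant death rate 0.2%.  The default planted scenario
carries four maternal factors: diabetes (prevalence 1.4%, outcome OR 2.2,
emitting a diagnosis section, an insulin code and a retinopathy code),
chronic hypertension (2.8%, OR 1.52), supervision of high-risk pregnancy
(25%, OR 1.29), and a fertility-treatment proxy (2%, OR 1.0 direct, twin
log-odds shift +2.5).  Prevalences and effect sizes follow well-replicated
claims-cohort findings for these conditions.

What the generator does **not** emulate: real ICD code semantics, billing
and coding-intensity behaviour, calendar-time ICD-9/ICD-10 transition
dynamics (events carry a vocabulary flag only), correlated maternal/paternal
exposures (independent given family linkage), and within-twin outcome
correlation.  Passing tests therefore demonstrate the statistical machinery
under a faithful but idealized data-generating process, not performance on
real claims data.

## Cohort construction

Eligibility (applied in order; the final set is order-invariant, the
exclusion tally is not): (1) at least one linked infant; (2) continuous
maternal enrollment over [LMP-180, end+30]; (3) maternal medication benefits
over [LMP-180, end]; (4) every linked infant enrolled through end+90, or to
death if earlier; (5) maternal age 12-55.  Enrollment spans touching within
one day are merged before coverage checks.  Fathers are the adult males
sharing the mother's family key in the delivery year with rx-benefit
coverage over [LMP-180, LMP]; ties resolve to the oldest, then the smallest
person id (deterministic, logged).

All exposure windows are closed on both endpoints.  The default windows are:
maternal diagnoses [-180, +90], maternal medications [0, +90] (first
trimester), paternal diagnoses [-180, 0], paternal medications [-90, 0]
(spermatogenesis); the "acute" preset narrows diagnosis windows to the
medication windows.  Diagnosis codes are reduced to ICD-9 3-digit sections:
directly by prefix for ICD-9, through a General Equivalence Mapping crosswalk
for ICD-10 (first-listed target per source; a source whose targets disagree
at the section level is tallied as ambiguous; unmappable codes are dropped
and counted).  Indicators are `count >= threshold` with threshold 1 (2 in
the corresponding sensitivity analysis).  Per panel the 500 most common
codes are retained, ranked by pregnancy-level prevalence (the natural unit
given indicator covariates) with lexicographic tie-break.

## Screening

Each code is screened in its own logistic model with a restricted cubic
spline in maternal age (Harrell truncated-power basis; 4 knots at the
5/35/65/95th age percentiles; dimension = knots - 1; linear tails).  P-values
are likelihood-ratio tests with 1 df.  A code with any empty cell in its
exposure-outcome 2x2 margin is reported `non-estimable` with p = 1 rather
than dropped, keeping the BH family size honest.  Selection uses
Benjamini-Hochberg step-up at 1/5/10% FDR; maternal and paternal runs form
separate BH families, each pooling that run's diagnosis and medication codes.

The inner fitter is an undamped Newton solver warm-started from the reduced
(age-only) fit, with a damped likelihood-monotone fallback; coefficient
drift beyond |beta| > 500 is treated as degeneracy.  Equivalence with a
conventional GLM fit (statsmodels) is asserted in the test suite to 1e-6.

Winner's curse: effect estimates that survive selection are biased away from
the null.  The correction implemented is a conditional bootstrap: for each of
B resamples of pregnancies (with replacement) the entire screen including BH
selection is rerun; for an originally selected code, the bias estimate is
the mean over resamples *in which it was re-selected* of (bootstrap log-OR -
full-data log-OR), and the corrected estimate subtracts this bias.  B >= 50
is enforced; codes never re-selected carry a missing correction and a flag.
This is one standard realization of bootstrap selection-bias correction, and
corrected estimates are labelled with the scheme.

Manhattan output is -log10(p) signed by the log-OR, capped at 20 for display
(underlying tables keep the raw p).  The maternal age-risk curve is the
predicted probability from an age-only spline fit, with observed risks per
2-year bin reported only for bins holding more than 100 pregnancies.

Paternal runs adjust for maternal age, the covariate the screening design
names; whether paternal age should replace or accompany it is left to the
caller (the design matrix accepts any age vector).

## Latent semantic characterization

Counts over all mapped codes (not only the top-500) are transformed
x -> log(1+x) — the +1 offset is forced by zero counts — and decomposed by
truncated SVD without centering (classical latent-semantic-analysis
convention; centering is available but off by default).  Code vectors are the
right singular vectors scaled by their singular values; the retained rank
defaults to 500, capped at the matrix rank (desk-scale runs have far fewer
codes).  Exact dense SVD is used when the smaller matrix dimension is <= 800,
a seeded randomized solver otherwise.  Similarity is cosine; zero-norm codes
are flagged and excluded.  Grouping uses average-linkage agglomerative
clustering on the angular distance arccos(cos)/pi in [0, 1]; single and
complete linkage are available.  The default cut 0.35 was chosen from the
geometry of the planted-factor scenario (within-factor angular distances
concentrate below ~0.25, between-factor distances near 0.5) before being
fixed; clustering quality is reported as adjusted Rand index against the
planted factor labels.

## Subgroup discovery

Apriori-style mining runs on the balanced maternal binary data: all cases
are kept and non-cases are down-sampled without replacement to a 50/50 mix.
Rule support is the fraction of the balanced data with the antecedent AND
the outcome (anti-monotone in the antecedent, so counting is restricted to
case rows during the level-wise generation); confidence is the fraction of
antecedent holders with the outcome.  Defaults: minimum support 0.1%,
minimum confidence 55%, maximum antecedent length 10; maternal age enters
dichotomized at 35.  The subgroup-discovery post-processing is deliberately
modular because the canonical variant is loosely specified in the
literature this follows: (a) outcome-consequent filtering, (b) an optional
closed-set reduction dropping antecedents that have a proper superset with
identical case support, and (c) ranking by the rule's balanced-data 2x2
chi-square statistic (configurable to confidence ranking).

Family-wise error is controlled by Westfall-Young maxT permutation: outcome
labels are permuted and, in the strict default mode, the rule family is
re-mined per permutation under identical thresholds; each observed statistic
is compared with the permutation distribution of the family maximum, and the
adjusted p is the fraction of permutations whose maximum reaches it.  A
fixed-family mode that only re-scores the observed antecedents is offered
and labelled approximate.  Selected subgroups are then reported on the full
(un-downsampled) data: prevalence, and risk ratio with the Katz log-normal
95% CI; a zero cell triggers the 0.5 continuity correction on all four
cells (flagged), and an empty in- or out-group leaves the RR undefined
(flagged).

## Pipeline and reproducibility

`run_all` executes simulate -> eligibility/linkage -> outcomes -> panels ->
screening (+ winner's curse) -> age-risk curve -> latent space/clustering ->
subgroup discovery, writing plain delimited text with headers throughout.
Per-stage seeds derive from the master seed as the first 4 bytes of
SHA-256("{master}:{stage}") modulo 2^31, so stages can be rerun
independently; two runs with one seed are byte-identical (asserted in the
test suite), and the manifest records the config hash (over analysis
parameters, not file locations), package version, per-stage seeds and stage
counts.  Secondary (subtype) outcomes are screened separately; a subtype
with fewer than 10 cases cannot support the spline adjustment and yields an
empty selection with a low-power warning instead.

## Problem sizes in tests and the acceptance script

Simulation-based checks run at desk scale, chosen so each property is
measured with adequate Monte-Carlo precision: FDR control uses 200 global-
null screens of 200 codes at n = 20,000; winner's-curse bias reduction uses
10 replicates of 100 codes (15 non-null at OR 1.5) at n = 10,000 with B = 60;
planted-signal recovery uses 20 generator runs at n = 200,000 (the empirical
selection fraction reported is the power at that scale; at larger cohort
sizes it is higher still); Westfall-Young control uses 200 null minings with
150 permutations each.  The acceptance script runs the default scenario at
n = 300,000 with the top 100 codes per panel and B = 60 bootstrap
replicates.  At these scales the headline odds-ratio estimate for the
planted diabetes factor carries a standard error near 0.11 on the log scale,
so individual runs scatter around the planted 2.2 accordingly.

## Known limitations

* Confounding control is restricted to maternal age, matching the screening
  design this implements; identified associations are signals, not causal
  estimates.
* The Apriori-SD post-processing is an interpretation of a loosely specified
  procedure; every step is independently switchable and documented above.
* The strict Westfall-Young mode re-mines per permutation and is the
  computational bottleneck at scale; the fixed-family approximation trades
  exactness of the null family for speed.
* The generator's independence assumptions (factors, parental exposures,
  fetal outcomes given the linear predictor) understate the dependence
  structure of real claims data.
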