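# cardioscreen

Hypothesis-free screening of parental insurance-claims codes for
associations with cardiac malformations in live-born infants.

Cardiac malformations are among the most common congenital malformations,
and their etiology is largely unexplained outside known genetic causes.
Rather than testing pre-specified exposures one at a time, this package
screens *every* sufficiently common maternal and paternal diagnosis and
medication code in a pregnancy cohort against the outcome, controls the
multiplicity honestly, and then characterizes what was found.  It is aimed
at pharmacoepidemiologists and perinatal researchers working with claims
data (or anyone who wants a fully testable, synthetic-data-driven reference
implementation of this class of screening design).

## What it computes

For a cohort of pregnancies linked to live-born infants (relational tables
of persons, enrollment spans, coded diagnosis/dispensing events, pregnancy
episodes and infant links):

1. **Cohort construction** — eligibility (continuous maternal enrollment
   over [LMP−180, end+30], medication benefits, ≥90-day infant follow-up
   with an infant-death exception, maternal age 12–55), father linkage via
   family key with rx-benefit coverage over [LMP−180, LMP], ICD-10→ICD-9
   section mapping through a GEM crosswalk, and sparse pregnancy × code
   indicator/count panels over LMP-anchored exposure windows, keeping the
   500 most common codes per panel.
2. **Screening** — for each code *j*, a logistic model

       logit P(Y=1) = β₀ + β₁·xⱼ + f(age),   f = restricted cubic spline,

   with a 1-df likelihood-ratio p-value; Benjamini–Hochberg selection at
   1/5/10% FDR; a conditional-bootstrap winner's-curse correction of
   selected odds ratios; and signed-Manhattan output, −log₁₀(p)·sign(β̂₁).
3. **Characterization** — truncated SVD of the log(1+count) matrix (latent
   semantic analysis); cosine similarity between selected codes' vectors;
   average-linkage clustering on angular distance arccos(cos)/π; and the
   maternal age–risk curve from an age-only spline fit.
4. **Subgroup discovery** — Apriori rule mining on class-balanced data
   (min support 0.1%, min confidence 55%, antecedent length ≤ 10, age
   dichotomized at 35), Westfall–Young maxT permutation control of the
   family-wise error rate at 5%, and full-data prevalence and risk ratios
   (Katz CI) for the discovered subgroups.

Because real claims cohorts are proprietary, the package ships a
first-class synthetic generator: latent clinical factors emit correlated
diagnosis and medication codes, outcomes follow a per-fetus logistic model
with planted odds ratios (counted at the pregnancy level, reproducing the
twin-counting artefact), fathers link at a configurable rate, and a
configurable fraction of pregnancies violates each eligibility rule.  All
planted truth is returned alongside the cohort, so parameter recovery is
testable end to end.  See `docs/methods.md` for models, defaults and
limitations.

## Worked example

```python
import cardioscreen as cs
from cardioscreen import cohort as cb, screening as scr
from cardioscreen.pipeline import maternal_ages

cfg = cs.default_config(n_pregnancies=200_000, seed=1)   # planted scenario
cohort, truth = cs.generate_cohort(cfg)

eligible, tally = cs.apply_eligibility(cohort)
ids = sorted(eligible)
gem = cb.gem_from_frame(cohort.gem)
panel = cs.select_top_codes(
    cs.derive_panel(cohort, ids, cb.WindowSpec("maternal-dx", -180, 90),
                    gem=gem), k=500)
y = cs.flag_outcomes(cohort, ids, cs.default_code_lists())["primary"]
tab = scr.screen([panel], y, maternal_ages(cohort, ids))
print(tab.loc[tab.selected_fdr05,
              ["code", "n_exposed", "odds_ratio", "p", "p_adj"]])
```

Output (seed 1):

```
   code  n_exposed  odds_ratio         p     p_adj
50  250       2347    1.825940  0.000088  0.002421
52  401       4162    1.751849  0.000002  0.000106
```

Two planted maternal factors are selected from among ~100 codes: the
diabetes section code (true OR 2.2, estimated 1.83 this draw) and essential
hypertension (true 1.52, estimated 1.75); the weaker high-risk-supervision
signal (true OR 1.29, diluted by its 90% emission probability) misses the
5% FDR cut-off at this cohort size.  No noise code is selected.

The same analysis runs from the shell:

```bash
cardioscreen simulate --n 50000 --seed 1 --out cohort_dir
cardioscreen run-all --cohort-dir cohort_dir --out run --seed 1
cardioscreen report --out run
```

`run-all` writes plain-TSV outputs (exclusion tally, screening tables with
corrected ORs, Manhattan data, singular values, similarity matrix, code
groups, subgroup rules, age-risk curve) plus a `manifest.json`; reruns with
the same seed are byte-identical.

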