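# Methods

## The problem

In the UK, patients with new breast symptoms reach a specialist breast
clinic through a GP referral, either urgently (the two-week-wait
suspected-cancer pathway) or routinely (about six weeks). GPs refer
conservatively — in symptomatic breast cohorts nearly every referral
rides the urgent pathway — so a large fraction of clinic slots go to
patients who could have been seen routinely or managed in the
community. `breast_triage` implements a deterministic, explainable
triage rule engine for this setting, the accuracy machinery to score
any decision source against a breast surgeon's recommendation, and a
synthetic cohort simulator so the whole pipeline can be exercised and
tested without patient data.

## The rule engine

A presentation is a `PatientRecord`: integer age (16–110), sex, a
`SymptomProfile` of flags (breast/axillary lump and whether it is
explained by a known benign cause; pain and whether it is bilateral
and cyclical; nipple discharge `none`/`clear`/`bloody` with a
unilateral flag; nipple retraction; other nipple change of concern;
suspicious skin change; symptom duration in weeks), family history
(`none`/`moderate`/`strong`) and a prior-condition flag. Dependent
flags are constrained (laterality requires a discharge, and so on) and
a record must carry at least one presenting complaint.

The engine encodes the 2015 NICE "suspected cancer: recognition and
referral" breast criteria as rules R1–R9 over four outcomes, ordered
`URGENT_SPECIALIST > ROUTINE_SPECIALIST > NURSE_SPECIALIST >
COMMUNITY_GP`:

| rule | condition | outcome |
|------|-----------|---------|
| R1 | age ≥ 30, unexplained breast lump | urgent |
| R2 | age ≥ 50, unilateral discharge / retraction / other nipple change | urgent |
| R2b | bloody discharge at any age (config toggle, default on) | urgent |
| R3 | suspicious skin change at any age | urgent |
| R4 | age ≥ 30, unexplained axillary lump | urgent |
| R5 | age < 30, unexplained breast lump | routine |
| R6 | age < 50, clear unilateral discharge / retraction / other nipple change | routine |
| R7 | moderate/strong family history, no symptom rule fired | nurse |
| R8 | pain only, no lump or skin/nipple red flag | community |
| R9 | explained lump, no other red flag | community |

Design choices where the guideline text leaves latitude:

* **"Consider referral" is encoded as a firm referral** at the stated
  urgency. A rule-based triage front door should fail toward caution;
  the same choice makes over-triage the engine's only error mode.
* **Age thresholds are inclusive** (≥ 30, ≥ 50), age in integer years
  at referral.
* **Laterality** is representable only for discharge in the symptom
  schema, so the unilateral qualifier in R2/R6 gates the discharge arm
  only; retraction and other nipple change count regardless.
* **Nurse referral** has no published criterion; family-history review
  is the natural nurse-led pathway, so R7 routes a
  family-history-dominant presentation there.
* **Fallback**: a validated record matching no rule gets
  `ROUTINE_SPECIALIST` with a fallback marker in the trace — an
  unmatched presentation is never silently dismissed. The fallback
  outcome is configurable.
* **Tie-break**: the final outcome is the maximum urgency among fired
  rules; among equals the lowest rule id is reported as primary.
* **Males** are triaged with the same table; no male-specific logic is
  defined. `duration_weeks` is carried but used by no default rule.

The engine is a pure function of (record, config). Every decision
comes with a `RuleTrace` listing each enabled rule and whether it
fired.

## Accuracy evaluation

`build_confusion` cross-tabulates any decision source against the
surgeon gold standard over the four outcomes. `overall_accuracy` is
trace/n; per-class sensitivity/specificity/PPV/NPV are one-vs-rest;
the urgent-vs-not pair is the one-vs-rest pair for
`URGENT_SPECIALIST`. Zero-denominator metrics are reported as `None`
(undefined), never 0. The referral audit operationalizes an
"appropriate" referral as gold ≠ community (its complement is the
community-manageable share) and reports the fraction of GP-urgent
referrals that were gold-urgent.

Group comparisons: Pearson chi-square on the 2×2 table without Yates
correction (df = 1; correction available as an option) — the simplest
reading of "chi-square" — and Welch's unequal-variance two-sided
t-test as the robust default, with the pooled-variance test as an
option. Zero-margin tables raise a degenerate-table error rather than
returning a statistic.

## Scenarios

Four built-in vignettes mirror the questionnaire phase: (1) an
unexplained hard lump at 52 → urgent; (2) clear unilateral discharge
at 40 → routine; (3) bilateral cyclical pain at 22 and (4) an
explained lump at 24 → no specialist review. Ages were chosen so each
record lands in its stated outcome band under the rule table; the
engine's classification of all four against the answer keys is the
package's worked-example anchor. Responder scoring treats lay judgment
as a diagnostic test (sensitivity on the two review-needed scenarios,
specificity on the two benign ones); urgency accuracy is scored
conditional on a correct needs-review answer, and the per-scenario
report exposes both the all-responder and the said-review denominators
because published summaries of this design are ambiguous about which
was used. `simulate_responses` defaults to the observed lay
performance (0.981 correct on review-needed, 0.184 on benign); its
third probability (correct urgency given a correct review answer) has
no single observed value — 1.0 for the cancer vignette, 0.3 for the
routine one — so the default is the 0.65 midpoint.

## The cohort simulator

`generate_cohort` emulates the two study cohorts. Presets (all
overridable):

| parameter | phase1 | phase2 |
|---|---|---|
| presentation mix | lump .476, pain .269, nipple change .079, other .176 | lump .791, remainder split equally over pain / nipple change / discharge |
| age (mean ± SD, years) | 49.1 ± 17.7 | 43.9 ± 13.3 |
| male fraction | 0 | 2/86 |
| GP urgent probability | 0.948 | 1.0 |

The phase-2 mix beyond the lump share and the phase-1 residual
category are not published; the remainder is split equally, and the
residual "other" maps to a suspicious skin change (a distinct,
recoverable presenting feature). Category → symptom-flag mapping (all
probabilities exposed as parameters): lumps are explained with
probability 0.2 in under-30 patients (creating community-manageable
young-benign cases); pain is bilateral/cyclical with probability 0.7;
a nipple change is retraction vs other change 50/50; discharge is
clear vs bloody 0.9/0.1 and unilateral with probability 0.8. These
values populate all four outcome classes and are otherwise
uncalibrated.

Age is a normal draw truncated to [16, 95] and rounded to integer
years. Truncation and rounding shift the phase-2 sample mean about
+0.55 years above the nominal 43.9 (the lower bound sits 2.1 SD below
the mean); tests therefore compare sample moments to the analytic
truncated-normal values, and the reported mean age of a large phase-2
cohort is ≈ 44.4–44.6.

Latent malignancy is assigned only to lump presentations that meet an
urgent criterion, with probability `p_malignant_given_lump` (default
0.15, a typical cancer yield among urgent-referred symptomatic lump
presentations). The simulated surgeon starts from the engine's
criteria-based outcome: malignant ⇒ gold urgent; benign and
criteria-urgent ⇒ downgraded to routine or community (equal split)
with probability `p_surgeon_override` (default 0.3); the surgeon never
upgrades. Two structural consequences, both tested:

* **Gold containment** — gold urgency ≤ engine urgency for every
  patient, so the engine's urgent-vs-not sensitivity against gold is
  exactly 1.0 on every generated cohort, and
* **over-triage-only errors** — every engine/gold disagreement has the
  engine more urgent.

The default `p_surgeon_override` produces over-triage-dominated
inaccuracy in the observed direction; it is deliberately not
calibrated to reproduce any particular headline accuracy figure.

Randomness: one root `SeedSequence`, one spawned substream per patient
in fixed order, so cohorts are reproducible and growing `n` preserves
the prefix. GP behaviour is Bernoulli(`p_gp_urgent`), independent of
gold.

### What the simulator does and does not emulate

It reproduces the marginal presentation mix, age distribution, sex
balance and GP referral behaviour, and the direction of the
software-vs-surgeon disagreement. It does not model symptom
co-occurrence beyond the category mapping, age-dependent malignancy
risk, surgeon inter-rater variability, waiting times (the clinic-delay
descriptors are carried as preset metadata only), or questionnaire
non-response. Passing tests therefore show the pipeline is correct and
its structural claims hold under the stated generative model — not
that the engine would achieve any particular accuracy on real
patients.

## Numerical and testing choices

Problem sizes: the oracle-equivalence grid is every consistent
symptom-flag combination × ten ages spanning the thresholds × sex
(≈17k records); calibration and parameter-recovery checks use cohorts
of n = 10,000 with 3-standard-error bands; the structural sensitivity
check uses n = 500. The test oracle re-derives each criterion as plain
boolean expressions, independent of the engine's rule table.
`scripts/acceptance.py` recomputes the headline quantities from
scratch at the same sizes, with every random stream derived from its
`--seed` argument.

## Known limitations

The exact questionnaire wording and the deployed software's private
rule set are not published; the rule table here is the public 2015
guideline reading plus the documented design choices, validated
against the four scenario anchors. Real-cohort headline accuracies
depend on an unavailable patient sample and are not reproduction
targets. The audit's "appropriateness" is a recommendation-level
judgment, not a biopsy-confirmed outcome.
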