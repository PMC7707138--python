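"""Synthetic cohort generator emulating the two study phases.

Each simulated patient bundles a symptom record, a latent condition
(malignant/benign), a surgeon gold-standard referral outcome and a GP
referral decision. The generative story:

1. A presenting category (lump, pain, nipple change, discharge, other)
   is drawn from the preset mix and mapped to symptom flags.
2. Age is a truncated normal on the preset bounds, rounded to integer
   years; sex is Bernoulli on the male fraction.
3. Latent malignancy arises only among lump presentations that meet an
   urgent referral criterion; this makes the surgeon's urgent calls a
   superset of nothing and, crucially, a subset of the rule engine's -
   the gold-containment property below.
4. The surgeon gold standard starts from the engine's criteria-based
   outcome ("NICE core"); a malignant patient is always gold-urgent; a
   benign patient meeting an urgent criterion is downgraded to routine
   or community (equal split) with probability ``p_surgeon_override``.
   The surgeon never upgrades beyond the criteria.
5. The GP refers urgently with probability ``p_gp_urgent``, independent
   of the gold standard (the observed GP behaviour: essentially every
   referral rode the fast-track pathway).

Gold containment means the engine's urgency is always >= the gold
urgency, so the engine's urgent-vs-not sensitivity against gold is
exactly 1 on every generated cohort, and every engine error is an
over-triage - the structural mechanism behind a rule-based triage tool
whose only failure mode is excess caution.

Randomness uses one root seed with an independent substream per patient
(spawned in fixed order), so growing ``n`` preserves the cohort prefix.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .core import (
    FamilyHistory,
    NippleDischarge,
    PatientRecord,
    Sex,
    SymptomProfile,
    TriageOutcome,
    triage,
    urgency_rank,
)
from .evaluation import GPUrgency

PRESENTATION_CATEGORIES = ("lump", "pain", "nipple_change", "discharge", "other")


class LatentCondition(str, enum.Enum):
    MALIGNANT = "malignant"
    BENIGN = "benign"


class CohortParams(BaseModel):
    """Generator configuration; presets are documented defaults, all
    overridable.

    ``phase2`` mirrors the self-referral cohort: lump share 0.791 with
    the remainder split equally among pain, nipple change and
    discharge; age 43.9 +/- 13.3; 2/86 male; every GP referral urgent.
    ``phase1`` mirrors the questionnaire cohort: lump 0.476, pain
    0.269, nipple change 0.079, residual "other" 0.176; age 49.1 +/-
    17.7; all female; GP urgent with probability 0.948. Clinic-delay
    descriptors (10.6 +/- 6.7 days to be seen) are carried as metadata
    only; no waiting-time events are simulated.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n: int
    seed: int
    presentation_mix: dict[str, float]
    age_mean: float
    age_sd: float
    age_bounds: tuple[int, int] = (16, 95)
    male_fraction: float = 0.0
    p_malignant_given_lump: float = 0.15
    p_surgeon_override: float = 0.3
    p_gp_urgent: float = 1.0
    phase_preset: str = "custom"
    # symptom-flag mapping knobs (see docs/methods.md)
    p_lump_explained_under30: float = 0.2
    p_pain_bilateral_cyclical: float = 0.7
    p_nipple_retraction: float = 0.5
    p_discharge_clear: float = 0.9
    p_discharge_unilateral: float = 0.8
    metadata: dict = {}

    @model_validator(mode="after")
    def _check(self) -> "CohortParams":
        if self.n < 0:
            raise ValueError("n must be >= 0")
        mix = self.presentation_mix
        unknown = set(mix) - set(PRESENTATION_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown presentation categories: {sorted(unknown)}")
        if any(p < 0 for p in mix.values()):
            raise ValueError("presentation_mix probabilities must be >= 0")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("presentation_mix must sum to 1 (tolerance 1e-9)")
        lo, hi = self.age_bounds
        if not (16 <= lo < hi <= 110):
            raise ValueError("age_bounds must satisfy 16 <= lo < hi <= 110")
        for name in (
            "male_fraction",
            "p_malignant_given_lump",
            "p_surgeon_override",
            "p_gp_urgent",
            "p_lump_explained_under30",
            "p_pain_bilateral_cyclical",
            "p_nipple_retraction",
            "p_discharge_clear",
            "p_discharge_unilateral",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        return self

    @classmethod
    def phase1(cls, n: int, seed: int, **overrides) -> "CohortParams":
        """Questionnaire-phase cohort preset."""
        defaults = dict(
            n=n,
            seed=seed,
            presentation_mix={
                "lump": 0.476,
                "pain": 0.269,
                "nipple_change": 0.079,
                "discharge": 0.0,
                "other": round(1.0 - 0.476 - 0.269 - 0.079, 12),
            },
            age_mean=49.1,
            age_sd=17.7,
            male_fraction=0.0,
            p_gp_urgent=0.948,
            phase_preset="phase1",
            metadata={"clinic_wait_days_mean": 10.6, "clinic_wait_days_sd": 6.7},
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def phase2(cls, n: int, seed: int, **overrides) -> "CohortParams":
        """Self-referral-phase cohort preset."""
        rest = (1.0 - 0.791) / 3.0
        defaults = dict(
            n=n,
            seed=seed,
            presentation_mix={
                "lump": 0.791,
                "pain": rest,
                "nipple_change": rest,
                "discharge": 1.0 - 0.791 - 2 * rest,
                "other": 0.0,
            },
            age_mean=43.9,
            age_sd=13.3,
            male_fraction=2.0 / 86.0,
            p_gp_urgent=1.0,
            phase_preset="phase2",
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class SimulatedPatient:
    record: PatientRecord
    latent_condition: LatentCondition
    gold: TriageOutcome
    gp_decision: GPUrgency
    presentation: str


@dataclass(frozen=True)
class CohortSummary:
    n: int
    age_mean: float
    age_sd: float
    sex_counts: dict[str, int]
    presentation_proportions: dict[str, float]
    gold_prevalence: dict[str, float]
    gp_urgent_fraction: float

    def to_dict(self) -> dict:
        return vars(self)


def _draw_age(rng: np.random.Generator, params: CohortParams) -> int:
    lo, hi = params.age_bounds
    while True:  # rejection sampling; bounds are wide so this is cheap
        age = int(round(rng.normal(params.age_mean, params.age_sd)))
        if lo <= age <= hi:
            return age


def _draw_symptoms(
    rng: np.random.Generator, category: str, age: int, params: CohortParams
) -> SymptomProfile:
    duration = round(float(rng.exponential(4.0)), 1)
    kw: dict = {"duration_weeks": duration}
    if category == "lump":
        kw["lump_breast"] = True
        if age < 30 and rng.random() < params.p_lump_explained_under30:
            kw["lump_explained"] = True
    elif category == "pain":
        kw["pain"] = True
        if rng.random() < params.p_pain_bilateral_cyclical:
            kw["pain_bilateral_cyclical"] = True
    elif category == "nipple_change":
        if rng.random() < params.p_nipple_retraction:
            kw["nipple_retraction"] = True
        else:
            kw["nipple_change_other"] = True
    elif category == "discharge":
        kw["nipple_discharge"] = (
            NippleDischarge.CLEAR
            if rng.random() < params.p_discharge_clear
            else NippleDischarge.BLOODY
        )
        if rng.random() < params.p_discharge_unilateral:
            kw["nipple_discharge_unilateral"] = True
    elif category == "other":
        # residual category: skin changes of concern and similar findings
        kw["skin_change_suspicious"] = True
    else:  # pragma: no cover - params validation prevents this
        raise ValueError(f"unknown category {category}")
    return SymptomProfile(**kw)


def nice_core_outcome(record: PatientRecord) -> TriageOutcome:
    """The criteria-based outcome the simulated surgeon starts from
    (the default rule engine's decision)."""
    return triage(record)[0]


def assign_gold(
    record: PatientRecord,
    latent: LatentCondition,
    params: CohortParams,
    rng: np.random.Generator,
) -> TriageOutcome:
    """Simulated surgeon recommendation for one patient.

    Malignant patients are always gold-urgent. A benign patient whose
    symptoms meet an urgent criterion is downgraded (to routine or
    community, equal split) with probability ``p_surgeon_override``.
    The surgeon never recommends more urgency than the criteria do.
    """
    core = nice_core_outcome(record)
    if latent == LatentCondition.MALIGNANT:
        return TriageOutcome.URGENT_SPECIALIST
    if core == TriageOutcome.URGENT_SPECIALIST and rng.random() < params.p_surgeon_override:
        return (
            TriageOutcome.ROUTINE_SPECIALIST
            if rng.random() < 0.5
            else TriageOutcome.COMMUNITY_GP
        )
    return core


def assign_gp(
    gold: TriageOutcome, params: CohortParams, rng: np.random.Generator
) -> GPUrgency:
    """GP referral urgency, independent of the gold standard."""
    return GPUrgency.URGENT if rng.random() < params.p_gp_urgent else GPUrgency.ROUTINE


def generate_cohort(params: CohortParams) -> list[SimulatedPatient]:
    """Generate ``params.n`` patients, reproducibly under the root seed."""
    categories = list(PRESENTATION_CATEGORIES)
    probs = np.array([params.presentation_mix.get(c, 0.0) for c in categories])
    probs = probs / probs.sum() if params.n else probs
    children = np.random.SeedSequence(params.seed).spawn(params.n)
    cohort: list[SimulatedPatient] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        category = categories[rng.choice(len(categories), p=probs)]
        age = _draw_age(rng, params)
        sex = Sex.MALE if rng.random() < params.male_fraction else Sex.FEMALE
        symptoms = _draw_symptoms(rng, category, age, params)
        record = PatientRecord(
            patient_id=f"sim-{i:06d}",
            age_years=age,
            sex=sex,
            symptoms=symptoms,
            family_history=FamilyHistory.NONE,
            prior_breast_condition=False,
        )
        core = nice_core_outcome(record)
        malignant = (
            category == "lump"
            and core == TriageOutcome.URGENT_SPECIALIST
            and rng.random() < params.p_malignant_given_lump
        )
        latent = LatentCondition.MALIGNANT if malignant else LatentCondition.BENIGN
        gold = assign_gold(record, latent, params, rng)
        gp = assign_gp(gold, params, rng)
        cohort.append(SimulatedPatient(record, latent, gold, gp, category))
    return cohort


def cohort_summary(cohort: list[SimulatedPatient]) -> CohortSummary:
    """Descriptive statistics of a generated cohort."""
    if not cohort:
        raise ValueError("empty cohort")
    ages = np.array([p.record.age_years for p in cohort], dtype=float)
    n = len(cohort)
    sex_counts = {s.value: 0 for s in Sex}
    for p in cohort:
        sex_counts[p.record.sex.value] += 1
    pres = {c: 0 for c in PRESENTATION_CATEGORIES}
    for p in cohort:
        pres[p.presentation] += 1
    gold = {o.value: 0 for o in TriageOutcome}
    for p in cohort:
        gold[p.gold.value] += 1
    return CohortSummary(
        n=n,
        age_mean=float(ages.mean()),
        age_sd=float(ages.std(ddof=1)) if n > 1 else 0.0,
        sex_counts=sex_counts,
        presentation_proportions={c: k / n for c, k in pres.items()},
        gold_prevalence={o: k / n for o, k in gold.items()},
        gp_urgent_fraction=sum(p.gp_decision == GPUrgency.URGENT for p in cohort) / n,
    )
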