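"""Shared fixtures and the independent brute-force triage oracle.

The oracle evaluates each referral criterion as a plain boolean
expression and returns the maximum-urgency outcome, with no code shared
with the engine's rule table, so engine/oracle agreement over the full
discretized patient grid is a meaningful check.
"""

import itertools

import pytest

from breast_triage.core import (
    PatientRecord,
    SymptomProfile,
    TriageOutcome,
    validate_record,
)
from breast_triage.cohort import CohortParams, generate_cohort


def make_record(age=45, sex="female", family_history="none", patient_id="p1",
                prior=False, **symptoms) -> PatientRecord:
    return validate_record(
        dict(
            patient_id=patient_id,
            age_years=age,
            sex=sex,
            symptoms=symptoms,
            family_history=family_history,
            prior_breast_condition=prior,
        )
    )


# --- independent oracle ----------------------------------------------------

RANK = {"URGENT_SPECIALIST": 4, "ROUTINE_SPECIALIST": 3,
        "NURSE_SPECIALIST": 2, "COMMUNITY_GP": 1}


def oracle_outcome(rec: PatientRecord, bloody_escalation=True) -> TriageOutcome:
    """Brute-force re-derivation: list every (condition, outcome) pair and
    take the most urgent that holds; routine-specialist fallback."""
    s = rec.symptoms
    age = rec.age_years
    unexp_breast = s.lump_breast and not s.lump_explained
    unexp_axilla = s.lump_axilla and not s.lump_explained
    discharge = s.nipple_discharge.value
    uni = s.nipple_discharge_unilateral
    candidates = []
    # urgent criteria
    if age >= 30 and unexp_breast:
        candidates.append("URGENT_SPECIALIST")
    if age >= 50 and ((discharge != "none" and uni) or s.nipple_retraction
                      or s.nipple_change_other):
        candidates.append("URGENT_SPECIALIST")
    if bloody_escalation and discharge == "bloody":
        candidates.append("URGENT_SPECIALIST")
    if s.skin_change_suspicious:
        candidates.append("URGENT_SPECIALIST")
    if age >= 30 and unexp_axilla:
        candidates.append("URGENT_SPECIALIST")
    # routine criteria
    if age < 30 and unexp_breast:
        candidates.append("ROUTINE_SPECIALIST")
    if age < 50 and ((discharge == "clear" and uni) or s.nipple_retraction
                     or s.nipple_change_other):
        candidates.append("ROUTINE_SPECIALIST")
    # nurse: family history with no symptom criterion met so far
    if rec.family_history.value in ("moderate", "strong") and not candidates:
        candidates.append("NURSE_SPECIALIST")
    # community
    if (s.pain and not s.lump_breast and not s.lump_axilla
            and not s.skin_change_suspicious and not s.nipple_retraction
            and not s.nipple_change_other and discharge == "none"):
        candidates.append("COMMUNITY_GP")
    if (s.lump_explained and not unexp_breast and not unexp_axilla
            and not s.skin_change_suspicious and not s.nipple_retraction
            and not s.nipple_change_other and discharge == "none"):
        candidates.append("COMMUNITY_GP")
    if not candidates:
        return TriageOutcome.ROUTINE_SPECIALIST
    return TriageOutcome(max(candidates, key=RANK.__getitem__))


def consistent_symptom_profiles():
    """Every consistent symptom-flag combination with a presenting complaint."""
    profiles = []
    for lb, la in itertools.product([False, True], repeat=2):
        le_options = [False, True] if (lb or la) else [False]
        for le in le_options:
            for pain in [False, True]:
                pbc_options = [False, True] if pain else [False]
                for pbc in pbc_options:
                    for disc in ["none", "clear", "bloody"]:
                        uni_options = [False, True] if disc != "none" else [False]
                        for uni in uni_options:
                            for ret, other, skin in itertools.product(
                                [False, True], repeat=3
                            ):
                                sp = SymptomProfile(
                                    lump_breast=lb, lump_axilla=la,
                                    lump_explained=le, pain=pain,
                                    pain_bilateral_cyclical=pbc,
                                    nipple_discharge=disc,
                                    nipple_discharge_unilateral=uni,
                                    nipple_retraction=ret,
                                    nipple_change_other=other,
                                    skin_change_suspicious=skin,
                                )
                                if sp.has_complaint():
                                    profiles.append(sp)
    return profiles


GRID_AGES = [16, 25, 29, 30, 45, 49, 50, 51, 70, 90]


def patient_grid(ages=GRID_AGES, sexes=("female", "male"),
                 family_histories=("none",)):
    """The full discretized patient grid used for oracle equivalence."""
    profiles = consistent_symptom_profiles()
    records = []
    i = 0
    for age, sex, fh in itertools.product(ages, sexes, family_histories):
        for sp in profiles:
            records.append(
                PatientRecord(
                    patient_id=f"grid-{i}", age_years=age, sex=sex,
                    symptoms=sp, family_history=fh,
                )
            )
            i += 1
    return records


@pytest.fixture(scope="session")
def phase2_10k():
    return generate_cohort(CohortParams.phase2(n=10_000, seed=1))


@pytest.fixture(scope="session")
def phase1_10k():
    return generate_cohort(CohortParams.phase1(n=10_000, seed=1))
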