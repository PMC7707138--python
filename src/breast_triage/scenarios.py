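"""The four built-in hypothetical scenarios and lay-response scoring.

Responders in the questionnaire phase were shown four vignettes and
asked, for each, whether the patient needed breast-specialist review
and, if so, how urgently. The answer key: one scenario requires urgent
review (a suspicious lump in an older patient), one routine review
(clear unilateral nipple discharge under 50), and two need no
specialist review at all (bilateral cyclical pain and a lump explained
by a known benign cause, both in young patients).

Responder judgment is scored like a diagnostic test: sensitivity is the
proportion of correct "review needed" answers on the two scenarios
requiring review, specificity the proportion of correct "no review"
answers on the two that do not. Urgency accuracy is scored conditional
on a correct needs-review answer, mirroring the questionnaire's
two-level question; because one published summary is ambiguous about
its denominator, the per-scenario report exposes both the all-responder
and the said-review denominators.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np

from .core import (
    EngineConfig,
    FamilyHistory,
    NippleDischarge,
    PatientRecord,
    Sex,
    SymptomProfile,
    TriageOutcome,
    triage,
)


class ReviewUrgency(str, enum.Enum):
    URGENT = "urgent"
    ROUTINE = "routine"
    NONE = "none"


#: Engine outcome consistent with each answer-key urgency.
_URGENCY_TO_OUTCOME = {
    ReviewUrgency.URGENT: TriageOutcome.URGENT_SPECIALIST,
    ReviewUrgency.ROUTINE: TriageOutcome.ROUTINE_SPECIALIST,
    ReviewUrgency.NONE: TriageOutcome.COMMUNITY_GP,
}


@dataclass(frozen=True)
class AnswerKey:
    needs_review: bool
    urgency: ReviewUrgency

    def __post_init__(self):
        if self.needs_review == (self.urgency == ReviewUrgency.NONE):
            raise ValueError("needs_review must be False exactly when urgency is none")


@dataclass(frozen=True)
class Scenario:
    scenario_id: int
    record: PatientRecord
    answer_key: AnswerKey

    def __post_init__(self):
        if self.scenario_id not in (1, 2, 3, 4):
            raise ValueError("scenario_id must be in 1..4")


@dataclass(frozen=True)
class Response:
    needs_review: bool
    urgency: ReviewUrgency


@dataclass(frozen=True)
class ResponseSet:
    """Responses keyed by (responder_id, scenario_id)."""

    responses: Mapping[tuple[str, int], Response]

    def __post_init__(self):
        for (_, sid) in self.responses:
            if sid not in (1, 2, 3, 4):
                raise ValueError(f"unknown scenario_id {sid}")


@dataclass(frozen=True)
class ScenarioScore:
    """Per-scenario response proportions with both denominators exposed."""

    n_responses: int
    p_needs_review_correct: float
    p_said_review: float
    p_urgency_correct_given_correct_review: Optional[float]
    p_urgency_correct_of_all: float


@dataclass(frozen=True)
class ScenarioScoreReport:
    per_scenario: Mapping[int, ScenarioScore]
    sensitivity: Optional[float]
    specificity: Optional[float]

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "per_scenario": {
                sid: vars(score) for sid, score in self.per_scenario.items()
            },
        }


def builtin_scenarios() -> list[Scenario]:
    """The four vignettes with their answer keys.

    Ages are chosen so each record lands in its stated outcome band:
    52 (above both age thresholds for a lump), 40 (under 50, so clear
    discharge is routine), 22 and 24 (under 30, benign patterns).
    """
    female = Sex.FEMALE
    return [
        Scenario(
            1,
            PatientRecord(
                patient_id="scenario-1",
                age_years=52,
                sex=female,
                symptoms=SymptomProfile(lump_breast=True, duration_weeks=4),
                family_history=FamilyHistory.NONE,
            ),
            AnswerKey(True, ReviewUrgency.URGENT),
        ),
        Scenario(
            2,
            PatientRecord(
                patient_id="scenario-2",
                age_years=40,
                sex=female,
                symptoms=SymptomProfile(
                    nipple_discharge=NippleDischarge.CLEAR,
                    nipple_discharge_unilateral=True,
                    duration_weeks=3,
                ),
            ),
            AnswerKey(True, ReviewUrgency.ROUTINE),
        ),
        Scenario(
            3,
            PatientRecord(
                patient_id="scenario-3",
                age_years=22,
                sex=female,
                symptoms=SymptomProfile(
                    pain=True, pain_bilateral_cyclical=True, duration_weeks=8
                ),
            ),
            AnswerKey(False, ReviewUrgency.NONE),
        ),
        Scenario(
            4,
            PatientRecord(
                patient_id="scenario-4",
                age_years=24,
                sex=female,
                symptoms=SymptomProfile(
                    lump_breast=True, lump_explained=True, duration_weeks=2
                ),
            ),
            AnswerKey(False, ReviewUrgency.NONE),
        ),
    ]


def classify_scenarios(
    config: Union[EngineConfig, Mapping, None] = None,
) -> dict[int, TriageOutcome]:
    """Run the engine on every built-in scenario."""
    return {
        sc.scenario_id: triage(sc.record, config)[0] for sc in builtin_scenarios()
    }


def scenario_key_outcome(scenario: Scenario) -> TriageOutcome:
    """The engine outcome consistent with a scenario's answer key."""
    return _URGENCY_TO_OUTCOME[scenario.answer_key.urgency]


def score_responses(
    responses: ResponseSet,
    scenarios: Optional[Iterable[Scenario]] = None,
) -> ScenarioScoreReport:
    """Score lay responses against the answer keys."""
    scens = {sc.scenario_id: sc for sc in (scenarios or builtin_scenarios())}
    for (_, sid) in responses.responses:
        if sid not in scens:
            raise ValueError(f"response references unknown scenario_id {sid}")

    per_scenario: dict[int, ScenarioScore] = {}
    sens_num = sens_den = spec_num = spec_den = 0
    for sid, sc in sorted(scens.items()):
        answers = [
            resp for (rid, s), resp in responses.responses.items() if s == sid
        ]
        n = len(answers)
        key = sc.answer_key
        review_correct = [a for a in answers if a.needs_review == key.needs_review]
        said_review = [a for a in answers if a.needs_review]
        urgency_correct_all = [a for a in answers if a.urgency == key.urgency]
        urgency_correct_given = [
            a for a in review_correct if a.urgency == key.urgency
        ]
        per_scenario[sid] = ScenarioScore(
            n_responses=n,
            p_needs_review_correct=len(review_correct) / n if n else float("nan"),
            p_said_review=len(said_review) / n if n else float("nan"),
            p_urgency_correct_given_correct_review=(
                len(urgency_correct_given) / len(review_correct)
                if review_correct
                else None
            ),
            p_urgency_correct_of_all=(
                len(urgency_correct_all) / n if n else float("nan")
            ),
        )
        if key.needs_review:
            sens_num += len(review_correct)
            sens_den += n
        else:
            spec_num += len(review_correct)
            spec_den += n
    return ScenarioScoreReport(
        per_scenario=per_scenario,
        sensitivity=sens_num / sens_den if sens_den else None,
        specificity=spec_num / spec_den if spec_den else None,
    )


def simulate_responses(
    p_correct_review_needed: float = 0.981,
    p_correct_no_review: float = 0.184,
    p_urgent_given_review: float = 0.65,
    n_responders: int = 0,
    seed: int = 0,
) -> ResponseSet:
    """Draw independent lay responses per responder x scenario.

    On scenarios requiring review, a responder answers "review needed"
    with probability ``p_correct_review_needed`` and, having done so,
    picks the correct urgency with probability ``p_urgent_given_review``
    (otherwise the other urgency). On no-review scenarios the correct
    "no review" answer has probability ``p_correct_no_review``; an
    incorrect reviewer picks urgent or routine with equal probability.
    Defaults for the two needs-review probabilities reproduce the
    observed lay performance (98.1% on review-needed scenarios, 18.4%
    on benign ones).
    """
    for name, p in (
        ("p_correct_review_needed", p_correct_review_needed),
        ("p_correct_no_review", p_correct_no_review),
        ("p_urgent_given_review", p_urgent_given_review),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if n_responders < 0:
        raise ValueError("n_responders must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, int], Response] = {}
    for i in range(n_responders):
        rid = f"resp-{i:05d}"
        for sc in builtin_scenarios():
            key = sc.answer_key
            if key.needs_review:
                if rng.random() < p_correct_review_needed:
                    if rng.random() < p_urgent_given_review:
                        urgency = key.urgency
                    else:
                        urgency = (
                            ReviewUrgency.ROUTINE
                            if key.urgency == ReviewUrgency.URGENT
                            else ReviewUrgency.URGENT
                        )
                    resp = Response(True, urgency)
                else:
                    resp = Response(False, ReviewUrgency.NONE)
            else:
                if rng.random() < p_correct_no_review:
                    resp = Response(False, ReviewUrgency.NONE)
                else:
                    urgency = (
                        ReviewUrgency.URGENT
                        if rng.random() < 0.5
                        else ReviewUrgency.ROUTINE
                    )
                    resp = Response(True, urgency)
            out[(rid, sc.scenario_id)] = resp
    return ResponseSet(out)
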