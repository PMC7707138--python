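"""Deterministic triage rule engine for symptomatic breast presentations.

The engine encodes the 2015 NICE "suspected cancer: recognition and
referral" criteria for breast symptoms as an explicit, auditable rule
table. A validated patient record is matched against every enabled rule;
each rule maps to one of four referral outcomes, and the final decision
is the most urgent outcome among the rules that fired. A
:class:`RuleTrace` records, for every rule, whether it fired, which rule
was decisive, and whether the safety-net fallback applied, so every
decision is explainable after the fact.

Outcomes, ordered by urgency::

    URGENT_SPECIALIST  > ROUTINE_SPECIALIST > NURSE_SPECIALIST > COMMUNITY_GP
    (two-week wait)      (~six weeks)         (family-history     (managed by
                                              review)             the GP)

The rule table (R1-R9) follows the published age/symptom criteria:
unexplained lumps at >=30 and suspicious skin or unilateral nipple
changes at >=50 are urgent; the same findings in younger patients are
routine; isolated breast pain and lumps explained by a known benign
cause are community-manageable; a family-history-only presentation is
routed to the breast specialist nurse. "Consider referral" phrasings
are encoded as firm referrals at the stated urgency, and bloody nipple
discharge escalates to urgent at any age unless disabled - both
conservative readings consistent with the over-triage behaviour this
kind of software exhibits in practice.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Union

from pydantic import BaseModel, ConfigDict, model_validator


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class NippleDischarge(str, enum.Enum):
    NONE = "none"
    CLEAR = "clear"
    BLOODY = "bloody"


class FamilyHistory(str, enum.Enum):
    NONE = "none"
    MODERATE = "moderate"
    STRONG = "strong"


class TriageOutcome(str, enum.Enum):
    """One of the four referral outcomes, ordered by urgency."""

    URGENT_SPECIALIST = "URGENT_SPECIALIST"
    ROUTINE_SPECIALIST = "ROUTINE_SPECIALIST"
    NURSE_SPECIALIST = "NURSE_SPECIALIST"
    COMMUNITY_GP = "COMMUNITY_GP"


_URGENCY_RANK: dict[TriageOutcome, int] = {
    TriageOutcome.URGENT_SPECIALIST: 4,
    TriageOutcome.ROUTINE_SPECIALIST: 3,
    TriageOutcome.NURSE_SPECIALIST: 2,
    TriageOutcome.COMMUNITY_GP: 1,
}

#: Outcomes in decreasing urgency; the canonical axis order for confusion
#: matrices and reports.
OUTCOME_ORDER: tuple[TriageOutcome, ...] = (
    TriageOutcome.URGENT_SPECIALIST,
    TriageOutcome.ROUTINE_SPECIALIST,
    TriageOutcome.NURSE_SPECIALIST,
    TriageOutcome.COMMUNITY_GP,
)


def urgency_rank(outcome: TriageOutcome) -> int:
    """Strictly decreasing integer rank over URGENT > ROUTINE > NURSE > COMMUNITY."""
    return _URGENCY_RANK[TriageOutcome(outcome)]


class RecordValidationError(ValueError):
    """Raised when a patient record violates one or more invariants.

    ``violations`` lists every violated invariant, not just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(violations))


class SymptomProfile(BaseModel):
    """Presenting symptom flags for one triage request.

    Dependent flags are constrained: ``lump_explained`` (the lump is
    attributable to a known benign cause such as recent trauma or a
    previously diagnosed cyst) requires a lump; laterality of discharge
    requires a discharge; cyclicality of pain requires pain.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    lump_breast: bool = False
    lump_axilla: bool = False
    lump_explained: bool = False
    pain: bool = False
    pain_bilateral_cyclical: bool = False
    nipple_discharge: NippleDischarge = NippleDischarge.NONE
    nipple_discharge_unilateral: bool = False
    nipple_retraction: bool = False
    nipple_change_other: bool = False
    skin_change_suspicious: bool = False
    duration_weeks: float = 0.0

    @model_validator(mode="after")
    def _check_dependent_flags(self) -> "SymptomProfile":
        violations = []
        if self.lump_explained and not (self.lump_breast or self.lump_axilla):
            violations.append("lump_explained set without any lump")
        if (
            self.nipple_discharge_unilateral
            and self.nipple_discharge == NippleDischarge.NONE
        ):
            violations.append("nipple_discharge_unilateral set without discharge")
        if self.pain_bilateral_cyclical and not self.pain:
            violations.append("pain_bilateral_cyclical set without pain")
        if self.duration_weeks < 0:
            violations.append("duration_weeks negative")
        if violations:
            raise RecordValidationError(violations)
        return self

    def has_complaint(self) -> bool:
        return (
            self.lump_breast
            or self.lump_axilla
            or self.pain
            or self.nipple_retraction
            or self.nipple_change_other
            or self.skin_change_suspicious
            or self.nipple_discharge != NippleDischarge.NONE
        )


class PatientRecord(BaseModel):
    """One symptomatic presentation: the unit of triage."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    patient_id: str
    age_years: int
    sex: Sex
    symptoms: SymptomProfile
    family_history: FamilyHistory = FamilyHistory.NONE
    prior_breast_condition: bool = False

    @model_validator(mode="after")
    def _check_invariants(self) -> "PatientRecord":
        violations = []
        if not (16 <= self.age_years <= 110):
            violations.append(f"age out of range: {self.age_years} not in [16, 110]")
        if not self.symptoms.has_complaint():
            violations.append("no presenting complaint")
        if violations:
            raise RecordValidationError(violations)
        return self


def validate_record(record: Union[PatientRecord, Mapping]) -> PatientRecord:
    """Validate a record (or a plain mapping) against every type invariant.

    Returns the validated :class:`PatientRecord`; raises
    :class:`RecordValidationError` naming every violated invariant.
    """
    if isinstance(record, PatientRecord):
        payload = record.model_dump()
    else:
        payload = dict(record)
    try:
        return PatientRecord.model_validate(payload)
    except RecordValidationError:
        raise
    except Exception as exc:  # pydantic wraps custom errors; unwrap for callers
        violations = []
        for err in getattr(exc, "errors", lambda: [])():
            ctx_err = err.get("ctx", {}).get("error")
            if isinstance(ctx_err, RecordValidationError):
                violations.extend(ctx_err.violations)
            else:
                loc = ".".join(str(p) for p in err.get("loc", ()))
                violations.append(f"{loc}: {err.get('msg', 'invalid')}")
        raise RecordValidationError(violations or [str(exc)]) from exc


class EngineConfig(BaseModel):
    """Engine options.

    ``bloody_discharge_escalation`` toggles rule R2b (bloody discharge is
    urgent at any age). ``fallback_outcome`` is the safety-net outcome
    applied when no rule fires on a validated symptomatic record;
    defaulting to a routine specialist review means an unmatched
    presentation is never silently dismissed.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    bloody_discharge_escalation: bool = True
    fallback_outcome: TriageOutcome = TriageOutcome.ROUTINE_SPECIALIST


@dataclass(frozen=True)
class TriageRule:
    """A single referral criterion: predicate over a record -> outcome."""

    rule_id: str
    description: str
    outcome: TriageOutcome
    predicate: Callable[[PatientRecord], bool]
    enabled: bool = True

    def to_config(self) -> dict:
        """Serializable view (rule_id, enabled, outcome) for config files."""
        return {
            "rule_id": self.rule_id,
            "enabled": self.enabled,
            "outcome": self.outcome.value,
            "description": self.description,
        }


@dataclass(frozen=True)
class RuleTrace:
    """Per-rule firing record explaining one triage decision.

    ``entries`` lists (rule_id, fired) for every rule in the active rule
    set, in rule order. ``primary_rule_id`` is the lowest-id rule among
    those fired at the decisive urgency; it is ``None`` when the
    fallback applied.
    """

    entries: tuple[tuple[str, bool], ...]
    final_outcome: TriageOutcome
    primary_rule_id: Optional[str]
    fallback: bool

    def fired_rule_ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, fired in self.entries if fired)


# --- rule predicates -------------------------------------------------------

def _unexplained_breast_lump(r: PatientRecord) -> bool:
    return r.symptoms.lump_breast and not r.symptoms.lump_explained


def _unexplained_axillary_lump(r: PatientRecord) -> bool:
    return r.symptoms.lump_axilla and not r.symptoms.lump_explained


def _r1(r: PatientRecord) -> bool:
    return r.age_years >= 30 and _unexplained_breast_lump(r)


def _r2(r: PatientRecord) -> bool:
    s = r.symptoms
    if r.age_years < 50:
        return False
    unilateral_discharge = (
        s.nipple_discharge != NippleDischarge.NONE and s.nipple_discharge_unilateral
    )
    return unilateral_discharge or s.nipple_retraction or s.nipple_change_other


def _r2b(r: PatientRecord) -> bool:
    return r.symptoms.nipple_discharge == NippleDischarge.BLOODY


def _r3(r: PatientRecord) -> bool:
    return r.symptoms.skin_change_suspicious


def _r4(r: PatientRecord) -> bool:
    return r.age_years >= 30 and _unexplained_axillary_lump(r)


def _r5(r: PatientRecord) -> bool:
    return r.age_years < 30 and _unexplained_breast_lump(r)


def _r6(r: PatientRecord) -> bool:
    s = r.symptoms
    if r.age_years >= 50:
        return False
    clear_unilateral = (
        s.nipple_discharge == NippleDischarge.CLEAR and s.nipple_discharge_unilateral
    )
    return clear_unilateral or s.nipple_retraction or s.nipple_change_other


def _symptom_referral_fired(r: PatientRecord, bloody_escalation: bool) -> bool:
    """Any red-flag symptom rule (R1-R6, R2b when enabled) fires."""
    preds = [_r1, _r2, _r3, _r4, _r5, _r6]
    if bloody_escalation:
        preds.append(_r2b)
    return any(p(r) for p in preds)


def _r8(r: PatientRecord) -> bool:
    s = r.symptoms
    return (
        s.pain
        and not s.lump_breast
        and not s.lump_axilla
        and not s.skin_change_suspicious
        and not s.nipple_retraction
        and not s.nipple_change_other
        and s.nipple_discharge == NippleDischarge.NONE
    )


def _r9(r: PatientRecord) -> bool:
    s = r.symptoms
    return (
        s.lump_explained
        and not _unexplained_breast_lump(r)
        and not _unexplained_axillary_lump(r)
        and not s.skin_change_suspicious
        and not s.nipple_retraction
        and not s.nipple_change_other
        and s.nipple_discharge == NippleDischarge.NONE
    )


def default_ruleset(
    config: Union[EngineConfig, Mapping, None] = None,
) -> list[TriageRule]:
    """The default rule table R1-R9 in stable order.

    ``config`` may be an :class:`EngineConfig` or a mapping of engine
    options; unknown keys are rejected. The bloody-discharge escalation
    toggle is reflected in R2b's ``enabled`` flag.
    """
    cfg = _coerce_config(config)

    def r7(r: PatientRecord) -> bool:
        return (
            r.family_history in (FamilyHistory.MODERATE, FamilyHistory.STRONG)
            and not _symptom_referral_fired(r, cfg.bloody_discharge_escalation)
        )

    U = TriageOutcome.URGENT_SPECIALIST
    R = TriageOutcome.ROUTINE_SPECIALIST
    return [
        TriageRule("R1", "age >= 30 with an unexplained breast lump", U, _r1),
        TriageRule(
            "R2",
            "age >= 50 with unilateral nipple discharge, retraction or other "
            "nipple change of concern",
            U,
            _r2,
        ),
        TriageRule(
            "R2b",
            "bloody nipple discharge at any age",
            U,
            _r2b,
            enabled=cfg.bloody_discharge_escalation,
        ),
        TriageRule("R3", "suspicious skin change (dimpling, peau d'orange, ulceration)", U, _r3),
        TriageRule("R4", "age >= 30 with an unexplained axillary lump", U, _r4),
        TriageRule("R5", "age < 30 with an unexplained breast lump", R, _r5),
        TriageRule(
            "R6",
            "age < 50 with clear unilateral discharge, retraction or other "
            "nipple change",
            R,
            _r6,
        ),
        TriageRule(
            "R7",
            "moderate or strong family history with no red-flag symptom rule fired",
            TriageOutcome.NURSE_SPECIALIST,
            r7,
        ),
        TriageRule(
            "R8",
            "breast pain only, no lump and no skin or nipple red flag",
            TriageOutcome.COMMUNITY_GP,
            _r8,
        ),
        TriageRule(
            "R9",
            "lump explained by a known benign cause, no other red flag",
            TriageOutcome.COMMUNITY_GP,
            _r9,
        ),
    ]


def _coerce_config(config: Union[EngineConfig, Mapping, None]) -> EngineConfig:
    if config is None:
        return EngineConfig()
    if isinstance(config, EngineConfig):
        return config
    return EngineConfig.model_validate(dict(config))


def fire_rules(
    record: PatientRecord,
    ruleset: Iterable[TriageRule],
    fallback_outcome: TriageOutcome = TriageOutcome.ROUTINE_SPECIALIST,
) -> RuleTrace:
    """Evaluate every enabled rule on a validated record.

    The final outcome is the maximum-urgency outcome among fired rules;
    among equal urgency the lowest rule_id is decisive. When nothing
    fires the fallback outcome applies and the trace is marked.
    """
    active = [rule for rule in ruleset if rule.enabled]
    entries = tuple((rule.rule_id, bool(rule.predicate(record))) for rule in active)
    fired = [rule for rule, (_, hit) in zip(active, entries) if hit]
    if not fired:
        return RuleTrace(entries, fallback_outcome, None, fallback=True)
    top_rank = max(urgency_rank(rule.outcome) for rule in fired)
    primary = min(
        (rule for rule in fired if urgency_rank(rule.outcome) == top_rank),
        key=lambda rule: rule.rule_id,
    )
    return RuleTrace(entries, primary.outcome, primary.rule_id, fallback=False)


def triage(
    record: Union[PatientRecord, Mapping],
    config: Union[EngineConfig, Mapping, None] = None,
) -> tuple[TriageOutcome, RuleTrace]:
    """Triage one record: validate, fire the default rule set, return
    the outcome with its explanatory trace. Pure function of
    (record, config)."""
    cfg = _coerce_config(config)
    validated = validate_record(record)
    trace = fire_rules(validated, default_ruleset(cfg), cfg.fallback_outcome)
    return trace.final_outcome, trace


def ruleset_to_config(ruleset: Iterable[TriageRule]) -> list[dict]:
    """Serializable rule-set document (rule_id, enabled, outcome) so that
    toggles are reproducible from a config file."""
    return [rule.to_config() for rule in ruleset]
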