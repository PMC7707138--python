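"""Diagnostic-accuracy statistics against the surgeon gold standard.

The breast surgeon's recommended management is the reference standard;
software and GP decisions are scored against it through a 4x4 confusion
matrix over the referral outcomes. Per-class sensitivity, specificity,
PPV and NPV are one-vs-rest; the headline urgent-vs-not pair collapses
the matrix to suspected-cancer (two-week wait) versus everything else.
Metrics with a zero denominator are reported as explicitly undefined
(``None``), never as zero, so they cannot silently distort averages.

Group comparisons use the Pearson chi-square on 2x2 tables (no Yates
continuity correction by default, df=1) and Welch's unequal-variance
two-sided t-test; pooled variance and continuity correction are exposed
as options.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .core import OUTCOME_ORDER, TriageOutcome


class DecisionSource(str, enum.Enum):
    SOFTWARE = "software"
    GP = "gp"
    SURGEON_GOLD = "surgeon_gold"


class GPUrgency(str, enum.Enum):
    URGENT = "urgent"
    ROUTINE = "routine"


class DegenerateTableError(ValueError):
    """A contingency table with a zero margin: the statistic is undefined."""


@dataclass(frozen=True)
class DecisionSet:
    """Referral decisions from one source, keyed by patient id."""

    source: DecisionSource
    decisions: Mapping[str, TriageOutcome]

    def __post_init__(self):
        object.__setattr__(self, "source", DecisionSource(self.source))
        object.__setattr__(
            self,
            "decisions",
            {str(pid): TriageOutcome(o) for pid, o in dict(self.decisions).items()},
        )

    def patient_ids(self) -> frozenset[str]:
        return frozenset(self.decisions)


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 counts indexed (gold outcome, predicted outcome) in
    :data:`~breast_triage.core.OUTCOME_ORDER`."""

    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=int)
        if arr.shape != (4, 4) or (arr < 0).any():
            raise ValueError("counts must be a 4x4 non-negative integer array")
        object.__setattr__(self, "counts", arr)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def index_of(self, outcome: TriageOutcome) -> int:
        return OUTCOME_ORDER.index(TriageOutcome(outcome))


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics; ``None`` marks a zero-denominator metric."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass(frozen=True)
class AccuracyReport:
    overall_accuracy: float
    per_class: Mapping[TriageOutcome, ClassMetrics]
    urgent_binary: Mapping[str, Optional[float]]

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_class": {o.value: m.to_dict() for o, m in self.per_class.items()},
            "urgent_binary": dict(self.urgent_binary),
        }


@dataclass(frozen=True)
class StatTestResult:
    statistic: float
    p_value: float
    test_name: str
    df: float


@dataclass(frozen=True)
class AuditReport:
    """Referral-appropriateness audit against the surgeon standard.

    A referral is appropriate when the surgeon's recommendation is any
    specialist review (gold != COMMUNITY_GP); its complement is the
    community-manageable share. ``proportion_urgent_correct`` is the
    share of GP-urgent referrals whose gold standard is urgent; it is
    ``None`` (undefined) when no referral was GP-urgent.
    """

    n_referrals: int
    proportion_appropriate: float
    proportion_community_manageable: float
    proportion_urgent_correct: Optional[float]

    def to_dict(self) -> dict:
        return {
            "n_referrals": self.n_referrals,
            "proportion_appropriate": self.proportion_appropriate,
            "proportion_community_manageable": self.proportion_community_manageable,
            "proportion_urgent_correct": self.proportion_urgent_correct,
        }


def build_confusion(gold: DecisionSet, predicted: DecisionSet) -> ConfusionMatrix:
    """Cross-tabulate predicted against gold decisions over the shared ids."""
    if gold.source != DecisionSource.SURGEON_GOLD:
        raise ValueError(f"gold set must have source surgeon_gold, got {gold.source.value}")
    gold_ids, pred_ids = gold.patient_ids(), predicted.patient_ids()
    if not gold_ids or gold_ids != pred_ids:
        missing = sorted(gold_ids ^ pred_ids)[:10]
        raise ValueError(
            "decision sets must cover identical, non-empty patient ids"
            + (f"; mismatched ids include {missing}" if missing else "")
        )
    counts = np.zeros((4, 4), dtype=int)
    for pid in gold_ids:
        g = OUTCOME_ORDER.index(gold.decisions[pid])
        p = OUTCOME_ORDER.index(predicted.decisions[pid])
        counts[g, p] += 1
    return ConfusionMatrix(counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Proportion of exact agreement: trace / n."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.n


def _safe_div(num: float, den: float) -> Optional[float]:
    return None if den == 0 else float(num) / float(den)


def class_metrics(cm: ConfusionMatrix, outcome: TriageOutcome) -> ClassMetrics:
    """One-vs-rest sensitivity/specificity/PPV/NPV for one outcome class."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    k = cm.index_of(outcome)
    tp = cm.counts[k, k]
    fn = cm.counts[k, :].sum() - tp
    fp = cm.counts[:, k].sum() - tp
    tn = cm.n - tp - fn - fp
    return ClassMetrics(
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        ppv=_safe_div(tp, tp + fp),
        npv=_safe_div(tn, tn + fn),
    )


def urgent_binary_metrics(cm: ConfusionMatrix) -> dict[str, Optional[float]]:
    """Sensitivity/specificity after collapsing to urgent vs not-urgent.

    Identical to one-vs-rest metrics for URGENT_SPECIALIST.
    """
    m = class_metrics(cm, TriageOutcome.URGENT_SPECIALIST)
    return {"sensitivity": m.sensitivity, "specificity": m.specificity}


def accuracy_report(cm: ConfusionMatrix) -> AccuracyReport:
    """Full accuracy report: overall, per-class and urgent-binary metrics."""
    return AccuracyReport(
        overall_accuracy=overall_accuracy(cm),
        per_class={o: class_metrics(cm, o) for o in OUTCOME_ORDER},
        urgent_binary=urgent_binary_metrics(cm),
    )


def two_proportion_chisq(
    successes_a: int,
    n_a: int,
    successes_b: int,
    n_b: int,
    continuity_correction: bool = False,
) -> StatTestResult:
    """Pearson chi-square comparing two proportions (2x2 table, df=1)."""
    for label, s, n in (("a", successes_a, n_a), ("b", successes_b, n_b)):
        if n < 1:
            raise ValueError(f"group {label}: n must be >= 1")
        if not 0 <= s <= n:
            raise ValueError(f"group {label}: successes must be in [0, n]")
    table = np.array(
        [[successes_a, n_a - successes_a], [successes_b, n_b - successes_b]], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("a table margin is zero; chi-square is undefined")
    res = stats.chi2_contingency(table, correction=continuity_correction)
    return StatTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="chi-square" + (" (Yates)" if continuity_correction else ""),
        df=1.0,
    )


def t_test_means(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    pooled: bool = False,
) -> StatTestResult:
    """Two-sided t-test of means; Welch (unequal variances) by default."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    for label, x in (("a", a), ("b", b)):
        if x.size < 2:
            raise ValueError(f"sample {label}: need at least 2 observations")
        if np.var(x, ddof=1) == 0:
            raise ValueError(f"sample {label}: zero variance")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return StatTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="t-test (pooled)" if pooled else "t-test (Welch)",
        df=float(res.df),
    )


def referral_audit(
    gp_urgencies: Mapping[str, Union[GPUrgency, str]],
    gold: DecisionSet,
) -> AuditReport:
    """Audit GP referrals against the surgeon standard."""
    if gold.source != DecisionSource.SURGEON_GOLD:
        raise ValueError("audit requires a surgeon_gold decision set")
    gp = {str(pid): GPUrgency(u) for pid, u in dict(gp_urgencies).items()}
    if not gp or set(gp) != set(gold.patient_ids()):
        raise ValueError("gp and gold sets must cover identical, non-empty patient ids")
    n = len(gp)
    appropriate = sum(
        1 for pid in gp if gold.decisions[pid] != TriageOutcome.COMMUNITY_GP
    )
    gp_urgent_ids = [pid for pid, u in gp.items() if u == GPUrgency.URGENT]
    urgent_correct = sum(
        1
        for pid in gp_urgent_ids
        if gold.decisions[pid] == TriageOutcome.URGENT_SPECIALIST
    )
    return AuditReport(
        n_referrals=n,
        proportion_appropriate=appropriate / n,
        proportion_community_manageable=(n - appropriate) / n,
        proportion_urgent_correct=_safe_div(urgent_correct, len(gp_urgent_ids)),
    )
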