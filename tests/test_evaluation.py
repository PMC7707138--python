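"""Accuracy-metric and statistics tests against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from breast_triage.core import OUTCOME_ORDER, TriageOutcome
from breast_triage.evaluation import (
    ConfusionMatrix,
    DecisionSet,
    DecisionSource,
    DegenerateTableError,
    accuracy_report,
    build_confusion,
    class_metrics,
    overall_accuracy,
    referral_audit,
    t_test_means,
    two_proportion_chisq,
    urgent_binary_metrics,
)

U = TriageOutcome.URGENT_SPECIALIST
R = TriageOutcome.ROUTINE_SPECIALIST
N = TriageOutcome.NURSE_SPECIALIST
C = TriageOutcome.COMMUNITY_GP


def decision_set(source, outcomes):
    return DecisionSet(source, {f"p{i}": o for i, o in enumerate(outcomes)})


@pytest.fixture
def small_pair():
    gold = decision_set(DecisionSource.SURGEON_GOLD, [U, U, R, C])
    pred = decision_set(DecisionSource.SOFTWARE, [U, R, R, C])
    return gold, pred


class TestConfusion:
    def test_perfect_agreement_is_diagonal(self):
        outcomes = [U, R, N, C, U, U, R, C, N, C]
        gold = decision_set(DecisionSource.SURGEON_GOLD, outcomes)
        pred = decision_set(DecisionSource.SOFTWARE, outcomes)
        cm = build_confusion(gold, pred)
        assert cm.n == 10 and np.trace(cm.counts) == 10

    def test_direct_counts(self, small_pair):
        cm = build_confusion(*small_pair)
        assert cm.n == 4 and np.trace(cm.counts) == 3

    def test_disjoint_ids_rejected(self):
        gold = DecisionSet(DecisionSource.SURGEON_GOLD, {"a": U})
        pred = DecisionSet(DecisionSource.SOFTWARE, {"b": U})
        with pytest.raises(ValueError, match="identical"):
            build_confusion(gold, pred)

    def test_gold_source_enforced(self, small_pair):
        gold, pred = small_pair
        with pytest.raises(ValueError, match="surgeon_gold"):
            build_confusion(pred, gold)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            build_confusion(
                DecisionSet(DecisionSource.SURGEON_GOLD, {}),
                DecisionSet(DecisionSource.SOFTWARE, {}),
            )


class TestAccuracy:
    def test_three_of_four(self, small_pair):
        assert overall_accuracy(build_confusion(*small_pair)) == 0.75

    def test_diagonal_is_one_zero_diagonal_is_zero(self):
        eye = ConfusionMatrix(np.diag([3, 2, 1, 4]))
        assert overall_accuracy(eye) == 1.0
        off = ConfusionMatrix(np.array([[0, 5, 0, 0]] + [[1, 0, 0, 0]] * 3))
        assert overall_accuracy(off) == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            overall_accuracy(ConfusionMatrix(np.zeros((4, 4), dtype=int)))

    def test_permutation_invariance(self, rng=np.random.default_rng(7)):
        all_outcomes = list(TriageOutcome)
        outcomes_g = [all_outcomes[i] for i in rng.integers(0, 4, size=30)]
        outcomes_p = [all_outcomes[i] for i in rng.integers(0, 4, size=30)]
        ids = [f"p{i}" for i in range(30)]
        perm = rng.permutation(30)
        a = overall_accuracy(
            build_confusion(
                DecisionSet(DecisionSource.SURGEON_GOLD, dict(zip(ids, outcomes_g))),
                DecisionSet(DecisionSource.SOFTWARE, dict(zip(ids, outcomes_p))),
            )
        )
        b = overall_accuracy(
            build_confusion(
                DecisionSet(
                    DecisionSource.SURGEON_GOLD,
                    {ids[i]: outcomes_g[i] for i in perm},
                ),
                DecisionSet(
                    DecisionSource.SOFTWARE, {ids[i]: outcomes_p[i] for i in perm}
                ),
            )
        )
        assert a == b


def bruteforce_class_metrics(gold, pred, outcome):
    """Independent one-vs-rest counting over the collapsed 2x2 table."""
    tp = sum(1 for g, p in zip(gold, pred) if g == outcome and p == outcome)
    fn = sum(1 for g, p in zip(gold, pred) if g == outcome and p != outcome)
    fp = sum(1 for g, p in zip(gold, pred) if g != outcome and p == outcome)
    tn = sum(1 for g, p in zip(gold, pred) if g != outcome and p != outcome)
    div = lambda a, b: None if b == 0 else a / b
    return (div(tp, tp + fn), div(tn, tn + fp), div(tp, tp + fp), div(tn, tn + fn))


class TestClassMetrics:
    def test_direct_example(self, small_pair):
        m = class_metrics(build_confusion(*small_pair), U)
        assert m.sensitivity == 0.5 and m.specificity == 1.0

    def test_absent_gold_class_is_undefined(self):
        gold = decision_set(DecisionSource.SURGEON_GOLD, [R, R, C])
        pred = decision_set(DecisionSource.SOFTWARE, [R, C, C])
        m = class_metrics(build_confusion(gold, pred), U)
        assert m.sensitivity is None

    def test_random_sets_match_bruteforce_oracle(self):
        rng = np.random.default_rng(123)
        outcomes = list(TriageOutcome)
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            gold_o = [outcomes[i] for i in rng.integers(0, 4, size=n)]
            pred_o = [outcomes[i] for i in rng.integers(0, 4, size=n)]
            ids = [f"p{i}" for i in range(n)]
            cm = build_confusion(
                DecisionSet(DecisionSource.SURGEON_GOLD, dict(zip(ids, gold_o))),
                DecisionSet(DecisionSource.SOFTWARE, dict(zip(ids, pred_o))),
            )
            assert overall_accuracy(cm) == pytest.approx(
                sum(g == p for g, p in zip(gold_o, pred_o)) / n
            )
            for outcome in outcomes:
                m = class_metrics(cm, outcome)
                expect = bruteforce_class_metrics(gold_o, pred_o, outcome)
                got = (m.sensitivity, m.specificity, m.ppv, m.npv)
                for a, b in zip(got, expect):
                    assert (a is None) == (b is None)
                    if a is not None:
                        assert a == pytest.approx(b)
            ub = urgent_binary_metrics(cm)
            mu = class_metrics(cm, U)
            assert ub == {"sensitivity": mu.sensitivity, "specificity": mu.specificity}

    def test_weighted_sensitivity_equals_accuracy(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            counts = rng.integers(0, 9, size=(4, 4))
            if counts.sum() == 0:
                continue
            cm = ConfusionMatrix(counts)
            total = 0.0
            for k, outcome in enumerate(OUTCOME_ORDER):
                row = counts[k].sum()
                if row:
                    total += (row / counts.sum()) * class_metrics(cm, outcome).sensitivity
            assert total == pytest.approx(overall_accuracy(cm))


class TestUrgentBinary:
    def test_complete_capture(self):
        gold = decision_set(DecisionSource.SURGEON_GOLD, [U, U])
        pred = decision_set(DecisionSource.SOFTWARE, [U, U])
        assert urgent_binary_metrics(build_confusion(gold, pred))["sensitivity"] == 1.0

    def test_degenerate_all_urgent_predictor(self):
        gold = decision_set(DecisionSource.SURGEON_GOLD, [U, R, C])
        pred = decision_set(DecisionSource.SOFTWARE, [U, U, U])
        ub = urgent_binary_metrics(build_confusion(gold, pred))
        assert ub == {"sensitivity": 1.0, "specificity": 0.0}


def pearson_chisq_2x2(a, b, c, d):
    """Closed-form Pearson statistic for the table [[a, b], [c, d]]."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestChiSquare:
    def test_identical_proportions(self):
        res = two_proportion_chisq(50, 100, 50, 100)
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.df == 1

    def test_matches_closed_form(self):
        res = two_proportion_chisq(8, 10, 2, 10)
        expected = pearson_chisq_2x2(8, 2, 2, 8)
        assert res.statistic == pytest.approx(expected)
        assert res.p_value == pytest.approx(stats.chi2.sf(expected, 1))

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            two_proportion_chisq(0, 10, 0, 10)

    def test_precondition_errors(self):
        with pytest.raises(ValueError):
            two_proportion_chisq(5, 0, 1, 2)
        with pytest.raises(ValueError):
            two_proportion_chisq(5, 4, 1, 2)

    @settings(derandomize=True, max_examples=60)
    @given(
        sa=st.integers(0, 20), na=st.integers(1, 20),
        sb=st.integers(0, 20), nb=st.integers(1, 20),
    )
    def test_symmetric_under_group_swap(self, sa, na, sb, nb):
        sa, sb = min(sa, na), min(sb, nb)
        try:
            ab = two_proportion_chisq(sa, na, sb, nb)
        except DegenerateTableError:
            with pytest.raises(DegenerateTableError):
                two_proportion_chisq(sb, nb, sa, na)
            return
        ba = two_proportion_chisq(sb, nb, sa, na)
        assert ab.statistic == pytest.approx(ba.statistic)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_continuity_correction_shrinks_statistic(self):
        plain = two_proportion_chisq(8, 10, 2, 10)
        yates = two_proportion_chisq(8, 10, 2, 10, continuity_correction=True)
        assert yates.statistic < plain.statistic


def welch_oracle(a, b):
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestTTest:
    def test_sample_vs_itself(self):
        res = t_test_means([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_welch_formula(self):
        a = [43.1, 50.2, 61.0, 38.4, 47.7]
        b = [39.0, 44.1, 41.3, 52.8, 36.6]
        res = t_test_means(a, b)
        t, df, p = welch_oracle(a, b)
        assert res.statistic == pytest.approx(t)
        assert res.df == pytest.approx(df)
        assert res.p_value == pytest.approx(p)

    def test_pooled_option_matches_scipy_equal_var(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 9.0, 3.0]
        res = t_test_means(a, b, pooled=True)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(float(ref.statistic))

    @pytest.mark.parametrize("a, b", [([1.0], [1.0, 2.0]), ([1.0, 1.0], [1.0, 2.0])])
    def test_preconditions(self, a, b):
        with pytest.raises(ValueError):
            t_test_means(a, b)


class TestAudit:
    def test_direct_counts(self):
        gold = decision_set(DecisionSource.SURGEON_GOLD, [U, U, U, R, R, R, C, C])
        gp = {f"p{i}": "urgent" for i in range(8)}
        rep = referral_audit(gp, gold)
        assert rep.n_referrals == 8
        assert rep.proportion_appropriate == 0.75
        assert rep.proportion_community_manageable == 0.25
        assert rep.proportion_urgent_correct == pytest.approx(3 / 8)

    def test_all_community_gold(self):
        gold = decision_set(DecisionSource.SURGEON_GOLD, [C, C, C])
        rep = referral_audit({f"p{i}": "urgent" for i in range(3)}, gold)
        assert rep.proportion_appropriate == 0.0
        assert rep.proportion_community_manageable == 1.0

    def test_all_urgent_agreement(self):
        gold = decision_set(DecisionSource.SURGEON_GOLD, [U, U])
        rep = referral_audit({"p0": "urgent", "p1": "urgent"}, gold)
        assert (
            rep.proportion_appropriate,
            rep.proportion_community_manageable,
            rep.proportion_urgent_correct,
        ) == (1.0, 0.0, 1.0)

    def test_mismatched_ids_rejected(self):
        gold = decision_set(DecisionSource.SURGEON_GOLD, [U, U])
        with pytest.raises(ValueError):
            referral_audit({"zz": "urgent"}, gold)

    def test_complementarity_always_holds(self):
        rng = np.random.default_rng(11)
        outcomes = list(TriageOutcome)
        for _ in range(50):
            n = int(rng.integers(1, 20))
            gold = decision_set(
                DecisionSource.SURGEON_GOLD,
                [outcomes[i] for i in rng.integers(0, 4, size=n)],
            )
            gp = {
                f"p{i}": "urgent" if rng.random() < 0.8 else "routine"
                for i in range(n)
            }
            rep = referral_audit(gp, gold)
            assert rep.proportion_appropriate + rep.proportion_community_manageable == pytest.approx(1.0)


class TestAccuracyReport:
    def test_report_fields_and_serialization(self, small_pair):
        rep = accuracy_report(build_confusion(*small_pair))
        doc = rep.to_dict()
        assert doc["overall_accuracy"] == 0.75
        assert set(doc["per_class"]) == {o.value for o in TriageOutcome}
        assert set(doc["urgent_binary"]) == {"sensitivity", "specificity"}
        for metrics in doc["per_class"].values():
            for v in metrics.values():
                assert v is None or 0.0 <= v <= 1.0
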