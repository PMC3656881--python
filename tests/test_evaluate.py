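"""Performance measures and the model-selection protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sh2pep as s
from sh2pep.evaluate import (
    SelectionProtocol,
    auc_pr,
    auc_roc,
    confusion,
    cross_validated_auc,
    select_model,
    threshold_at_specificity,
)
from sh2pep.svm import SVMConfig


def brute_force_auc(scores, labels):
    """Oracle: concordant-pair count over all pos x neg pairs, ties half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_separation(self):
        cm = confusion([-1, -1, 1, 1], [-1, -1, 1, 1], 0.0)
        assert (cm.sensitivity, cm.specificity, cm.precision) == (1.0, 1.0, 1.0)

    def test_all_predicted_positive(self):
        cm = confusion([1, 1, 1, 1], [1, 1, -1, -1], 0.0)
        assert cm.sensitivity == 1.0 and cm.specificity == 0.0

    def test_hand_computed_toy_table(self):
        """TP=3, FN=1, TN=4, FP=2 -> sens 0.75, spec 2/3, prec 0.6."""
        labels = [1] * 4 + [-1] * 6
        scores = [1, 1, 1, -1] + [1, 1, -1, -1, -1, -1]
        cm = confusion(scores, labels, 0.0)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (3, 1, 4, 2)
        assert cm.sensitivity == pytest.approx(0.75)
        assert cm.specificity == pytest.approx(2 / 3)
        assert cm.precision == pytest.approx(0.6)

    def test_undefined_ratios_are_none_not_zero(self):
        cm = confusion([-1.0, -1.0], [-1, -1], 0.0)
        assert cm.sensitivity is None and cm.specificity == 1.0
        assert cm.precision is None


class TestAUC:
    def test_perfect_separation_gives_one(self):
        assert auc_roc([0.9, 0.8, 0.1, 0.2], [1, 1, -1, -1]) == 1.0

    def test_independent_scores_near_half(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.choice([1, -1], size=4000)
        assert auc_roc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_matches_brute_force_pair_count(self, rng):
        """Exact agreement with exhaustive pair enumeration, incl. ties."""
        for _ in range(30):
            n = int(rng.integers(6, 20))
            labels = np.array([1] * (n // 2) + [-1] * (n - n // 2))
            scores = rng.integers(0, 5, size=n).astype(float)  # forces ties
            assert auc_roc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_roc([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="both classes"):
            auc_pr([1.0, 2.0], [-1, -1])

    def test_auc_pr_by_threshold_sweep_oracle(self):
        """Average precision on a small list equals the hand-done sweep:
        scores (4,3,2,1), labels (+,-,+,-): AP = 0.5*1 + 0.5*(2/3)."""
        ap = auc_pr([4.0, 3.0, 2.0, 1.0], [1, -1, 1, -1])
        assert ap == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.integers(-5, 5), min_size=6, max_size=12),
    st.data(),
)
def test_auc_invariances(score_ints, data):
    """AUC ROC is invariant under strictly monotone transforms, and score
    negation maps it to its complement."""
    n = len(score_ints)
    labels = data.draw(
        st.lists(st.sampled_from([1, -1]), min_size=n, max_size=n).filter(
            lambda L: 1 in L and -1 in L
        )
    )
    scores = np.array(score_ints, dtype=float)
    base = auc_roc(scores, labels)
    assert auc_roc(np.exp(scores / 2) + 3, labels) == pytest.approx(base, abs=1e-12)
    assert auc_roc(-scores, [-l for l in labels]) == pytest.approx(base, abs=1e-12)
    assert auc_roc(-scores, labels) == pytest.approx(1 - base, abs=1e-12)


class TestThresholdAtSpecificity:
    def test_target_one_excludes_all_negatives(self):
        scores = [0.1, 0.5, 0.9, 1.2]
        labels = [-1, -1, 1, 1]
        t, sens = threshold_at_specificity(scores, labels, 1.0)
        assert t > 0.5 and sens == 1.0

    def test_target_zero_admits_everything(self):
        scores = [0.1, 0.5, 0.9]
        labels = [-1, 1, 1]
        t, sens = threshold_at_specificity(scores, labels, 0.0)
        assert t <= 0.1 and sens == 1.0

    def test_five_negative_toy_admits_exactly_one_fp(self):
        """Enumerating all 6 cut positions: spec >= 0.8 with 5 negatives
        means at most 1 FP, and the smallest such threshold admits exactly 1."""
        scores = [1.0, 2.0, 3.0, 4.0, 5.0, 4.5]
        labels = [-1, -1, -1, -1, -1, 1]
        t, _ = threshold_at_specificity(scores, labels, 0.8)
        cm = confusion(np.array(scores), np.array(labels), t)
        assert cm.fp == 1 and cm.specificity == 0.8

    def test_no_negatives_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            threshold_at_specificity([1.0], [1], 0.9)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            threshold_at_specificity([1.0, 0.0], [1, -1], 1.5)


class TestSelectionProtocol:
    def _toy(self, rng, n=60):
        rule = s.make_rule(11, n_pairwise=0)
        prob = s.sample_problem(rule, n, n, 0, seed=13)
        X = s.encode_many(prob.positives + prob.negatives)
        y = np.concatenate([np.ones(n), -np.ones(n)])
        return X, y

    def test_stratified_folds_reproduce_under_fixed_seed(self, rng):
        X, y = self._toy(rng)
        proto = SelectionProtocol(n_outer_folds=3, n_repeats=1, n_inner_folds=3, seed=5)
        out1 = select_model(X, y, degrees=(1,), costs=(1.0,), protocol=proto)
        out2 = select_model(X, y, degrees=(1,), costs=(1.0,), protocol=proto)
        assert out1[0] == out2[0]
        assert [f for f in out1[1].per_fold] == [f for f in out2[1].per_fold]

    def test_modal_config_and_tie_break(self, rng):
        """With a single-point grid the winner is trivially modal; with two
        exactly-tied configs the tie breaks toward smaller degree then C."""
        X, y = self._toy(rng)
        proto = SelectionProtocol(n_outer_folds=3, n_repeats=1, n_inner_folds=3, seed=5)
        cfg, _, winners = select_model(X, y, degrees=(2,), costs=(10.0,), protocol=proto)
        assert cfg == SVMConfig(2, 10.0) and set(winners) == {SVMConfig(2, 10.0)}
        # duplicate cost values -> identical inner AUCs -> earliest grid entry wins
        cfg, _, _ = select_model(X, y, degrees=(1,), costs=(1.0, 1.0), protocol=proto)
        assert cfg.C == 1.0

    def test_random_split_protocol_runs(self, rng):
        X, y = self._toy(rng)
        proto = SelectionProtocol(
            outer="random_split_75_25_x10", n_repeats=3, n_inner_folds=3, seed=5
        )
        cfg, report, winners = select_model(X, y, degrees=(1,), costs=(1.0,), protocol=proto)
        assert len(winners) == 3 and len(report.per_fold) == 3

    def test_unknown_protocol_rejected(self, rng):
        X, y = self._toy(rng)
        with pytest.raises(ValueError, match="outer"):
            select_model(X, y, protocol=SelectionProtocol(outer="loocv"))

    def test_fold_reduction_warns_on_tiny_class(self):
        X = np.vstack([np.eye(3), -np.eye(3) * 0.5])
        y = np.array([1, 1, 1, -1, -1, -1])
        with pytest.warns(UserWarning, match="reducing folds"):
            cross_validated_auc(X, y, SVMConfig(1, 1.0), n_folds=5, seed=0)

    def test_report_summary_has_sd_fields(self, rng):
        X, y = self._toy(rng)
        proto = SelectionProtocol(n_outer_folds=3, n_repeats=2, n_inner_folds=3, seed=5)
        _, report, _ = select_model(X, y, degrees=(1,), costs=(1.0,), protocol=proto)
        summary = report.summary()
        assert set(summary) >= {"sensitivity", "sensitivity_sd", "auc_roc", "auc_roc_sd"}
        assert 0.5 <= summary["auc_roc"] <= 1.0


class TestLinearVsNonlinear:
    def test_xor_linear_at_chance_quadratic_separates(self, xor_split, xor_models):
        """The linear-vs-polynomial mechanism: held-out AUC ~0.5 for degree 1,
        >0.9 for degree 2 on the balanced XOR domain."""
        _, _, Xt, yt = xor_split
        a1 = auc_roc(xor_models[1].decision_values(Xt), yt)
        a2 = auc_roc(xor_models[2].decision_values(Xt), yt)
        assert abs(a1 - 0.5) <= 0.1
        assert a2 > 0.9

    def test_additive_rule_linear_is_sufficient(self):
        """Purely additive rule: a degree-1 model reaches AUC >= 0.95."""
        rule = s.make_rule(3, n_pairwise=0)
        prob = s.sample_problem(rule, 500, 500, 0, seed=11)
        X = s.encode_many(prob.positives + prob.negatives)
        y = np.concatenate([np.ones(500), -np.ones(500)])
        assert cross_validated_auc(X, y, SVMConfig(1, 1.0), n_folds=5, seed=0) >= 0.95
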