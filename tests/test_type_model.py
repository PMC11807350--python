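"""Multi-label type classifier, dynamic thresholding, Funding rule."""

import numpy as np
import pytest

from salnlp.encoders import HashingEncoder
from salnlp.eval_stats import micro_prf
from salnlp.sentence_model import TrainConfig
from salnlp.type_model import (
    DEFAULT_GRID,
    ThresholdVector,
    fit_thresholds,
    funding_rule,
    predict_types,
    predict_with_rules,
    train_type,
)
from tests.conftest import make_sentence


@pytest.fixture(scope="module")
def sal_train(medium_corpus):
    return [s for s in medium_corpus.sentences if s.is_sal]


@pytest.fixture(scope="module")
def type_clf(sal_train, taxonomy):
    return train_type(
        sal_train, "top",
        TrainConfig(seed=2, epochs=120, header_order="headers_first"),
        taxonomy=taxonomy,
    )


class TestTraining:
    def test_label_space_size_top(self, type_clf):
        assert len(type_clf.label_space) == 15

    def test_probabilities_sum_to_one(self, type_clf, sal_train):
        P = type_clf.predict_proba(sal_train[:40])
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-6)
        assert (P >= 0).all()

    def test_training_micro_f1_on_separable_fixture(self, type_clf, sal_train, taxonomy):
        probs = type_clf.predict_proba(sal_train)
        gold = [s.types_top for s in sal_train]
        tv = fit_thresholds(probs, gold, type_clf.label_space)
        pred = predict_types(type_clf, tv, sal_train)
        _, _, f1 = micro_prf(gold, pred)
        assert f1 >= 0.9

    def test_fixed_seed_reproducible(self, sal_train, taxonomy):
        cfg = TrainConfig(seed=5, epochs=15, header_order="headers_first")
        a = train_type(sal_train, "top", cfg, taxonomy=taxonomy)
        b = train_type(sal_train, "top", cfg, taxonomy=taxonomy)
        assert np.array_equal(a.predict_proba(sal_train[:20]), b.predict_proba(sal_train[:20]))

    def test_empty_gold_set_rejected(self, sal_train, taxonomy):
        bad = sal_train[:5] + [make_sentence("No labels here.")]
        with pytest.raises(ValueError, match="empty gold"):
            train_type(bad, "top", TrainConfig(epochs=1), taxonomy=taxonomy)

    def test_fine_granularity_label_space(self, sal_train, taxonomy):
        clf = train_type(sal_train, "fine",
                         TrainConfig(seed=1, epochs=5, header_order="headers_first"),
                         taxonomy=taxonomy)
        assert len(clf.label_space) == 39  # 15 top + 24 fine


def _threshold_oracle(probs, gold_flags, grid):
    """Exhaustive per-grid-point F1, independent of the implementation."""
    best_t, best_f1 = None, -1.0
    for t in grid:
        pred = probs >= t
        tp = int((gold_flags & pred).sum())
        fp = int((~gold_flags & pred).sum())
        fn = int((gold_flags & ~pred).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return best_t, best_f1


class TestThresholds:
    def test_clean_separation(self):
        probs = np.array([[0.95], [0.65], [0.4], [0.2]])
        gold = [{"A"}, {"A"}, set(), set()]
        grid = [round(0.1 * i, 1) for i in range(1, 10)]
        tv = fit_thresholds(probs, gold, ["A"], grid)
        assert tv.thresholds["A"] == 0.5

    def test_tie_break_smallest(self):
        probs = np.ones((4, 1))
        gold = [{"A"}] * 4
        grid = [round(0.1 * i, 1) for i in range(1, 10)]
        tv = fit_thresholds(probs, gold, ["A"], grid)
        assert tv.thresholds["A"] == 0.1

    def test_absent_label_gets_grid_max_with_warning(self):
        probs = np.full((3, 2), 0.5)
        gold = [{"A"}, {"A"}, {"A"}]
        tv = fit_thresholds(probs, gold, ["A", "B"])
        assert tv.thresholds["B"] == DEFAULT_GRID[-1]
        assert any("B" in w for w in tv.warnings)

    def test_optimal_on_random_fixtures(self):
        rng = np.random.default_rng(12)
        grid = [round(x, 2) for x in np.arange(0.05, 1.0, 0.05)]
        for _ in range(40):
            n, k = int(rng.integers(5, 40)), 4
            probs = rng.random((n, k))
            labels = [f"L{j}" for j in range(k)]
            gold = [
                {labels[j] for j in range(k) if rng.random() < 0.4} or {labels[0]}
                for _ in range(n)
            ]
            tv = fit_thresholds(probs, gold, labels, grid)
            for j, lab in enumerate(labels):
                g = np.array([lab in s for s in gold])
                if not g.any():
                    continue
                t_star, f_star = _threshold_oracle(probs[:, j], g, grid)
                _, f_fit = _threshold_oracle(probs[:, j], g, [tv.thresholds[lab]])
                assert f_fit == pytest.approx(f_star)
                assert tv.thresholds[lab] <= t_star or f_fit == f_star

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            fit_thresholds(np.ones((1, 1)), [{"A"}], ["A"], grid=[0.5, 0.2])
        with pytest.raises(ValueError):
            fit_thresholds(np.ones((1, 1)), [{"A"}], ["A"], grid=[0.0, 0.5])


class TestPredictTypes:
    def _clf_with_probs(self, probs, labels):
        class _Fixed:
            label_space = labels

            def predict_proba(self, records):
                return probs[: len(records)]

        return _Fixed()

    def test_direct_comparison(self):
        clf = self._clf_with_probs(np.array([[0.5, 0.3, 0.2]]), ["A", "B", "C"])
        tv = ThresholdVector(thresholds={"A": 0.4, "B": 0.25, "C": 0.9})
        out = predict_types(clf, tv, [make_sentence("x", fine={"Population"})])
        assert out == [frozenset({"A", "B"})]

    def test_fallback_argmax_and_empty(self):
        clf = self._clf_with_probs(np.array([[0.4, 0.35, 0.25]]), ["A", "B", "C"])
        tv = ThresholdVector(thresholds={"A": 0.9, "B": 0.9, "C": 0.9})
        rec = [make_sentence("x", fine={"Population"})]
        assert predict_types(clf, tv, rec, fallback="argmax") == [frozenset({"A"})]
        assert predict_types(clf, tv, rec, fallback="empty") == [frozenset()]

    def test_label_space_mismatch(self):
        clf = self._clf_with_probs(np.ones((1, 2)), ["A", "B"])
        tv = ThresholdVector(thresholds={"A": 0.5})
        with pytest.raises(ValueError):
            predict_types(clf, tv, [make_sentence("x", fine={"Population"})])

    def test_lowering_threshold_is_monotone(self, type_clf, sal_train):
        probs = type_clf.predict_proba(sal_train[:30])
        gold = [s.types_top for s in sal_train[:30]]
        tv = fit_thresholds(probs, gold, type_clf.label_space)
        base = predict_types(type_clf, tv, sal_train[:30], fallback="empty")
        label = type_clf.label_space[0]
        lowered = ThresholdVector(thresholds={**tv.thresholds, label: 0.01})
        low = predict_types(type_clf, lowered, sal_train[:30], fallback="empty")
        for b, l in zip(base, low):
            if label in b:
                assert label in l


class TestFundingRule:
    @pytest.mark.parametrize(
        "sentence,expected",
        [
            ("No external funding was received.", True),
            ("The trial was financed by the sponsor.", True),
            ("Participants provided informed consent.", False),
            ("Funds were insufficient to extend recruitment.", True),
            ("A fundamental flaw remained.", False),  # 'fundamental' does not stem to 'fund'
        ],
    )
    def test_default_stems(self, sentence, expected):
        assert funding_rule(sentence) is expected

    def test_literal_stem_config(self):
        # honoring the literal configured strings instead of stemmed forms
        assert funding_rule("funding ran out", stemmer=str, stems=("funding",)) is True

    def test_rule_supplements_classifier(self, type_clf, sal_train, taxonomy):
        probs = type_clf.predict_proba(sal_train[:10])
        gold = [s.types_top for s in sal_train[:10]]
        tv = fit_thresholds(probs, gold, type_clf.label_space)
        rec = make_sentence("The trial was financed by the sponsor entirely.",
                            fine={"Population"})
        base = predict_types(type_clf, tv, [rec])
        with_rule = predict_with_rules(type_clf, tv, [rec])
        assert with_rule[0] >= base[0] | {"Funding"}

    def test_union_idempotent_when_rule_silent(self, type_clf, sal_train):
        probs = type_clf.predict_proba(sal_train[:10])
        tv = fit_thresholds(probs, [s.types_top for s in sal_train[:10]],
                            type_clf.label_space)
        recs = [r for r in sal_train[:10] if not funding_rule(r.text)]
        assert predict_with_rules(type_clf, tv, recs) == predict_types(type_clf, tv, recs)
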