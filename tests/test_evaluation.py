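"""Confusion matrix and classification statistics against a gold standard."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invivoannot import (
    ConfusionMatrix,
    GoldLabel,
    classification_stats,
    confusion_matrix,
)

cells = st.integers(min_value=0, max_value=10_000)


class TestConfusionMatrix:
    def test_one_exemplar_per_quadrant(self):
        """One published exemplar per cell: an annotated+curated assay, a
        doubly blank one, an annotated-only one, a curated-only one."""
        gold = [
            GoldLabel("CHEMBL985321", curator_positive=True),   # TP
            GoldLabel("CHEMBL843578", curator_positive=False),  # TN
            GoldLabel("CHEMBL851918", curator_positive=False),  # FP
            GoldLabel("CHEMBL2020189", curator_positive=True),  # FN
        ]
        predictions = {
            "CHEMBL985321": True,
            "CHEMBL843578": False,
            "CHEMBL851918": True,
            "CHEMBL2020189": False,
        }
        assert confusion_matrix(predictions, gold) == ConfusionMatrix(
            tp=1, fn=1, fp=1, tn=1
        )

    def test_all_positive(self):
        gold = [GoldLabel(f"A{i}", True) for i in range(5)]
        predictions = {f"A{i}": True for i in range(5)}
        cm = confusion_matrix(predictions, gold)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (5, 0, 0, 0)

    def test_excluded_rows_never_scored(self):
        gold = [GoldLabel("A1", True), GoldLabel("A2", True, excluded=True)]
        cm = confusion_matrix({"A1": True, "A2": True}, gold)
        assert cm.n_scored == 1

    def test_500_gold_rows_with_12_excluded_score_488(self):
        gold = [GoldLabel(f"A{i}", True, excluded=i < 12) for i in range(500)]
        predictions = {f"A{i}": True for i in range(500)}
        cm = confusion_matrix(predictions, gold)
        assert cm.n_scored == 488
        assert sum(1 for g in gold if g.excluded) == 12

    def test_duplicate_gold_id_rejected(self):
        gold = [GoldLabel("A1", True), GoldLabel("A1", False)]
        with pytest.raises(ValueError, match="duplicate"):
            confusion_matrix({"A1": True}, gold)

    def test_missing_prediction_defaults_negative_or_errors(self):
        gold = [GoldLabel("A1", True)]
        cm = confusion_matrix({}, gold)
        assert cm.fn == 1
        with pytest.raises(ValueError, match="A1"):
            confusion_matrix({}, gold, strict_missing=True)

    def test_invariant_to_gold_row_order(self):
        gold = [GoldLabel(f"A{i}", i % 2 == 0) for i in range(20)]
        predictions = {f"A{i}": i % 3 == 0 for i in range(20)}
        assert confusion_matrix(predictions, gold) == confusion_matrix(
            predictions, gold[::-1]
        )

    def test_random_tally_agrees_with_bruteforce_and_sklearn(self):
        import numpy as np
        from sklearn.metrics import confusion_matrix as sk_confusion

        rng = np.random.default_rng(5)
        truth = rng.integers(0, 2, size=200).astype(bool)
        pred = rng.integers(0, 2, size=200).astype(bool)
        gold = [GoldLabel(f"A{i}", bool(truth[i])) for i in range(200)]
        predictions = {f"A{i}": bool(pred[i]) for i in range(200)}
        cm = confusion_matrix(predictions, gold)
        tally = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
        for t, p in zip(truth, pred):
            tally[("tp" if t else "fp") if p else ("fn" if t else "tn")] += 1
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (
            tally["tp"], tally["fn"], tally["fp"], tally["tn"]
        )
        sk = sk_confusion(truth, pred, labels=[True, False])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (
            sk[0, 0], sk[0, 1], sk[1, 0], sk[1, 1]
        )


class TestClassificationStats:
    def test_published_matrix_reproduces_published_statistics(self):
        stats = classification_stats(ConfusionMatrix(tp=315, fn=63, fp=36,
                                                     tn=74))
        assert stats.rounded(2) == {
            "sensitivity": 0.83, "specificity": 0.67,
            "precision": 0.90, "f1": 0.86,
        }

    def test_perfect_classifier(self):
        stats = classification_stats(ConfusionMatrix(10, 0, 0, 10))
        assert stats.rounded(2) == {
            "sensitivity": 1.0, "specificity": 1.0,
            "precision": 1.0, "f1": 1.0,
        }

    def test_hand_computed_fractions(self):
        stats = classification_stats(ConfusionMatrix(tp=7, fn=3, fp=2, tn=8))
        assert stats.sensitivity == pytest.approx(0.70)
        assert stats.specificity == pytest.approx(0.80)
        assert stats.precision == pytest.approx(7 / 9)
        assert stats.f1 == pytest.approx(14 / 19)

    def test_zero_denominators_reported_absent_not_zero(self):
        stats = classification_stats(ConfusionMatrix(0, 0, 0, 5))
        assert stats.sensitivity is None
        assert stats.precision is None
        assert stats.f1 is None
        assert stats.specificity == 1.0
        assert set(stats.undefined) == {"sensitivity", "precision", "f1"}

    @settings(derandomize=True, max_examples=200)
    @given(tp=cells, fn=cells, fp=cells, tn=cells)
    def test_f1_is_harmonic_mean_of_precision_and_sensitivity(
        self, tp, fn, fp, tn
    ):
        stats = classification_stats(ConfusionMatrix(tp, fn, fp, tn))
        if None in (stats.precision, stats.sensitivity, stats.f1):
            return
        if stats.precision + stats.sensitivity == 0:
            assert stats.f1 == 0.0
            return
        harmonic = (2 * stats.precision * stats.sensitivity
                    / (stats.precision + stats.sensitivity))
        assert stats.f1 == pytest.approx(harmonic)

    @settings(derandomize=True, max_examples=200)
    @given(tp=cells, fn=cells, fp=cells, tn=cells)
    def test_label_flip_symmetry(self, tp, fn, fp, tn):
        """Swapping predicted labels maps (TP,FN,FP,TN) -> (FP,TN,TP,FN)."""
        gold = (
            [GoldLabel(f"tp{i}", True) for i in range(min(tp, 50))]
            + [GoldLabel(f"fn{i}", True) for i in range(min(fn, 50))]
            + [GoldLabel(f"fp{i}", False) for i in range(min(fp, 50))]
            + [GoldLabel(f"tn{i}", False) for i in range(min(tn, 50))]
        )
        predictions = {
            g.assay_id: g.assay_id.startswith(("tp", "fp")) for g in gold
        }
        cm = confusion_matrix(predictions, gold)
        flipped_gold = [
            GoldLabel(g.assay_id, not g.curator_positive) for g in gold
        ]
        flipped = confusion_matrix(predictions, flipped_gold)
        assert (flipped.tp, flipped.fn, flipped.fp, flipped.tn) == (
            cm.fp, cm.tn, cm.tp, cm.fn
        )
        # flipping the predictions instead transposes the other diagonal
        pred_flipped = confusion_matrix(
            {k: not v for k, v in predictions.items()}, gold
        )
        assert (pred_flipped.tp, pred_flipped.fn, pred_flipped.fp,
                pred_flipped.tn) == (cm.fn, cm.tp, cm.tn, cm.fp)

    def test_statistics_lie_in_unit_interval(self):
        stats = classification_stats(ConfusionMatrix(3, 1, 4, 1))
        for value in (stats.sensitivity, stats.specificity, stats.precision,
                      stats.f1):
            assert 0.0 <= value <= 1.0
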