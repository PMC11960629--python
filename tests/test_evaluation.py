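"""Confusion matrix, metrics (vs brute-force oracle), curves, size sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from octsex.evaluation import (
    CLASSES,
    TABLE_SIZES,
    ConfusionMatrix3,
    confusion_matrix,
    learning_curves,
    metrics,
    plot_learning_curves,
    size_ablation,
)


# ---------------------------------------------------------------- oracle
def brute_force_metrics(cm: np.ndarray) -> dict:
    """Independent re-derivation with explicit loops (the test oracle)."""
    k = len(cm)
    prec, rec, f1, supp = [], [], [], []
    for c in range(k):
        tp = cm[c][c]
        col = sum(cm[r][c] for r in range(k))
        row = sum(cm[c][r] for r in range(k))
        p = tp / col if col else 0.0
        r = tp / row if row else 0.0
        prec.append(p)
        rec.append(r)
        f1.append(2 * p * r / (p + r) if (p + r) else 0.0)
        supp.append(row)
    total = sum(supp)
    present = [c for c in range(k) if supp[c] > 0]
    out = {
        "macro_precision": sum(prec[c] for c in present) / len(present),
        "macro_recall": sum(rec[c] for c in present) / len(present),
        "macro_f1": sum(f1[c] for c in present) / len(present),
        "weighted_precision": sum(prec[c] * supp[c] for c in range(k)) / total,
        "weighted_recall": sum(rec[c] * supp[c] for c in range(k)) / total,
        "weighted_f1": sum(f1[c] * supp[c] for c in range(k)) / total,
        "accuracy": sum(cm[c][c] for c in range(k)) / total,
    }
    return out


def _cm(counts) -> ConfusionMatrix3:
    return ConfusionMatrix3(counts=tuple(tuple(int(v) for v in row) for row in counts))


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = ["female"] * 3 + ["male"] * 4 + ["not_detect"]
        cm = confusion_matrix(y, y)
        np.testing.assert_array_equal(cm.array, np.diag([3, 4, 1]))

    def test_degenerate_predictor_fills_one_column(self):
        y_true = ["female", "male", "female", "not_detect"]
        cm = confusion_matrix(y_true, ["not_detect"] * 4)
        assert cm.array[:, 2].sum() == 4
        assert cm.array[:, :2].sum() == 0

    def test_random_pairs_match_explicit_tally(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(CLASSES, 200)
        y_pred = rng.choice(CLASSES, 200)
        cm = confusion_matrix(y_true, y_pred).array
        for i, ti in enumerate(CLASSES):
            for j, pj in enumerate(CLASSES):
                tally = sum(1 for t, p in zip(y_true, y_pred) if t == ti and p == pj)
                assert cm[i, j] == tally
        assert cm.sum() == 200

    def test_total_conserved(self):
        rng = np.random.default_rng(1)
        y_true = rng.choice(CLASSES, 57)
        y_pred = rng.choice(CLASSES, 57)
        assert confusion_matrix(y_true, y_pred).total == 57

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            confusion_matrix(["female"], ["rooster"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            confusion_matrix(["female"], [])


class TestMetrics:
    def test_diagonal_matrix_gives_all_ones(self):
        rep = metrics(_cm([[5, 0, 0], [0, 7, 0], [0, 0, 2]]))
        assert rep.accuracy == 1.0
        assert rep.macro_f1 == 1.0
        assert all(v == 1.0 for v in rep.precision.values())

    def test_two_class_hand_example(self):
        # [[5,1],[2,4]] with empty not_detect: handbook arithmetic
        rep = metrics(_cm([[5, 1, 0], [2, 4, 0], [0, 0, 0]]))
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.precision["female"] == pytest.approx(5 / 7)
        assert rep.recall["female"] == pytest.approx(5 / 6)
        # macro averages exclude the zero-support class
        assert rep.macro_recall == pytest.approx((5 / 6 + 4 / 6) / 2)

    def test_oracle_equivalence_on_100_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            counts = rng.integers(0, 40, (3, 3))
            if counts.sum() == 0:
                counts[0, 0] = 1
            rep = metrics(_cm(counts))
            oracle = brute_force_metrics(counts.tolist())
            for key, val in oracle.items():
                assert abs(getattr(rep, key) - val) < 1e-12, key

    def test_weighted_recall_equals_accuracy(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            counts = rng.integers(0, 30, (3, 3))
            if counts.sum() == 0:
                counts[1, 1] = 3
            rep = metrics(_cm(counts))
            assert abs(rep.weighted_recall - rep.accuracy) < 1e-12

    def test_f1_bounded_by_max_of_precision_recall(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            counts = rng.integers(0, 30, (3, 3))
            counts[0, 0] += 1
            rep = metrics(_cm(counts))
            for c in CLASSES:
                assert rep.f1[c] <= max(rep.precision[c], rep.recall[c]) + 1e-12

    def test_agrees_with_sklearn_when_all_classes_present(self):
        # independent library cross-check on matrices with no empty class
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(10)
        counts = rng.integers(1, 30, (3, 3))
        rep = metrics(_cm(counts))
        y_true, y_pred = [], []
        for i, ti in enumerate(CLASSES):
            for j, pj in enumerate(CLASSES):
                y_true += [ti] * counts[i, j]
                y_pred += [pj] * counts[i, j]
        for avg, prefix in (("macro", "macro"), ("weighted", "weighted")):
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, labels=list(CLASSES), average=avg, zero_division=0
            )
            assert getattr(rep, f"{prefix}_precision") == pytest.approx(p, abs=1e-12)
            assert getattr(rep, f"{prefix}_recall") == pytest.approx(r, abs=1e-12)
            assert getattr(rep, f"{prefix}_f1") == pytest.approx(f, abs=1e-12)

    def test_metrics_in_unit_interval(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 20, (3, 3))
        counts[2, 2] += 1
        rep = metrics(_cm(counts))
        for v in rep.to_dict().values():
            if isinstance(v, float):
                assert 0.0 <= v <= 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(_cm(np.zeros((3, 3), dtype=int)))


class TestLearningCurves:
    def _history(self, n=10):
        return {
            "train_loss": list(np.linspace(1, 0.1, n)),
            "val_loss": list(np.linspace(1.1, 0.3, n)),
            "train_acc": list(np.linspace(0.5, 1.0, n)),
            "val_acc": list(np.linspace(0.5, 0.9, n)),
        }

    def test_length_preserved(self):
        df = learning_curves(self._history(10))
        assert len(df) == 10
        assert df["epoch"].iloc[-1] == 10

    def test_csv_roundtrip_is_exact(self, tmp_path):
        df = learning_curves(self._history(7))
        path = tmp_path / "history.csv"
        df.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, df)

    def test_plot_written(self, tmp_path):
        out = tmp_path / "curves.png"
        plot_learning_curves(self._history(5), out)
        assert out.exists() and out.stat().st_size > 0

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            learning_curves({})


class TestSizeAblation:
    def test_default_sweep_matches_published_sizes(self):
        assert TABLE_SIZES == (
            (1000, 600), (224, 224), (128, 128), (128, 64), (64, 64), (75, 64)
        )

    def test_single_size_row_and_error_row(self, separable_images):
        X, y = separable_images
        train_imgs = [(im * 255).astype(np.uint8) for im in X[:30]]
        test_imgs = [(im * 255).astype(np.uint8) for im in X[30:]]
        df = size_ablation(
            train_imgs, y[:30], test_imgs, y[30:],
            sizes=((16, 16), (4, 4)),
            clf_params=dict(learning_rate=1e-3, batch_size=16, max_epochs=12,
                            patience=11, val_fraction=0.2),
            seeds=(0,),
            tau=0.0,
        )
        assert len(df) == 2
        ok = df.iloc[0]
        assert ok["error"] == ""
        assert 0.0 <= ok["accuracy"] <= 1.0
        assert abs(ok["weighted_recall"] - ok["accuracy"]) < 1e-12
        assert "too small" in df.iloc[1]["error"]
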