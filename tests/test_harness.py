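"""Fold construction, metric oracles, combined loss, and training control."""

import numpy as np
import pytest

from thermoseg.caps import CapsConfig
from thermoseg.harness import (
    MetricsReport,
    PipelineConfig,
    PipelineModel,
    TrainConfig,
    classification_metrics,
    combined_loss,
    cross_entropy,
    make_folds,
    segmentation_metrics,
    train,
)
from thermoseg.nn import Tensor
from thermoseg.synthio import SynthConfig, generate_cohort
from thermoseg.umst import UmstConfig, dice_loss


def brute_force_seg_metrics(S, T):
    """Independent pixel-count oracle (explicit loops)."""
    inter = s = t = 0
    for a, b in zip(S.ravel(), T.ravel()):
        inter += int(bool(a) and bool(b))
        s += int(bool(a))
        t += int(bool(b))
    if s + t - inter == 0:
        return 1.0, 1.0, 1.0, 1.0
    return (2 * inter / (s + t), inter / (s + t - inter),
            inter / s if s else 0.0, inter / t if t else 0.0)


def brute_force_cls_metrics(pred, true):
    tp = sum(1 for p, q in zip(pred, true) if p == 1 and q == 1)
    tn = sum(1 for p, q in zip(pred, true) if p == 0 and q == 0)
    fp = sum(1 for p, q in zip(pred, true) if p == 1 and q == 0)
    fn = sum(1 for p, q in zip(pred, true) if p == 0 and q == 1)
    acc = (tp + tn) / len(pred)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, prec, rec, f1


class TestFolds:
    def test_study_cohort_fold_sizes(self):
        """122 DM + 45 CG -> folds of 33-34 subjects with 24-25 DM and 9 CG."""
        recs = generate_cohort(SynthConfig(n_dm=122, n_cg=45, seed=7))
        plan = make_folds(recs, k=5, seed=0)
        label = {r.meta.subject_code: r.label for r in recs}
        for f in range(5):
            test = plan.test_subjects(f)
            assert 33 <= len(test) <= 34
            n_dm = sum(label[c] for c in test)
            assert 24 <= n_dm <= 25
            assert len(test) - n_dm == 9

    def test_partition_disjoint_and_covering(self, small_cohort):
        plan = make_folds(small_cohort, k=5, seed=1)
        all_test = [c for f in range(5) for c in plan.test_subjects(f)]
        assert len(all_test) == len(set(all_test)) == len(small_cohort)
        for f in range(5):
            train_set = set(plan.train_subjects(f))
            test_set = set(plan.test_subjects(f))
            assert not train_set & test_set
            assert train_set | test_set == set(plan.fold_of)

    def test_each_subject_in_exactly_four_training_folds(self, small_cohort):
        plan = make_folds(small_cohort, k=5, seed=2)
        counts = {c: 0 for c in plan.fold_of}
        for f in range(5):
            for c in plan.train_subjects(f):
                counts[c] += 1
        assert set(counts.values()) == {4}

    def test_stratification_tolerance(self):
        recs = generate_cohort(SynthConfig(n_dm=30, n_cg=12, seed=5))
        plan = make_folds(recs, k=5, seed=3)
        label = {r.meta.subject_code: r.label for r in recs}
        cohort_frac = 30 / 42
        for f in range(5):
            test = plan.test_subjects(f)
            frac = sum(label[c] for c in test) / len(test)
            assert abs(frac - cohort_frac) <= 1.0 / len(test)

    def test_deterministic_per_seed(self, small_cohort):
        a = make_folds(small_cohort, k=5, seed=9)
        b = make_folds(small_cohort, k=5, seed=9)
        assert a.fold_of == b.fold_of

    def test_too_few_subjects_rejected(self):
        recs = generate_cohort(SynthConfig(n_dm=6, n_cg=3, seed=0))
        with pytest.raises(ValueError, match="at least 5"):
            make_folds(recs, k=5, seed=0)


class TestMetricOracles:
    def test_segmentation_against_brute_force(self, rng):
        for _ in range(200):
            shape = (rng.integers(2, 8), rng.integers(2, 8))
            S = rng.random(shape) > 0.5
            T = rng.random(shape) > 0.5
            np.testing.assert_allclose(segmentation_metrics(S, T),
                                       brute_force_seg_metrics(S, T), atol=1e-12)

    def test_classification_against_brute_force(self, rng):
        for _ in range(200):
            n = rng.integers(1, 30)
            pred = rng.integers(0, 2, n)
            true = rng.integers(0, 2, n)
            np.testing.assert_allclose(classification_metrics(pred, true),
                                       brute_force_cls_metrics(pred, true),
                                       atol=1e-12)

    def test_identical_nonempty_masks_all_one(self):
        m = np.zeros((4, 4), dtype=bool)
        m[1:3, 1:3] = True
        assert segmentation_metrics(m, m) == (1.0, 1.0, 1.0, 1.0)

    def test_disjoint_masks_all_zero(self):
        S = np.zeros((4, 4), dtype=bool); S[0, 0] = True
        T = np.zeros((4, 4), dtype=bool); T[3, 3] = True
        assert segmentation_metrics(S, T) == (0.0, 0.0, 0.0, 0.0)

    def test_half_overlap_worked_example(self):
        """|S|=4, |T|=4, |SnT|=2 -> DSC 0.5, IoU 1/3, precision/recall 0.5."""
        S = np.zeros((4, 4), dtype=bool); S[0, :4] = True
        T = np.zeros((4, 4), dtype=bool); T[0, 2:], T[1, :2] = True, True
        dsc, iou, prec, rec = segmentation_metrics(S, T)
        assert (dsc, prec, rec) == (0.5, 0.5, 0.5)
        assert iou == pytest.approx(1 / 3)

    def test_confusion_worked_example(self):
        """TP=3, FP=1, FN=1, TN=5 -> acc 0.8, prec/rec/F1 0.75."""
        true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        pred = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        acc, prec, rec, f1 = classification_metrics(pred, true)
        assert (acc, prec, rec, f1) == (0.8, 0.75, 0.75, 0.75)

    def test_all_negative_predictions_zero_recall(self):
        acc, prec, rec, f1 = classification_metrics([0, 0, 0], [1, 0, 1])
        assert rec == 0.0 and f1 == 0.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classification_metrics([], [])


class TestCombinedLoss:
    def test_pure_dice_when_beta_zero(self, rng):
        logits = Tensor(rng.normal(size=(2, 8, 8, 2)))
        mask = (rng.random((2, 8, 8)) > 0.8).astype(float)
        cls = Tensor(rng.normal(size=(2, 2)))
        onehot = np.eye(2)[[0, 1]]
        total = combined_loss(logits, mask, cls, onehot, alpha=1.0, beta=0.0)
        assert total.item() == pytest.approx(dice_loss(logits, mask).item())

    def test_affine_in_components(self, rng):
        """L(alpha, beta) = alpha * dice + beta * ce exactly."""
        logits = Tensor(rng.normal(size=(2, 8, 8, 2)))
        mask = (rng.random((2, 8, 8)) > 0.8).astype(float)
        cls = Tensor(rng.normal(size=(2, 2)))
        onehot = np.eye(2)[[0, 1]]
        d = dice_loss(logits, mask).item()
        ce = cross_entropy(cls, onehot).item()
        total = combined_loss(logits, mask, cls, onehot, alpha=0.6, beta=0.4)
        assert total.item() == pytest.approx(0.6 * d + 0.4 * ce, rel=1e-12)

    def test_worked_example_dice_half_ce_log_two(self):
        """dice loss 0.5 and CE log 2 at alpha=.6/beta=.4 -> .3 + .4 log 2."""
        target = np.zeros((1, 4, 4)); target[0, 0, :4] = 1
        logits = np.full((1, 4, 4, 2), 0.0); logits[..., 1] = -40.0
        logits[0, 0, 2:4, 1] = 40.0
        logits[0, 1, 0:2, 1] = 40.0
        cls = Tensor(np.zeros((1, 2)))
        onehot = np.array([[1.0, 0.0]])
        total = combined_loss(Tensor(logits), target, cls, onehot,
                              alpha=0.6, beta=0.4, dice_eps=1e-9)
        assert total.item() == pytest.approx(0.3 + 0.4 * np.log(2), abs=1e-6)

    def test_perfect_components_zero_loss(self):
        target = np.zeros((1, 4, 4)); target[0, :2] = 1
        logits = np.zeros((1, 4, 4, 2))
        logits[..., 1] = np.where(target > 0, 60.0, -60.0)
        cls = Tensor(np.array([[60.0, -60.0]]))
        onehot = np.array([[1.0, 0.0]])
        total = combined_loss(Tensor(logits), target, cls, onehot,
                              alpha=0.6, beta=0.4)
        assert total.item() == pytest.approx(0.0, abs=1e-4)


def _tiny_pipeline():
    return PipelineConfig(
        image_size=32,
        umst=UmstConfig(embed_dim=8, depths=(1, 1, 1), heads=(2, 2, 2),
                        window=2),
        caps=CapsConfig(n_primary=8, primary_dim=4, n_out=2, out_dim=4,
                        feature_len=8),
        elm_hidden=16, elm_C=1e3)


@pytest.fixture(scope="module")
def micro_records():
    return generate_cohort(SynthConfig(n_dm=4, n_cg=2, image_size=32,
                                       lesion_count_range=(1, 1),
                                       lesion_radius_range=(3.0, 5.0), seed=8))


class TestTraining:
    def test_zero_patience_stops_after_first_non_improvement(self, micro_records):
        cfg = TrainConfig(epochs_max=30, batch_size=6, early_stop_patience=0,
                          min_delta=10.0, seed=0)  # huge min_delta: nothing improves
        model = PipelineModel(_tiny_pipeline(), seed=0)
        history = train(model, micro_records, micro_records[:2], cfg,
                        fit_elm=False)
        assert history["stopped_epoch"] == 1
        assert len(history["val_loss"]) == 2

    def test_best_loss_bookkeeping_non_increasing(self, micro_records):
        cfg = TrainConfig(epochs_max=5, batch_size=6, early_stop_patience=50,
                          seed=0)
        model = PipelineModel(_tiny_pipeline(), seed=0)
        history = train(model, micro_records, None, cfg, fit_elm=False)
        best = np.minimum.accumulate(history["val_loss"])
        assert np.all(np.diff(best) <= 0)

    def test_elm_head_fitted_after_training(self, micro_records):
        cfg = TrainConfig(epochs_max=2, batch_size=6, seed=0)
        model = PipelineModel(_tiny_pipeline(), seed=0)
        history = train(model, micro_records, None, cfg)
        assert model.elm is not None and model.elm.fitted
        assert "elm_train_error" in history
        labels = model.predict_labels(
            np.stack([r.image for r in micro_records]))
        assert labels.shape == (6,)

    def test_training_deterministic_per_seed(self, micro_records):
        cfg = TrainConfig(epochs_max=2, batch_size=6, seed=4)
        states = []
        for _ in range(2):
            model = PipelineModel(_tiny_pipeline(), seed=4)
            train(model, micro_records, None, cfg)
            states.append((model.state_dict(), model.elm.beta))
        for a, b in zip(states[0][0], states[1][0]):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(states[0][1], states[1][1])


class TestReport:
    def test_mean_row_is_arithmetic_mean(self, rng):
        rows = [{k: float(v) for k, v in zip(
            ["dsc", "iou", "seg_precision", "seg_recall",
             "accuracy", "precision", "recall", "f1"], rng.random(8))}
            for _ in range(5)]
        report = MetricsReport.from_folds(rows)
        assert len(report.table) == 7  # 5 folds + mean + sd
        expected = np.mean([[r[c] for c in report.table.columns] for r in rows],
                           axis=0)
        np.testing.assert_allclose(report.mean.values, expected, atol=1e-12)

    def test_csv_roundtrip(self, rng, tmp_path):
        import pandas as pd
        rows = [{k: 0.5 for k in ["dsc", "iou", "seg_precision", "seg_recall",
                                  "accuracy", "precision", "recall", "f1"]}
                for _ in range(5)]
        report = MetricsReport.from_folds(rows)
        report.to_csv(tmp_path / "m.csv")
        back = pd.read_csv(tmp_path / "m.csv", index_col="fold")
        np.testing.assert_allclose(back.values, report.table.values)


class TestCvAndSweep:
    def test_run_cv_writes_report_and_log(self, micro_records, tmp_path):
        from thermoseg.harness import run_cv
        cfg = TrainConfig(epochs_max=1, batch_size=6, val_fraction=0.2, seed=0)
        report, plan = run_cv(micro_records, _tiny_pipeline(), cfg, k=2,
                              out_dir=tmp_path)
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "run.log").exists()
        assert list(report.table.index) == ["fold0", "fold1", "mean", "sd"]
        cols = list(report.table.columns)
        assert cols == ["dsc", "iou", "seg_precision", "seg_recall",
                        "accuracy", "precision", "recall", "f1"]
        assert ((report.table >= 0) & (report.table <= 1)).values.all()

    def test_dropout_sweep_one_row_per_rate_with_baseline(self, micro_records):
        from thermoseg.harness import dropout_sweep
        cfg = TrainConfig(epochs_max=1, batch_size=6, val_fraction=0.2, seed=0)
        rates = [0.0, 0.5]
        table = dropout_sweep(micro_records, _tiny_pipeline(), cfg, rates,
                              fold=0, k=2)
        assert list(table["dropout"]) == rates
        assert len(table) == 2
        assert table["accuracy"].between(0, 1).all()

    def test_dropout_sweep_rejects_out_of_range_rate(self, micro_records):
        from thermoseg.harness import dropout_sweep
        cfg = TrainConfig(epochs_max=1, batch_size=6, seed=0)
        with pytest.raises(ValueError, match="rates"):
            dropout_sweep(micro_records, _tiny_pipeline(), cfg, [0.95])
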