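"""Confusion accumulation and the mIoU/mPA/Accuracy/mF1 formulas."""

import json

import numpy as np
import pytest

from aphidseg import ConfusionMatrix, MetricReport, benchmark_fps, compute_metrics


def naive_counts(pred, gt, n):
    tp = np.zeros(n, dtype=int); fp = np.zeros(n, dtype=int)
    fn = np.zeros(n, dtype=int); tn = np.zeros(n, dtype=int)
    for p, g in zip(pred.ravel(), gt.ravel()):
        for c in range(n):
            if g == c and p == c:
                tp[c] += 1
            elif g != c and p == c:
                fp[c] += 1
            elif g == c and p != c:
                fn[c] += 1
            else:
                tn[c] += 1
    return tp, fp, fn, tn


def test_update_basic_counts():
    cm = ConfusionMatrix(2)
    cm.update(np.ones((2, 2), int), np.ones((2, 2), int))
    assert cm.tp[1] == 4 and cm.fp[1] == 0 and cm.fn[1] == 0

    cm2 = ConfusionMatrix(2)
    cm2.update(np.zeros((2, 2), int), np.ones((2, 2), int))
    assert cm2.fn[1] == 4 and cm2.fp[0] == 4


def test_counts_match_naive_loop(rng):
    cm = ConfusionMatrix(3)
    pred = rng.integers(0, 3, size=(8, 8))
    gt = rng.integers(0, 3, size=(8, 8))
    cm.update(pred, gt)
    tp, fp, fn, tn = naive_counts(pred, gt, 3)
    np.testing.assert_array_equal(cm.tp, tp)
    np.testing.assert_array_equal(cm.fp, fp)
    np.testing.assert_array_equal(cm.fn, fn)
    np.testing.assert_array_equal(cm.tn, tn)
    # per-class decomposition covers every pixel
    assert (cm.tp + cm.fp + cm.fn + cm.tn == pred.size).all()


def test_perfect_prediction_scores_one(rng):
    gt = rng.integers(0, 2, size=(16, 16))
    rep = compute_metrics(ConfusionMatrix(2).update(gt, gt))
    assert rep.miou == rep.mpa == rep.accuracy == rep.mf1 == 1.0


def test_hand_worked_two_by_two_example():
    gt = np.array([[1, 1], [0, 0]])
    pred = np.array([[1, 0], [0, 0]])
    rep = compute_metrics(ConfusionMatrix(2).update(pred, gt))
    assert rep.miou == pytest.approx(7 / 12)
    assert rep.mpa == pytest.approx(0.75)
    assert rep.accuracy == pytest.approx(0.75)
    assert rep.mf1 == pytest.approx(11 / 15)


def test_formulas_match_independent_recomputation(rng):
    for _ in range(20):
        pred = rng.integers(0, 2, size=(12, 12))
        gt = rng.integers(0, 2, size=(12, 12))
        cm = ConfusionMatrix(2).update(pred, gt)
        rep = compute_metrics(cm)
        tp, fp, fn, _ = naive_counts(pred, gt, 2)
        assert rep.miou == pytest.approx(np.mean(tp / (tp + fp + fn)))
        assert rep.mpa == pytest.approx(np.mean(tp / (tp + fn)))
        assert rep.mf1 == pytest.approx(np.mean(2 * tp / (2 * tp + fp + fn)))
        assert rep.accuracy == pytest.approx(tp.sum() / pred.size)


def test_accuracy_equals_trace_over_total(rng):
    pred = rng.integers(0, 2, size=(10, 10))
    gt = rng.integers(0, 2, size=(10, 10))
    cm = ConfusionMatrix(2).update(pred, gt)
    assert compute_metrics(cm).accuracy == pytest.approx(
        np.trace(cm.table) / cm.total
    )


def test_relabeling_invariance(rng):
    pred = rng.integers(0, 2, size=(9, 9))
    gt = rng.integers(0, 2, size=(9, 9))
    rep = compute_metrics(ConfusionMatrix(2).update(pred, gt))
    rep_sw = compute_metrics(ConfusionMatrix(2).update(1 - pred, 1 - gt))
    for k in ("miou", "mpa", "accuracy", "mf1"):
        assert getattr(rep, k) == pytest.approx(getattr(rep_sw, k))


def test_streaming_equals_single_shot(rng):
    preds = rng.integers(0, 2, size=(6, 8, 8))
    gts = rng.integers(0, 2, size=(6, 8, 8))
    streamed = ConfusionMatrix(2)
    for p, g in zip(preds, gts):
        streamed.update(p, g)
    single = ConfusionMatrix(2).update(preds, gts)
    np.testing.assert_array_equal(streamed.table, single.table)


def test_absent_class_rules():
    pred = np.zeros((4, 4), int)
    gt = np.zeros((4, 4), int)
    cm = ConfusionMatrix(2).update(pred, gt)
    rep = compute_metrics(cm)  # class 1 vacuously perfect
    assert rep.miou == 1.0 and rep.mf1 == 1.0
    rep_skip = compute_metrics(cm, absent_class="skip")
    assert rep_skip.miou == 1.0  # only class 0 remains, which is perfect


def test_invalid_inputs_rejected():
    cm = ConfusionMatrix(2)
    with pytest.raises(ValueError):
        cm.update(np.array([[2]]), np.array([[0]]))
    with pytest.raises(ValueError):
        cm.update(np.zeros((2, 2), int), np.zeros((3, 3), int))
    with pytest.raises(ValueError):
        compute_metrics(ConfusionMatrix(2))
    with pytest.raises(ValueError):
        MetricReport(miou=1.2, mpa=0.5, accuracy=0.5, mf1=0.5)


def test_report_serialisation(tmp_path):
    rep = MetricReport(miou=0.6876, mpa=0.7819, accuracy=0.9332, mf1=0.7901,
                       fps=12.3456)
    pct = rep.as_percent()
    assert pct["miou"] == 68.76 and pct["fps"] == 12.346
    rep.to_json(tmp_path / "m.json")
    assert json.loads((tmp_path / "m.json").read_text())["mpa"] == 78.19
    rep.to_csv(tmp_path / "m.csv")
    header, row = (tmp_path / "m.csv").read_text().strip().splitlines()
    assert "miou" in header and "68.76" in row


@pytest.fixture(scope="module")
def tiny_model():
    from aphidseg import ModelConfig, build_model

    return build_model(ModelConfig(widths=(4, 8, 16, 32, 64)), seed=0)


class TestFps:
    def test_positive_and_single_image_definition(self, tiny_model):
        fps = benchmark_fps(tiny_model, n_images=1, resolution=32, warmup=1)
        assert fps > 0  # by definition 1 / T_inference of one forward

    def test_stability_under_more_images(self, tiny_model):
        a = benchmark_fps(tiny_model, n_images=3, resolution=32, warmup=2)
        b = benchmark_fps(tiny_model, n_images=6, resolution=32, warmup=0)
        assert a > 0 and b > 0 and 0.2 < a / b < 5  # same order of magnitude

    def test_indivisible_resolution_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            benchmark_fps(tiny_model, n_images=1, resolution=479)
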