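"""Threshold training, classification, confusion metrics and reporting."""

import numpy as np
import pytest

import mwiphase as mw
from mwiphase.classify_eval import (
    ConfusionCounts,
    ThresholdModel,
    UndefinedMetricError,
    accuracy,
    classify,
    confusion,
    metrics_row,
    metrics_table,
    overlay,
    sensitivity,
    specificity,
    train_threshold,
)
from mwiphase.datasets import sample5_confusion, ten_specimen_table

from conftest import two_band_scene


def brute_force_best_threshold(values, labels):
    """Exhaustive oracle over midpoint candidates and both polarities."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    distinct = np.unique(values)
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    candidates = np.concatenate(
        ([max(0.0, distinct[0] - 0.5 * (distinct[-1] - distinct[0] + 1e-12))], mids)
    )
    best = (-np.inf, None, None)
    for polarity in ("tumor_above", "tumor_below"):
        for t in candidates:
            pred = values > t if polarity == "tumor_above" else values < t
            sen = (pred & labels).sum() / labels.sum()
            spec = (~pred & ~labels).sum() / (~labels).sum()
            j = sen + spec - 1
            if j > best[0] + 1e-15:
                best = (j, t, polarity)
    return best


class TestTraining:
    def test_perfect_separation(self):
        dphi = np.array([[0.7, 0.8, 0.9], [0.1, 0.2, 0.3]])
        mask = np.array([[1, 1, 1], [0, 0, 0]])
        model = train_threshold(dphi, mask)
        assert 0.3 < model.threshold < 0.7
        assert model.youden_j == pytest.approx(1.0)
        assert model.polarity == "tumor_above"
        assert model.informative

    def test_no_signal_is_flagged_uninformative(self):
        dphi = np.tile(np.array([0.1, 0.5, 0.9]), (2, 1))
        mask = np.array([[1, 1, 1], [0, 0, 0]])
        model = train_threshold(dphi, mask)
        assert model.youden_j == pytest.approx(0.0, abs=1e-12)
        assert not model.informative

    def test_pooling_invariance_under_duplication(self):
        rng = np.random.default_rng(3)
        dphi = rng.uniform(0, np.pi, (10, 10))
        mask = (rng.random((10, 10)) < 0.4).astype(np.uint8)
        one = train_threshold(dphi, mask)
        two = train_threshold([dphi, dphi], [mask, mask])
        assert one.threshold == two.threshold
        assert one.polarity == two.polarity
        assert one.youden_j == pytest.approx(two.youden_j)

    def test_single_class_mask_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_threshold(np.ones((4, 4)), np.ones((4, 4)))

    @pytest.mark.parametrize("seed", range(6))
    def test_sweep_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        values = np.round(rng.uniform(0, np.pi, n), 2)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        model = train_threshold(values[None, :], labels[None, :].astype(np.uint8))
        j, t, pol = brute_force_best_threshold(values, labels)
        assert model.youden_j == pytest.approx(j, abs=1e-12)
        assert model.threshold == pytest.approx(t, abs=1e-12)
        assert model.polarity == pol

    def test_excluded_pixels_never_enter_the_pool(self):
        dphi = np.array([[0.7, 0.8, 3.0], [0.1, 0.2, 0.0]])
        mask = np.array([[1, 1, 0], [0, 0, 1]])  # two mislabeled outliers
        exclude = np.array([[0, 0, 1], [0, 0, 1]], dtype=bool)
        model = train_threshold(dphi, mask, exclude=exclude)
        assert model.youden_j == pytest.approx(1.0)


class TestClassification:
    def test_all_zero_map_stays_normal(self):
        model = ThresholdModel(threshold=0.3)
        assert (classify(np.zeros((6, 6)), model) == 0).all()

    def test_tie_pixels_are_normal(self):
        model = ThresholdModel(threshold=0.3)
        assert (classify(np.full((6, 6), 0.3), model) == 0).all()

    def test_polarity_below(self):
        model = ThresholdModel(threshold=0.5, polarity="tumor_below")
        out = classify(np.array([[0.2, 0.8]]), model)
        np.testing.assert_array_equal(out, [[1, 0]])


class TestConfusionMetrics:
    def test_perfect_and_inverted_predictions(self, rng):
        truth = (rng.random((12, 12)) < 0.3).astype(np.uint8)
        c = confusion(truth, truth)
        assert c.FP == 0 and c.FN == 0
        c_inv = confusion(1 - truth, truth)
        assert c_inv.TP == 0 and c_inv.TN == 0
        assert c.total == truth.size

    def test_reported_specimen5_ratios(self):
        c = sample5_confusion()
        assert c == ConfusionCounts(TP=916, FP=48, TN=952, FN=84)
        assert 100 * sensitivity(c) == pytest.approx(91.6)
        assert 100 * specificity(c) == pytest.approx(95.2)
        assert accuracy(c) == pytest.approx(0.934)

    @pytest.mark.parametrize(
        "counts, expected",
        [(ConfusionCounts(1, 0, 0, 0), 1.0), (ConfusionCounts(5, 0, 0, 5), 0.5)],
    )
    def test_sensitivity_values(self, counts, expected):
        assert sensitivity(counts) == expected

    def test_zero_denominators_raise(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionCounts(0, 3, 4, 0))
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionCounts(3, 0, 0, 4))
        with pytest.raises(UndefinedMetricError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_excluded_region_not_scored(self):
        pred = np.ones((4, 4), dtype=np.uint8)
        truth = np.zeros((4, 4), dtype=np.uint8)
        exclude = np.zeros((4, 4), dtype=bool)
        exclude[:2] = True
        c = confusion(pred, truth, exclude=exclude)
        assert c.total == 8 and c.FP == 8


class TestReporting:
    def test_mean_row_of_reference_study(self):
        table = metrics_table(ten_specimen_table())
        mean = table[table.sample_id == "Mean"].iloc[0]
        assert mean.sen_pct == 90.903
        assert mean.spec_pct == 94.01
        assert mean.fn_ratio_pct == 9.097
        assert mean.fp_ratio_pct == 5.99

    def test_complement_identities_hold_for_every_row(self):
        df = ten_specimen_table()
        np.testing.assert_allclose(df.sen_pct + df.fn_ratio_pct, 100.0)
        np.testing.assert_allclose(df.spec_pct + df.fp_ratio_pct, 100.0)
        # and for computed rows
        row = metrics_row("x", sample5_confusion())
        assert row.sen_pct + row.fn_ratio_pct == 100.0
        assert row.spec_pct + row.fp_ratio_pct == 100.0

    def test_single_row_mean_is_identity(self):
        row = metrics_row("s1", sample5_confusion())
        table = metrics_table([row])
        assert len(table) == 2
        assert table.iloc[1].sen_pct == pytest.approx(row.sen_pct, abs=5e-4)

    def test_empty_table_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="at least one row"):
            metrics_table(pd.DataFrame())


class TestOverlay:
    def test_alpha_blending_limits(self, rng):
        base = rng.random((8, 8, 3)) * 255
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:4, 2:4] = 1
        np.testing.assert_array_equal(overlay(mask, base, alpha=0.0), base)
        solid = overlay(mask, base, alpha=1.0, color=(255, 0, 0))
        assert (solid[2:4, 2:4] == np.array([255.0, 0.0, 0.0])).all()
        empty = overlay(np.zeros((8, 8)), base, alpha=0.7)
        np.testing.assert_array_equal(empty, base)


class TestPhantomLearning:
    def test_youden_j_monotone_in_optical_contrast(self):
        js = []
        for c_sc in (0.18, 0.24, 0.30):
            scene = two_band_scene(
                tumor_medium=mw.OpticalMedium(c_sc=c_sc), seed=7
            )
            po = mw.render_phantom(scene)
            res = mw.run_pipeline(
                po.cube, reference_strip=scene.reference_strip, truth=po.truth
            )
            js.append(res.model.youden_j)
        assert js[0] <= js[1] <= js[2]

    def test_repeated_acquisitions_are_consistent(self):
        # same geometry, three different noise draws; train on the first
        sens, specs = [], []
        model = None
        for seed in (21, 22, 23):
            scene = two_band_scene(seed=seed)
            po = mw.render_phantom(scene)
            res = mw.run_pipeline(
                po.cube,
                reference_strip=scene.reference_strip,
                truth=po.truth,
                model=model,
            )
            model = model or res.model
            sens.append(100 * sensitivity(res.counts))
            specs.append(100 * specificity(res.counts))
        assert max(sens) - min(sens) < 5.0
        assert max(specs) - min(specs) < 5.0
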