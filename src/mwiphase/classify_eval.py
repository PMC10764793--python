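"""Pixelwise tumor classification on phase-shift maps and its evaluation.

The classifier is deliberately minimal: a single threshold on the
absolute inter-wavelength phase shift, chosen by exhaustive sweep to
maximize Youden's J = Sen + Spec − 1 on pooled labeled pixels.  Pixels
are classified independently — no spatial postprocessing — so tumors of
any size or shape can in principle be delineated.

Evaluation follows the standard confusion-count metrics: sensitivity
TP/(TP+FN), specificity TN/(TN+FP) and accuracy (TP+TN)/total, reported
per sample as percentages together with their complements (FN ratio =
100 − Sen, FP ratio = 100 − Spec), plus an arithmetic-mean summary row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdModel",
    "ConfusionCounts",
    "MetricsRow",
    "train_threshold",
    "classify",
    "confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "metrics_row",
    "metrics_table",
    "overlay",
    "roc_points",
    "UndefinedMetricError",
]

#: J below which a trained model is flagged uninformative.
UNINFORMATIVE_J = 0.05


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero (no pixels of the required class)."""


@dataclass
class ThresholdModel:
    """A trained single-feature threshold classifier.

    ``polarity`` says on which side of the threshold tumor lies;
    ``youden_j`` is the training-set J at the chosen operating point and
    ``informative`` is False when the feature carried no usable signal.
    """

    threshold: float
    polarity: str = "tumor_above"  # or "tumor_below"
    trained_on: tuple = ()
    band_pair: tuple[float, float] = (float("nan"), float("nan"))
    youden_j: float = 0.0
    informative: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= np.pi:
            raise ValueError("threshold must lie in [0, pi]")
        if self.polarity not in ("tumor_above", "tumor_below"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a binary comparison against truth."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsRow:
    """One evaluated sample: Sen/Spec/accuracy (%) and complements.

    The complements are exact by construction: sen + fn_ratio == 100 and
    spec + fp_ratio == 100.
    """

    sample_id: str
    sen_pct: float
    spec_pct: float
    fn_ratio_pct: float
    fp_ratio_pct: float
    accuracy_pct: float


def _pool(shift_maps, masks, exclude=None):
    values, labels = [], []
    maps = shift_maps if isinstance(shift_maps, (list, tuple)) else [shift_maps]
    truths = masks if isinstance(masks, (list, tuple)) else [masks]
    excludes = (
        exclude
        if isinstance(exclude, (list, tuple))
        else [exclude] * len(maps)
    )
    for smap, mask, excl in zip(maps, truths, excludes):
        dphi = smap.dphi if hasattr(smap, "dphi") else np.asarray(smap, dtype=float)
        mask = np.asarray(mask)
        keep = np.ones(dphi.shape, dtype=bool)
        if excl is not None:
            keep &= ~np.asarray(excl, dtype=bool)
        values.append(dphi[keep].ravel())
        labels.append(mask[keep].ravel().astype(bool))
    return np.concatenate(values), np.concatenate(labels)


def _sweep_j(values: np.ndarray, labels: np.ndarray):
    """J(t) for both polarities at midpoint candidates, vectorized.

    Candidates are the midpoints between consecutive distinct feature
    values (plus one below the minimum), so a perfectly separating
    threshold lands strictly between the two classes.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    lab = labels[order]
    n_pos = int(lab.sum())
    n_neg = lab.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training pixels must contain both classes")

    distinct = np.unique(v)
    candidates = np.concatenate(
        ([max(0.0, distinct[0] - 0.5 * (distinct[-1] - distinct[0] + 1e-12))],
         0.5 * (distinct[:-1] + distinct[1:]))
    )
    # pixels with value <= t, per candidate
    below = np.searchsorted(v, candidates, side="right")
    cum_pos = np.concatenate(([0], np.cumsum(lab)))
    pos_below = cum_pos[below]
    neg_below = below - pos_below

    # tumor_above: predict tumor where value > t
    sen_above = (n_pos - pos_below) / n_pos
    spec_above = neg_below / n_neg
    j_above = sen_above + spec_above - 1.0
    # tumor_below: predict tumor where value < t (strict; ties -> normal)
    strictly_below = np.searchsorted(v, candidates, side="left")
    pos_strict = cum_pos[strictly_below]
    neg_strict = strictly_below - pos_strict
    sen_below = pos_strict / n_pos
    spec_below = (n_neg - neg_strict) / n_neg
    j_below = sen_below + spec_below - 1.0
    return candidates, j_above, j_below


def train_threshold(
    shift_maps,
    masks,
    exclude=None,
    trained_on: tuple = (),
    band_pair: tuple[float, float] = (float("nan"), float("nan")),
) -> ThresholdModel:
    """Fit the J-optimal threshold on pooled labeled phase-shift pixels.

    Deterministic: among equal-J candidates the lowest threshold wins,
    and between polarities the one with higher J (ties → tumor_above).
    Pixels under ``exclude`` (e.g. phase edge artifacts, the reference
    strip) never enter the pool.
    """
    values, labels = _pool(shift_maps, masks, exclude)
    candidates, j_above, j_below = _sweep_j(values, labels)

    i_above = int(np.argmax(j_above))  # argmax takes the first = lowest t
    i_below = int(np.argmax(j_below))
    if j_above[i_above] >= j_below[i_below]:
        polarity, idx, best_j = "tumor_above", i_above, float(j_above[i_above])
    else:
        polarity, idx, best_j = "tumor_below", i_below, float(j_below[i_below])

    threshold = float(min(max(candidates[idx], 0.0), np.pi))
    return ThresholdModel(
        threshold=threshold,
        polarity=polarity,
        trained_on=tuple(trained_on),
        band_pair=band_pair,
        youden_j=best_j,
        informative=best_j >= UNINFORMATIVE_J,
    )


def classify(shift_map, model: ThresholdModel) -> np.ndarray:
    """Apply a trained threshold pixelwise; strict inequality decides tumor."""
    dphi = shift_map.dphi if hasattr(shift_map, "dphi") else np.asarray(shift_map)
    if model.polarity == "tumor_above":
        return (dphi > model.threshold).astype(np.uint8)
    return (dphi < model.threshold).astype(np.uint8)


def confusion(pred, truth, exclude=None) -> ConfusionCounts:
    """Per-pixel TP/FP/TN/FN tallies over non-excluded pixels."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth shape mismatch")
    keep = np.ones(pred.shape, dtype=bool)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    p, t = pred[keep], truth[keep]
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        FP=int(np.sum(p & ~t)),
        TN=int(np.sum(~p & ~t)),
        FN=int(np.sum(~p & t)),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """Sen = TP / (TP + FN)."""
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("no positive pixels: sensitivity undefined")
    return c.TP / (c.TP + c.FN)


def specificity(c: ConfusionCounts) -> float:
    """Spec = TN / (TN + FP)."""
    if c.TN + c.FP == 0:
        raise UndefinedMetricError("no negative pixels: specificity undefined")
    return c.TN / (c.TN + c.FP)


def accuracy(c: ConfusionCounts) -> float:
    """Accuracy = (TP + TN) / total."""
    if c.total == 0:
        raise UndefinedMetricError("no evaluated pixels: accuracy undefined")
    return (c.TP + c.TN) / c.total


def metrics_row(sample_id, counts: ConfusionCounts) -> MetricsRow:
    """Build a per-sample row with exact complement identities."""
    sen = 100.0 * sensitivity(counts)
    spec = 100.0 * specificity(counts)
    return MetricsRow(
        sample_id=str(sample_id),
        sen_pct=sen,
        spec_pct=spec,
        fn_ratio_pct=100.0 - sen,
        fp_ratio_pct=100.0 - spec,
        accuracy_pct=100.0 * accuracy(counts),
    )


_METRIC_COLUMNS = ["sen_pct", "spec_pct", "fn_ratio_pct", "fp_ratio_pct", "accuracy_pct"]


def metrics_table(rows) -> pd.DataFrame:
    """Assemble per-sample rows and append the arithmetic-mean row.

    Accepts MetricsRow objects, dicts, or a DataFrame with the metric
    columns.  Means are reported to 3 decimals in a final "Mean" row.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        records = [
            r.__dict__ if isinstance(r, MetricsRow) else dict(r) for r in rows
        ]
        df = pd.DataFrame.from_records(records)
    if df.empty:
        raise ValueError("metrics table needs at least one row")
    cols = [c for c in _METRIC_COLUMNS if c in df.columns]
    mean = {c: round(float(df[c].mean()), 3) for c in cols}
    mean["sample_id"] = "Mean"
    return pd.concat([df, pd.DataFrame([mean])], ignore_index=True)


def overlay(mask, rgb_image, alpha: float = 0.5, color=(255, 0, 0)) -> np.ndarray:
    """Alpha-blend tumor pixels in a fixed color over a base RGB image."""
    mask = np.asarray(mask).astype(bool)
    base = np.asarray(rgb_image, dtype=float)
    if base.ndim == 2:
        base = np.repeat(base[:, :, None], 3, axis=2)
    if base.shape[:2] != mask.shape:
        raise ValueError("mask/image shape mismatch")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    out = base.copy()
    out[mask] = (1.0 - alpha) * base[mask] + alpha * np.asarray(color, dtype=float)
    return out


def roc_points(shift_map, truth, exclude=None, n_thresholds: int = 101):
    """(FPR, TPR) samples over a threshold grid — for inspection only."""
    values, labels = _pool(shift_map, truth, exclude)
    thresholds = np.linspace(0.0, np.pi, n_thresholds)
    pos = labels.sum()
    neg = labels.size - pos
    tpr = [(values[labels] > t).sum() / pos for t in thresholds]
    fpr = [(values[~labels] > t).sum() / neg for t in thresholds]
    return np.array(fpr), np.array(tpr), thresholds
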