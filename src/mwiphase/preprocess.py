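"""Per-band image conditioning: white-reference normalization, histogram
equalization, 256-level normalization and moving-average filtering.

Two consumers with different needs share these stages.  The display /
segmentation-overlay path uses the full chain ending in 8-bit images; the
phase-extraction path must stay in floating point (quantizing to 256
levels injects ~1e-2 rad of phase noise) and therefore uses only the
white normalization and, optionally, the moving-average filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "PreprocessConfig",
    "white_normalize",
    "hist_equalize",
    "normalize_levels",
    "moving_average",
    "preprocess_display",
    "phase_input",
]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


@dataclass
class PreprocessConfig:
    """Knobs for the conditioning chain.

    ``ma_window`` is the (rows, cols) moving-average extent, both odd;
    ``reference_strategy`` selects whether the white reference comes from
    the in-scene strip or a separate reference cube; ``epsilon`` guards
    divisions; ``equalize_first`` swaps equalization ahead of level
    normalization (both orders are defensible, the default matches the
    processing-chain figure order); ``ma_for_phase`` applies the moving
    average to the float phase-branch input as a denoiser.
    """

    ma_window: tuple[int, int] = (3, 3)
    hist_bins: int = 256
    reference_strategy: str = "strip_mean"  # or "reference_cube"
    epsilon: float = 1e-6
    equalize_first: bool = True
    ma_for_phase: bool = True

    def __post_init__(self) -> None:
        n, m = self.ma_window
        if n < 1 or m < 1 or n % 2 == 0 or m % 2 == 0:
            raise ValueError("ma_window dimensions must be odd and >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.reference_strategy not in ("strip_mean", "reference_cube"):
            raise ValueError(f"unknown reference strategy {self.reference_strategy!r}")


def white_normalize(image, reference_image, epsilon: float = 1e-6):
    """Divide an image by the white reference, elementwise and regularized.

    ``out = image / max(reference, epsilon)``.  The reference may be a
    full image, a per-column profile or a scalar (broadcast).  Over the
    white region itself the output is ≈ 1 by construction.
    """
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference_image, dtype=float)
    try:
        np.broadcast_shapes(image.shape, reference.shape)
    except ValueError as exc:
        raise ValueError("image/reference shape mismatch") from exc
    return image / np.maximum(reference, epsilon)


def hist_equalize(image) -> np.ndarray:
    """Cumulative-histogram equalization onto integer levels 0..255.

    Each distinct input value v maps to floor(cdf(v)·255 + 0.5) where
    cdf(v) is the fraction of pixels ≤ v.  Monotone in the input, and a
    function of the value ranks only, so any strictly increasing
    intensity transform of the input leaves the output unchanged.
    """
    image = np.asarray(image)
    if not np.all(np.isfinite(image)):
        raise ValueError("input must be finite")
    values, inverse, counts = np.unique(
        image, return_inverse=True, return_counts=True
    )
    cdf = np.cumsum(counts) / image.size
    levels = _round_half_up(cdf * 255.0)
    return levels[inverse].reshape(image.shape).astype(np.uint8)


def normalize_levels(image) -> np.ndarray:
    """Affine min→0, max→255 rescale with round-half-up; constants → 0."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("input must be finite")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.uint8)
    scaled = (image - lo) / (hi - lo) * 255.0
    return _round_half_up(scaled).astype(np.uint8)


def moving_average(image, n: int = 3, m: int = 3) -> np.ndarray:
    """n × m window mean with reflective border padding.

    ``out(x, y) = (1/(n·m)) Σ_{(k,z) in w} NI(k, z)`` over the window
    centred at (x, y); output has the input's shape.
    """
    if n % 2 == 0 or m % 2 == 0 or n < 1 or m < 1:
        raise ValueError("window dimensions must be odd and >= 1")
    image = np.asarray(image, dtype=float)
    padded = np.pad(image, ((n // 2, n // 2), (m // 2, m // 2)), mode="symmetric")
    return sliding_window_view(padded, (n, m)).mean(axis=(-2, -1))


def preprocess_display(image, reference_image, config: PreprocessConfig | None = None):
    """Full 8-bit conditioning chain for display / overlay images.

    white normalization → histogram equalization → 256-level
    normalization → moving average (order of the two middle stages is
    configurable via ``equalize_first``).
    """
    cfg = config or PreprocessConfig()
    out = white_normalize(image, reference_image, cfg.epsilon)
    if cfg.equalize_first:
        out = hist_equalize(out)
        out = normalize_levels(out)
    else:
        out = normalize_levels(out)
        out = hist_equalize(out)
    return moving_average(out, *cfg.ma_window)


def phase_input(image, reference_image, config: PreprocessConfig | None = None):
    """Float conditioning for the phase branch: normalize, optionally denoise.

    Keeps the carrier fringe linear (no equalization, no quantization) so
    demodulated phase is unbiased.
    """
    cfg = config or PreprocessConfig()
    out = white_normalize(image, reference_image, cfg.epsilon)
    if cfg.ma_for_phase:
        out = moving_average(out, *cfg.ma_window)
    return out
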