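"""Fourier-domain phase extraction and inter-wavelength phase-shift maps.

The scene carries a spatial carrier fringe along the column axis.  Each
image line is demodulated with the analytic-signal (Hilbert) construction:
remove the line mean, Fourier transform, zero strictly negative frequency
bins, double strictly positive ones, inverse transform.  The argument of
the resulting complex signal is the local wrapped phase, its modulus the
fringe envelope.

The classification feature is the *absolute inter-wavelength phase shift*
|wrap(φ_λ1 − φ_λ2)| ∈ [0, π].  Because the carrier frequency is common to
all bands, the carrier ramp cancels exactly in this difference; only the
tissue-induced optical-path phase survives.

An alternative "fourier2d" route (full 2-D spectrum with a regularized
reference deconvolution) is provided for inspection; both routes share the
same half-plane demodulation operator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hs_io import SpectralCube, select_band
from .tissue_optics import wrap_phase

__all__ = [
    "PhaseMap",
    "PhaseShiftMap",
    "forward_spectrum",
    "inverse_spectrum",
    "deconvolve_reference",
    "analytic_phase",
    "phase_relative_to_reference",
    "phase_shift_map",
    "line_profile",
    "estimate_carrier_cycles",
    "remove_carrier",
    "phase_stack",
]


@dataclass
class PhaseMap:
    """Per-pixel wrapped phase (radians, (−π, π]) for one spectral band.

    ``amplitude`` is the fringe envelope (≥ 0); ``degenerate_lines`` flags
    lines that carried no fluctuation (phase defined as 0 there).
    """

    phase: np.ndarray
    wavelength_nm: float = float("nan")
    amplitude: np.ndarray | None = None
    degenerate_lines: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.amplitude is None:
            self.amplitude = np.ones_like(self.phase)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if not (np.all(self.phase > -np.pi) and np.all(self.phase <= np.pi)):
            raise ValueError("phase must be wrapped to (-pi, pi]")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")


@dataclass
class PhaseShiftMap:
    """Absolute inter-wavelength phase difference, per pixel, in [0, π]."""

    dphi: np.ndarray
    pair: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        self.dphi = np.asarray(self.dphi, dtype=float)
        if np.any(self.dphi < 0) or np.any(self.dphi > np.pi):
            raise ValueError("dphi must lie in [0, pi]")


def forward_spectrum(image) -> np.ndarray:
    """2-D discrete Fourier transform of a real image, origin at (0, 0)."""
    return np.fft.fft2(np.asarray(image, dtype=float))


def inverse_spectrum(spectrum) -> np.ndarray:
    """Inverse 2-D DFT; real part of the reconstruction."""
    return np.fft.ifft2(np.asarray(spectrum)).real


def deconvolve_reference(spectrum, reference_spectrum, epsilon: float = 1e-6):
    """Regularized (Wiener-style) division by a reference spectrum.

    ``out = S · conj(R) / (|R|² + ε)``: where the reference has power the
    division is exact as ε → 0; where it vanishes the output is bounded
    by |S|/ (2√ε) instead of blowing up.
    """
    spectrum = np.asarray(spectrum)
    reference = np.asarray(reference_spectrum)
    if spectrum.shape != reference.shape:
        raise ValueError("spectrum/reference shape mismatch")
    return spectrum * np.conj(reference) / (np.abs(reference) ** 2 + epsilon)


def _analytic_operator(n: int) -> np.ndarray:
    """Frequency-domain gain of the analytic-signal construction."""
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    return h


def analytic_phase(
    image,
    wavelength_nm: float = float("nan"),
    carrier_axis: int = 1,
) -> PhaseMap:
    """Per-line analytic-signal demodulation of a fringe-bearing image.

    Each line along ``carrier_axis`` (default: columns, i.e. one line per
    row) is mean-removed and converted to its analytic signal via the
    1-D Fourier transform.  Lines with no fluctuation at all get phase 0,
    amplitude 0 and a per-line degeneracy flag; a single warning reports
    how many lines were degenerate.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    work = image if carrier_axis == 1 else image.T

    centered = work - work.mean(axis=1, keepdims=True)
    degenerate = np.ptp(work, axis=1) == 0.0

    h = _analytic_operator(work.shape[1])
    analytic = np.fft.ifft(np.fft.fft(centered, axis=1) * h, axis=1)
    phase = wrap_phase(np.angle(analytic))  # fold the -pi edge case to +pi
    amplitude = np.abs(analytic)
    if degenerate.any():
        phase[degenerate] = 0.0
        amplitude[degenerate] = 0.0
        warnings.warn(
            f"{int(degenerate.sum())} constant line(s): phase undefined, set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    if carrier_axis != 1:
        phase, amplitude = phase.T, amplitude.T
    return PhaseMap(
        phase=phase,
        wavelength_nm=wavelength_nm,
        amplitude=amplitude,
        degenerate_lines=degenerate,
    )


def _as_phase_array(obj) -> np.ndarray:
    return obj.phase if isinstance(obj, PhaseMap) else np.asarray(obj, dtype=float)


def phase_relative_to_reference(sample_phase, reference_phase) -> PhaseMap:
    """Wrapped difference sample − reference, elementwise."""
    sample = _as_phase_array(sample_phase)
    reference = _as_phase_array(reference_phase)
    if sample.shape != np.broadcast_shapes(sample.shape, reference.shape):
        raise ValueError("sample/reference shape mismatch")
    wavelength = (
        sample_phase.wavelength_nm
        if isinstance(sample_phase, PhaseMap)
        else float("nan")
    )
    amplitude = (
        sample_phase.amplitude if isinstance(sample_phase, PhaseMap) else None
    )
    return PhaseMap(
        phase=wrap_phase(sample - reference),
        wavelength_nm=wavelength,
        amplitude=amplitude,
    )


def phase_shift_map(phase1, phase2) -> PhaseShiftMap:
    """Absolute wrapped phase difference |wrap(φ1 − φ2)| ∈ [0, π]."""
    p1 = _as_phase_array(phase1)
    p2 = _as_phase_array(phase2)
    if p1.shape != p2.shape:
        raise ValueError("phase map shape mismatch")
    pair = (
        phase1.wavelength_nm if isinstance(phase1, PhaseMap) else float("nan"),
        phase2.wavelength_nm if isinstance(phase2, PhaseMap) else float("nan"),
    )
    return PhaseShiftMap(dphi=np.abs(wrap_phase(p1 - p2)), pair=pair)


def line_profile(map_or_array, row_index: int) -> np.ndarray:
    """One horizontal line of a phase or shift map, as a 1-D signal."""
    arr = (
        map_or_array.dphi
        if isinstance(map_or_array, PhaseShiftMap)
        else _as_phase_array(map_or_array)
    )
    if not 0 <= row_index < arr.shape[0]:
        raise IndexError(f"row {row_index} outside image with {arr.shape[0]} rows")
    return arr[row_index]


def estimate_carrier_cycles(image) -> int:
    """Dominant positive spatial frequency (cycles/width) of the mean line.

    The scene's mean row spectrum is used as the stability anchor; the
    bin with the largest magnitude among strictly positive frequencies is
    returned.
    """
    image = np.asarray(image, dtype=float)
    line = image.mean(axis=0)
    line = line - line.mean()
    spec = np.abs(np.fft.rfft(line))
    if spec.size < 2:
        raise ValueError("image too narrow to estimate a carrier")
    return int(np.argmax(spec[1:]) + 1)


def remove_carrier(pmap: PhaseMap, cycles: int) -> PhaseMap:
    """Subtract the linear carrier ramp 2π·cycles·x/N and rewrap.

    Yields the per-pixel phase *offset* relative to an unperturbed fringe,
    which is the quantity plotted in per-line phase profiles.
    """
    n = pmap.phase.shape[1]
    ramp = 2.0 * np.pi * cycles * np.arange(n) / n
    return PhaseMap(
        phase=wrap_phase(pmap.phase - ramp[None, :]),
        wavelength_nm=pmap.wavelength_nm,
        amplitude=pmap.amplitude,
    )


def phase_stack(
    cube: SpectralCube,
    reference_phase=None,
    band_list=None,
) -> list[PhaseMap]:
    """Per-band phase maps, ascending wavelength — a depth-proxy stack.

    ``band_list`` holds target wavelengths in nm (default: every band).
    If ``reference_phase`` (a PhaseMap or array) is given, each band map
    is referenced to it.  Longer wavelengths probe deeper, so the band
    axis orders structures by optical depth.
    """
    if band_list is None:
        band_list = list(cube.wavelengths_nm)
    band_list = sorted(band_list)
    if len(band_list) == 0:
        raise ValueError("band list must not be empty")
    maps = []
    for target in band_list:
        img, actual = select_band(cube, target)
        pmap = analytic_phase(img, wavelength_nm=actual)
        if reference_phase is not None:
            pmap = phase_relative_to_reference(pmap, reference_phase)
        maps.append(pmap)
    return maps
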