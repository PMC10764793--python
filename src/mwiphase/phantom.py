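"""Physics-based synthetic hyperspectral phantom.

Each rendered scene holds a flat white-paper reference strip across the
top rows and a tissue region carrying a cosine carrier fringe along the
columns.  Embedded tumor ellipses differ from normal tissue in median
refractive index; the resulting round-trip optical path difference is
injected as a phase offset on the carrier, per band, so the full
demodulation pipeline can be exercised against known truth.

Model ingredients
-----------------
* Band reflectance ``R(λ) = exp(−k · µ_sc(λ) · λ_ref/λ)`` — a monotone map
  of the scattering coefficient with shorter wavelengths attenuating
  faster (λ_ref = 632 nm); ``k`` is calibrated so R(632 nm) ≈ 0.6.
* Tumor phase offset ``φ(λ) = vis(λ, d) · wrap(2π · Δn · 2d / λ)`` with
  Δn the median-index contrast and d the tumor depth (round-trip path in
  reflection, hence the factor 2).
* Depth visibility ``vis(λ, d) = exp(−max(0, d − L(λ)) / τ)`` with
  penetration limit ``L(λ) = L_ref (λ/λ_ref)^4``: a tumor buried beyond
  the blue penetration limit perturbs the red band but not the blue one.
* The tumor's *optical* footprint is its ellipse indicator blurred with a
  Gaussian PSF (lateral photon diffusion in tissue); the *truth mask*
  stays the hard ellipse.  A hard-edged phase step is not demodulable to
  high accuracy at a finite carrier frequency — the fringe's sidebands
  span roughly the phase swing times the profile bandwidth (the FM
  Carson rule) and must stay clear of the opposite carrier lobe — and
  real diffuse reflectance genuinely blurs lateral detail by roughly the
  transport length (σ = 10 px ≈ 400 µm at 40 µm/px).

Everything stochastic flows from the single scene seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .hs_io import SpectralCube
from .tissue_optics import (
    OpticalMedium,
    median_refractive_index,
    phase_from_opd,
    scattering_coefficient,
)

__all__ = [
    "TumorRegion",
    "PhantomScene",
    "PhantomOutput",
    "render_phantom",
    "make_training_set",
    "default_scene",
    "deep_tumor_scene",
    "interior_mask",
]

LAMBDA_REF_NM = 632.0


@dataclass(frozen=True)
class TumorRegion:
    """An elliptical tumor inclusion: center (row, col), semi-axes in px,
    and its depth below the tissue surface in µm."""

    center_row: int
    center_col: int
    semi_axis_r: float
    semi_axis_c: float
    depth_um: float

    def __post_init__(self) -> None:
        if self.semi_axis_r <= 0 or self.semi_axis_c <= 0:
            raise ValueError("tumor semi-axes must be positive")
        if self.depth_um <= 0:
            raise ValueError("tumor depth must be positive")


def _default_wavelengths() -> np.ndarray:
    # 128 bands, 380-1015 nm at 5 nm: the working spectral grid.
    return np.arange(380.0, 1016.0, 5.0)


@dataclass(frozen=True)
class PhantomScene:
    """Parametric description of a synthetic scene.

    ``reference_strip`` is the half-open row range [r0, r1) occupied by
    the flat white-paper region; everything below is tissue.
    ``carrier_cycles`` is the fringe frequency in cycles across the image
    width; ``modulation_depth`` its contrast.  ``noise_sigma`` is the
    additive Gaussian noise level as a fraction of full scale.
    ``attenuation_k_um`` (effective path, µm) is derived on first use so
    that R(632 nm) ≈ 0.6 for normal tissue when left at None.
    """

    rows: int = 224
    cols: int = 192
    wavelengths_nm: tuple = field(default_factory=lambda: tuple(_default_wavelengths()))
    reference_strip: tuple[int, int] = (0, 32)
    normal_medium: OpticalMedium = field(default_factory=lambda: OpticalMedium(c_sc=0.1))
    tumor_medium: OpticalMedium = field(default_factory=lambda: OpticalMedium(c_sc=0.3))
    tumor_regions: tuple[TumorRegion, ...] = field(
        default_factory=lambda: (TumorRegion(128, 96, 56.0, 44.0, 16.0),)
    )
    carrier_cycles: int = 8
    modulation_depth: float = 0.5
    noise_sigma: float = 0.02
    psf_sigma_px: float = 10.0
    attenuation_k_um: float | None = None
    vis_limit_ref_um: float = 600.0
    vis_tau_um: float = 50.0
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 < self.carrier_cycles < self.cols / 4:
            raise ValueError(
                "carrier must satisfy 0 < cycles < cols/4 (Nyquist margin)"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        r0, r1 = self.reference_strip
        if not 0 <= r0 < r1 <= self.rows:
            raise ValueError("reference strip rows out of range")
        margin = int(np.ceil(4 * self.psf_sigma_px))
        for t in self.tumor_regions:
            if (
                t.center_row - t.semi_axis_r - margin < r1
                or t.center_row + t.semi_axis_r + margin > self.rows
                or t.center_col - t.semi_axis_c - margin < 0
                or t.center_col + t.semi_axis_c + margin > self.cols
            ):
                raise ValueError(
                    "tumor (with its diffusion halo) must lie inside the tissue region"
                )

    def attenuation_k(self) -> float:
        """Effective attenuation path so R(632 nm) ≈ 0.6 for normal tissue."""
        if self.attenuation_k_um is not None:
            return self.attenuation_k_um
        mu_ref = scattering_coefficient(self.normal_medium, LAMBDA_REF_NM / 1000.0)
        return -np.log(0.6) / mu_ref

    def penetration_limit_um(self, wavelength_nm: float) -> float:
        return self.vis_limit_ref_um * (wavelength_nm / LAMBDA_REF_NM) ** 4

    def visibility(self, wavelength_nm: float, depth_um: float) -> float:
        """Fraction of a tumor's phase contrast that survives at this band."""
        excess = max(0.0, depth_um - self.penetration_limit_um(wavelength_nm))
        return float(np.exp(-excess / self.vis_tau_um))

    def band_reflectance(self, wavelength_nm: float) -> float:
        mu = scattering_coefficient(self.normal_medium, wavelength_nm / 1000.0)
        return float(
            np.exp(-self.attenuation_k() * mu * (LAMBDA_REF_NM / wavelength_nm))
        )

    def index_contrast(self) -> float:
        return median_refractive_index(self.tumor_medium) - median_refractive_index(
            self.normal_medium
        )


@dataclass
class PhantomOutput:
    """A rendered scene: the cube, the hard truth mask, per-pixel tumor
    depth (µm, 0 outside tumors) and the exact injected per-band phase
    offset (radians)."""

    cube: SpectralCube
    truth: np.ndarray
    depth_map: np.ndarray
    phase_truth: np.ndarray
    scene: PhantomScene


def _ellipse_indicator(scene: PhantomScene, tumor: TumorRegion) -> np.ndarray:
    rr, cc = np.mgrid[0 : scene.rows, 0 : scene.cols]
    rho2 = ((rr - tumor.center_row) / tumor.semi_axis_r) ** 2 + (
        (cc - tumor.center_col) / tumor.semi_axis_c
    ) ** 2
    return (rho2 <= 1.0).astype(float)


def render_phantom(scene: PhantomScene) -> PhantomOutput:
    """Render a scene into a cube + truth mask + injected-phase record.

    Deterministic given the scene (one RNG seeded by ``scene.seed``).
    """
    rows, cols = scene.rows, scene.cols
    wavelengths = np.asarray(scene.wavelengths_nm, dtype=float)
    n_bands = wavelengths.size
    r0, r1 = scene.reference_strip
    rng = np.random.default_rng(scene.seed)

    cc = np.arange(cols)
    ramp = 2.0 * np.pi * scene.carrier_cycles * cc / cols  # (cols,)

    delta_n = scene.index_contrast()
    truth = np.zeros((rows, cols), dtype=np.uint8)
    depth_map = np.zeros((rows, cols), dtype=float)
    phase_truth = np.zeros((rows, cols, n_bands), dtype=float)

    for tumor in scene.tumor_regions:
        hard = _ellipse_indicator(scene, tumor)
        truth |= hard.astype(np.uint8)
        depth_map = np.maximum(depth_map, tumor.depth_um * hard)
        footprint = ndimage.gaussian_filter(hard, scene.psf_sigma_px)
        opd_um = delta_n * 2.0 * tumor.depth_um
        offsets = np.array(
            [
                scene.visibility(w, tumor.depth_um)
                * phase_from_opd(opd_um, w / 1000.0)
                for w in wavelengths
            ]
        )
        phase_truth += footprint[:, :, None] * offsets[None, None, :]

    phase_truth[:r1] = 0.0  # the white strip carries no tissue phase

    reflectance = np.array([scene.band_reflectance(w) for w in wavelengths])
    fringe = 1.0 + scene.modulation_depth * np.cos(
        ramp[None, :, None] + phase_truth
    )
    data = reflectance[None, None, :] * fringe
    data[:r1] = 1.0
    if scene.noise_sigma > 0:
        data = data + scene.noise_sigma * rng.standard_normal(data.shape)

    cube = SpectralCube(
        data=data,
        wavelengths_nm=wavelengths,
        meta={"description": "synthetic MWI phantom", "seed": str(scene.seed)},
    )
    return PhantomOutput(
        cube=cube,
        truth=truth,
        depth_map=depth_map,
        phase_truth=phase_truth,
        scene=scene,
    )


def make_training_set(
    scene_template: PhantomScene, n_samples: int, seed: int = 0
) -> list[PhantomOutput]:
    """Render ``n_samples`` scenes with jittered tumor geometry and noise.

    Emulates repeated specimen acquisitions: tumor centers move by a few
    pixels, semi-axes and depth scale by ±15 % / ±10 %, and every render
    draws fresh noise.  Jittered geometry that would push a tumor (and
    its diffusion halo) outside the tissue region is resampled.  Fully
    reproducible from ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    outputs = []
    for _ in range(n_samples):
        for _attempt in range(100):
            tumors = tuple(
                TumorRegion(
                    center_row=int(t.center_row + rng.integers(-8, 9)),
                    center_col=int(t.center_col + rng.integers(-8, 9)),
                    semi_axis_r=t.semi_axis_r * rng.uniform(0.85, 1.15),
                    semi_axis_c=t.semi_axis_c * rng.uniform(0.85, 1.15),
                    depth_um=t.depth_um * rng.uniform(0.9, 1.1),
                )
                for t in scene_template.tumor_regions
            )
            try:
                scene = replace(
                    scene_template,
                    tumor_regions=tumors,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                break
            except ValueError:
                continue
        else:
            raise ValueError(
                "could not fit jittered tumors into the tissue region; "
                "the template leaves no room for geometric variation"
            )
        outputs.append(render_phantom(scene))
    return outputs


def default_scene(seed: int = 42, noise_sigma: float = 0.02, **overrides) -> PhantomScene:
    """The reference study scene: one shallow tumor, full 128-band grid."""
    return replace(PhantomScene(), seed=seed, noise_sigma=noise_sigma, **overrides)


def deep_tumor_scene(
    depth_um: float = 400.0, seed: int = 42, noise_sigma: float = 0.02, **overrides
) -> PhantomScene:
    """A scene whose tumor lies beyond the blue penetration limit.

    At 400 µm the 446.6 nm band retains < 1 % of the phase contrast while
    the 632 nm band sees it in full — the depth/wavelength asymmetry the
    two-band comparison exploits.
    """
    base = PhantomScene()
    tumors = tuple(
        TumorRegion(t.center_row, t.center_col, t.semi_axis_r, t.semi_axis_c, depth_um)
        for t in base.tumor_regions
    )
    return replace(
        base, tumor_regions=tumors, seed=seed, noise_sigma=noise_sigma, **overrides
    )


def interior_mask(truth: np.ndarray, margin_px: int) -> np.ndarray:
    """Tumor interior: the truth mask eroded by ``margin_px`` pixels.

    Used when comparing recovered against injected phase away from the
    diffusion-blurred boundary zone.
    """
    if margin_px <= 0:
        return truth.astype(bool)
    return ndimage.binary_erosion(
        truth.astype(bool), iterations=margin_px, border_value=0
    )
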