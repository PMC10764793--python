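"""Bulk tissue optics used to ground the phantom and interpret phase maps.

Tissue is modelled as dielectric scattering spheres (refractive index
``n_sc``) embedded in ground matter (``n_g``).  Two textbook relations are
exposed: the volume-weighted median refractive index of the mixture, and a
mono-disperse power-law scattering coefficient.  The third function maps an
optical path difference (OPD) to the interferometric phase it produces at a
given wavelength.

All lengths are micrometres; densities are µm⁻³.  Refractive indices and
volume concentrations are dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalMedium",
    "median_refractive_index",
    "scattering_coefficient",
    "phase_from_opd",
    "wrap_phase",
]

_SPHERE_VOLUME = lambda r: 4.0 / 3.0 * math.pi * r**3  # noqa: E731


@dataclass(frozen=True)
class OpticalMedium:
    """Optical description of a scattering tissue compartment.

    Parameters
    ----------
    n_g
        Refractive index of the ground (interstitial) matter, ≥ 1.
    n_sc
        Refractive index of the scattering centers, ≥ 1.
    c_sc
        Volume concentration of scatterers in [0, 1].
    r_um
        Scatterer sphere radius in µm, > 0.
    Vs_per_um3
        Sphere number density in µm⁻³.  If omitted it is derived from
        ``c_sc`` and the sphere volume so the description is internally
        consistent.
    """

    n_g: float = 1.36
    n_sc: float = 1.45
    c_sc: float = 0.1
    r_um: float = 0.5
    Vs_per_um3: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 <= self.c_sc <= 1.0:
            raise ValueError(f"c_sc must lie in [0, 1], got {self.c_sc}")
        if self.n_g < 1.0 or self.n_sc < 1.0:
            raise ValueError("refractive indices must be >= 1")
        if self.r_um <= 0.0:
            raise ValueError("scatterer radius must be positive")
        if self.Vs_per_um3 is None:
            object.__setattr__(
                self, "Vs_per_um3", self.c_sc / _SPHERE_VOLUME(self.r_um)
            )
        if self.Vs_per_um3 < 0.0:
            raise ValueError("sphere volume density must be non-negative")


def median_refractive_index(medium: OpticalMedium) -> float:
    """Volume-weighted median refractive index of the two-phase medium.

    ``n_m = c_sc * n_sc + (1 - c_sc) * n_g`` — affine in the scatterer
    concentration and bounded by the two component indices.
    """
    return medium.c_sc * medium.n_sc + (1.0 - medium.c_sc) * medium.n_g


def scattering_coefficient(medium: OpticalMedium, lambda_um: float) -> float:
    """Mono-disperse dielectric-sphere scattering coefficient in µm⁻¹.

    ``mu_sc = 3.28 π r² V_S (2πr/λ)^0.37 (n_sc/n_g − 1)^2.09`` with ``r``
    and ``λ`` in µm and ``V_S`` in µm⁻³.  The non-integer exponent on the
    index contrast restricts the model to ``n_sc >= n_g`` (scatterers at
    least as dense as the ground matter); anything else raises rather than
    silently returning NaN.
    """
    if lambda_um <= 0.0:
        raise ValueError("wavelength must be positive")
    if medium.n_sc < medium.n_g:
        raise ValueError(
            "scattering model requires n_sc >= n_g "
            f"(got n_sc={medium.n_sc}, n_g={medium.n_g})"
        )
    contrast = medium.n_sc / medium.n_g - 1.0
    r = medium.r_um
    return (
        3.28
        * math.pi
        * r**2
        * medium.Vs_per_um3
        * (2.0 * math.pi * r / lambda_um) ** 0.37
        * contrast**2.09
    )


def wrap_phase(phase):
    """Wrap phase (radians) into the principal interval (−π, π].

    Vectorized; the boundary convention keeps +π and maps −π to +π so a
    single representative exists for the half-turn.
    """
    return np.pi - np.mod(np.pi - np.asarray(phase), 2.0 * np.pi)


def phase_from_opd(delta_opd_um, lambda_um: float):
    """Interferometric phase of an optical path difference, wrapped.

    phase = wrap(2π · ΔOPD / λ); periodic in ΔOPD with period λ.
    """
    if lambda_um <= 0.0:
        raise ValueError("wavelength must be positive")
    out = wrap_phase(2.0 * np.pi * np.asarray(delta_opd_um) / lambda_um)
    if np.ndim(delta_opd_um) == 0:
        return float(out)
    return out
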