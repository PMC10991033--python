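"""Rayleigh and multi-Rayleigh (MRA) envelope-amplitude models.

The amplitude envelope of fully developed ultrasound speckle follows a
Rayleigh distribution

    p(x) = (2 x / sigma^2) exp(-x^2 / sigma^2),

where ``sigma^2`` is the echo signal power (so that ``E[x^2] = sigma^2``).
Inhomogeneous tissue with several scatterer populations is modelled as a
finite mixture of up to three Rayleigh components with ordered powers
``sigma_L^2 <= sigma_M^2 <= sigma_H^2`` (hypoechoic structures, normal
parenchyma, hyperechoic fibrotic tissue) and mixture rates summing to one.

Scales are stored as *powers* ``sigma^2`` throughout the package; the raw
moments of a mixture have the closed form

    E[x^k] = sum_c alpha_c * sigma_c^k * Gamma(1 + k/2),

with ``sigma_c = sqrt(scale_c)``, which this module provides exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "RayleighComponent",
    "MRAModel",
    "rayleigh_pdf",
    "mra_pdf",
    "theoretical_moment",
    "theoretical_moments",
]

_ORDER_TOL = 1e-12


@dataclass(frozen=True)
class RayleighComponent:
    """A single Rayleigh component parameterised by its echo power.

    Parameters
    ----------
    scale : float
        Echo signal power ``sigma^2`` (dimensionless after second-moment
        normalization). Must be strictly positive.
    """

    scale: float

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise InvalidParameterError(f"scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class MRAModel:
    """Three-component multi-Rayleigh mixture with ordered powers.

    Degenerate mixtures (one or two vanishing rates) keep the three-slot
    representation; a vanishing rate makes the corresponding scale inert.

    Parameters
    ----------
    scales : tuple of float
        Echo powers ``(sigma_L^2, sigma_M^2, sigma_H^2)``, non-decreasing.
    rates : tuple of float
        Mixture rates ``(alpha_L, alpha_M, alpha_H)`` in ``[0, 1]`` summing
        to one.
    """

    scales: tuple[float, float, float]
    rates: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.scales) != 3 or len(self.rates) != 3:
            raise InvalidParameterError("scales and rates must have length 3")
        object.__setattr__(self, "scales", tuple(float(s) for s in self.scales))
        object.__setattr__(self, "rates", tuple(float(a) for a in self.rates))
        if any(not (s > 0) for s in self.scales):
            raise InvalidParameterError(f"scales must be > 0, got {self.scales}")
        if any(a < -_ORDER_TOL or a > 1 + _ORDER_TOL for a in self.rates):
            raise InvalidParameterError(f"rates must lie in [0, 1], got {self.rates}")
        if abs(sum(self.rates) - 1.0) > 1e-12:
            raise InvalidParameterError(
                f"rates must sum to 1 within 1e-12, got sum {sum(self.rates)!r}"
            )
        sl, sm, sh = self.scales
        if sl > sm + _ORDER_TOL or sm > sh + _ORDER_TOL:
            raise InvalidParameterError(
                f"scales must satisfy sigma_L^2 <= sigma_M^2 <= sigma_H^2, got {self.scales}"
            )

    # -- constructors -----------------------------------------------------

    @classmethod
    def rayleigh(cls, scale: float = 1.0) -> "MRAModel":
        """Single Rayleigh distribution embedded as a degenerate mixture."""
        return cls(scales=(scale, scale, scale), rates=(0.0, 1.0, 0.0))

    @classmethod
    def two_component(
        cls,
        rate_lo: float,
        scale_lo: float,
        scale_hi: float,
        combination: str = "MH",
    ) -> "MRAModel":
        """Two-component mixture placed in the L+M or M+H slots.

        ``combination="MH"`` puts the low/high fitted components in the
        M/H slots (normal tissue + fibrosis); ``"LM"`` puts them in L/M
        (hypoechoic structure + normal tissue).
        """
        if combination == "MH":
            return cls(scales=(scale_lo, scale_lo, scale_hi), rates=(0.0, rate_lo, 1.0 - rate_lo))
        if combination == "LM":
            return cls(scales=(scale_lo, scale_hi, scale_hi), rates=(rate_lo, 1.0 - rate_lo, 0.0))
        raise InvalidParameterError(f"combination must be 'MH' or 'LM', got {combination!r}")

    # -- derived quantities ----------------------------------------------

    @property
    def power(self) -> float:
        """Total echo power ``sum_c alpha_c sigma_c^2`` (the second moment)."""
        return float(sum(a * s for a, s in zip(self.rates, self.scales)))

    @property
    def is_normalized(self) -> bool:
        """True when the total power is one within 1e-9 (second-moment normalization)."""
        return abs(self.power - 1.0) <= 1e-9

    @property
    def ratio_h_m(self) -> float:
        """Echo power ratio of the fibrosis to the normal component, sigma_H^2 / sigma_M^2."""
        return self.scales[2] / self.scales[1]

    def normalized(self) -> "MRAModel":
        """Return the model rescaled to unit total power."""
        p = self.power
        return MRAModel(scales=tuple(s / p for s in self.scales), rates=self.rates)


def rayleigh_pdf(x, scale: float):
    """Rayleigh probability density ``(2x/sigma^2) exp(-x^2/sigma^2)``.

    Parameters
    ----------
    x : array_like
        Envelope amplitudes, all ``>= 0``.
    scale : float
        Echo power ``sigma^2 > 0``.
    """
    if not (scale > 0):
        raise InvalidParameterError(f"scale must be > 0, got {scale}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise InvalidInputError("amplitudes must be non-negative")
    out = (2.0 * x / scale) * np.exp(-(x**2) / scale)
    return out if out.ndim else float(out)


def mra_pdf(x, model: MRAModel):
    """Mixture density ``alpha_L p_L(x) + alpha_M p_M(x) + alpha_H p_H(x)``."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x, dtype=float)
    for a, s in zip(model.rates, model.scales):
        if a > 0:
            out += a * rayleigh_pdf(x, s)
    return out if out.ndim else float(out)


def theoretical_moment(model: MRAModel, order: int) -> float:
    """Exact raw moment ``E[x^k]`` of a multi-Rayleigh model.

    Uses the closed form ``sum_c alpha_c sigma_c^k Gamma(1 + k/2)``; for a
    normalized model order 2 returns exactly 1.
    """
    if order < 1 or int(order) != order:
        raise InvalidParameterError(f"order must be a positive integer, got {order}")
    k = float(order)
    g = _gamma(1.0 + k / 2.0)
    return float(sum(a * s ** (k / 2.0) for a, s in zip(model.rates, model.scales)) * g)


def theoretical_moments(model: MRAModel, orders) -> np.ndarray:
    """Vector of raw moments ``E[x^k]`` for the given orders."""
    return np.array([theoretical_moment(model, k) for k in orders], dtype=float)
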