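"""Sample moments under second-moment normalization and the moment-space
squared Mahalanobis distance.

The component-count test works in the space of raw envelope moments of
orders (1, 3, 4, 5), computed after the envelope has been scaled so its
sample second moment is exactly one. The test statistic for a candidate
null model is

    D^2 = (m - mu)^T  Sigma^{-1}  (m - mu),

where ``mu`` holds the theoretical moments of the null and ``Sigma`` is the
sampling covariance of the moment vector at the effective number of
independent samples ``n_eff``. Under the null and iid sampling, D^2 is
asymptotically chi-square with 4 degrees of freedom.

Because the data are normalized by their own sample second moment, the
moment estimators are not the plain iid means; the covariance here applies
a first-order (delta-method) correction for that self-normalization,

    m~_k  ~=  m_k - (k/2) mu_k (m_2 - 1),

which materially improves the chi-square calibration of D^2 (the
uncorrected iid covariance is retained behind a flag for comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .envelope_model import MRAModel, theoretical_moment
from .errors import ContractError, InvalidInputError, NumericalError

__all__ = [
    "MOMENT_ORDERS",
    "MomentVector",
    "MomentCovariance",
    "normalize_envelope",
    "sample_moments",
    "moment_covariance",
    "mahalanobis_sq",
    "mahalanobis_sq_values",
]

#: Raw moment orders used by the component-count test.
MOMENT_ORDERS: tuple[int, ...] = (1, 3, 4, 5)

MIN_N_EFF = 8


@dataclass(frozen=True)
class MomentVector:
    """Raw moments (m1, m3, m4, m5) of a normalized envelope sample.

    Attributes
    ----------
    values : ndarray, shape (4,)
        Sample means of ``x^k`` for k in :data:`MOMENT_ORDERS`.
    n_eff : float
        Effective number of independent samples behind the estimate
        (``<= n_raw`` for correlated speckle).
    n_raw : int
        Raw number of pixels/samples the moments were computed from.
    """

    values: np.ndarray
    n_eff: float
    n_raw: int
    orders: tuple[int, ...] = field(default=MOMENT_ORDERS, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.orders),):
            raise ContractError(f"expected {len(self.orders)} moments, got shape {v.shape}")
        if not np.all(v > 0):
            raise ContractError(f"moments must be positive, got {v}")
        if self.n_eff < MIN_N_EFF:
            raise ContractError(f"n_eff must be >= {MIN_N_EFF}, got {self.n_eff}")
        if self.n_eff > self.n_raw + 1e-9:
            raise ContractError(f"n_eff ({self.n_eff}) cannot exceed n_raw ({self.n_raw})")


@dataclass(frozen=True)
class MomentCovariance:
    """Symmetric positive-definite covariance of (m1, m3, m4, m5) under a null model."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-12, rtol=0):
            raise NumericalError("covariance matrix must be symmetric within 1e-12")
        if np.linalg.eigvalsh(m)[0] <= 0:
            raise NumericalError(
                "covariance matrix is singular or indefinite; the null model is degenerate"
            )


def normalize_envelope(samples) -> np.ndarray:
    """Scale amplitudes so the sample second moment is exactly one.

    Raises :class:`InvalidInputError` for fewer than two samples, negative
    amplitudes, or an all-zero input.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise InvalidInputError(f"need at least 2 samples, got {x.size}")
    if np.any(x < 0):
        raise InvalidInputError("amplitudes must be non-negative")
    msq = float(np.mean(x**2))
    if msq == 0.0:
        raise InvalidInputError("all-zero envelope cannot be normalized")
    return x / np.sqrt(msq)


def sample_moments(samples, n_eff: float, n_raw: int | None = None) -> MomentVector:
    """Raw moments of orders (1, 3, 4, 5) of an already-normalized sample.

    The sample second moment must equal one within 1e-6, otherwise a
    :class:`ContractError` is raised (normalize first with
    :func:`normalize_envelope`).
    """
    x = np.asarray(samples, dtype=float).ravel()
    msq = float(np.mean(x**2))
    if abs(msq - 1.0) > 1e-6:
        raise ContractError(f"input is not second-moment normalized (E[x^2] = {msq})")
    values = np.array([np.mean(x ** float(k)) for k in MOMENT_ORDERS])
    return MomentVector(values=values, n_eff=float(n_eff), n_raw=int(n_raw or x.size))


def _model_moment(model: MRAModel, order: float) -> float:
    # closed form extended to the even "helper" orders used by the covariance
    from scipy.special import gamma

    return float(
        sum(a * s ** (order / 2.0) for a, s in zip(model.rates, model.scales))
        * gamma(1.0 + order / 2.0)
    )


@lru_cache(maxsize=256)
def _unit_covariance(model: MRAModel, correction: bool) -> np.ndarray:
    """Covariance of the moment vector at n_eff = 1 (scales as 1/n_eff)."""
    o = np.array(MOMENT_ORDERS, dtype=float)
    p = len(o)
    mu = np.array([_model_moment(model, k) for k in o])
    cov = np.empty((p, p))
    for j in range(p):
        for k in range(j, p):
            cov[j, k] = cov[k, j] = _model_moment(model, o[j] + o[k]) - mu[j] * mu[k]
    if correction:
        mu2 = _model_moment(model, 2.0)
        c2 = np.array([_model_moment(model, oj + 2.0) - _model_moment(model, oj) * mu2 for oj in o])
        v2 = _model_moment(model, 4.0) - mu2**2
        for j in range(p):
            for k in range(j, p):  # upper triangle, mirrored for exact symmetry
                cov[j, k] += (
                    -(o[k] / 2.0) * mu[k] * c2[j]
                    - (o[j] / 2.0) * mu[j] * c2[k]
                    + (o[j] * o[k] / 4.0) * mu[j] * mu[k] * v2
                )
                cov[k, j] = cov[j, k]
    return cov


def moment_covariance(
    null_model: MRAModel, n_eff: float, *, normalization_correction: bool = True
) -> MomentCovariance:
    """Sampling covariance of (m1, m3, m4, m5) under a normalized null model.

    Entry (j, k) is ``(E[x^(oj+ok)] - E[x^oj] E[x^ok]) / n_eff`` with, by
    default, the delta-method correction for normalization by the sample
    second moment. All expectations come from the exact closed-form moments
    of the null model.
    """
    if n_eff < MIN_N_EFF:
        raise ContractError(f"n_eff must be >= {MIN_N_EFF}, got {n_eff}")
    return MomentCovariance(matrix=_unit_covariance(null_model, normalization_correction) / n_eff)


def mahalanobis_sq(m: MomentVector, null_model: MRAModel, cov: MomentCovariance | None = None) -> float:
    """Squared Mahalanobis distance of a moment vector from a null model.

    ``D^2 = (m - mu)^T Sigma^{-1} (m - mu)`` with ``mu`` the theoretical
    moments of ``null_model`` and ``Sigma`` its moment covariance at
    ``m.n_eff`` (unless an explicit covariance is supplied).
    """
    mu = np.array([theoretical_moment(null_model, k) for k in m.orders])
    if cov is None:
        cov = moment_covariance(null_model, m.n_eff)
    d = m.values - mu
    try:
        sol = np.linalg.solve(cov.matrix, d)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by MomentCovariance
        raise NumericalError(f"covariance inversion failed: {exc}") from exc
    return float(d @ sol)


def mahalanobis_sq_values(values: np.ndarray, null_model: MRAModel, n_eff: float) -> np.ndarray:
    """Vectorized D^2 for a stack of moment vectors (rows) under one null.

    Intended for simulation studies where thousands of ROIs share a common
    null model and effective sample count.
    """
    mu = np.array([theoretical_moment(null_model, k) for k in MOMENT_ORDERS])
    cinv = np.linalg.inv(_unit_covariance(null_model, True))
    d = np.atleast_2d(values) - mu
    return n_eff * np.einsum("ij,jk,ik->i", d, cinv, d)
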