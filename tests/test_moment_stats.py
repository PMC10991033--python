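"""Normalized sample moments, the delta-method covariance, and D^2."""

import numpy as np
import pytest

from envmra import (
    MOMENT_ORDERS,
    MRAModel,
    MomentVector,
    mahalanobis_sq,
    moment_covariance,
    normalize_envelope,
    sample_moments,
    theoretical_moments,
)
from envmra.moment_stats import mahalanobis_sq_values
from envmra.errors import ContractError, InvalidInputError


def _simulate_moment_vectors(rng, n_roi, n, model=None):
    """Moment vectors of n_roi independent normalized Rayleigh ROIs."""
    x = np.sqrt(rng.exponential(1.0, size=(n_roi, n)))
    x /= np.sqrt((x**2).mean(axis=1, keepdims=True))
    return np.stack([(x**k).mean(axis=1) for k in MOMENT_ORDERS], axis=1)


class TestNormalizeEnvelope:
    def test_already_normalized_input_unchanged(self):
        np.testing.assert_array_equal(normalize_envelope([1, 1, 1, 1]), [1, 1, 1, 1])

    def test_scaling(self):
        np.testing.assert_allclose(normalize_envelope([2, 2]), [1, 1])
        np.testing.assert_allclose(
            normalize_envelope([1, 2, 3]), np.array([1, 2, 3]) / np.sqrt(14 / 3)
        )

    def test_rejects_bad_input(self):
        with pytest.raises(InvalidInputError):
            normalize_envelope([0.0, 0.0])
        with pytest.raises(InvalidInputError):
            normalize_envelope([1.0, -1.0])
        with pytest.raises(InvalidInputError):
            normalize_envelope([1.0])


class TestSampleMoments:
    def test_constant_input(self):
        m = sample_moments(np.ones(100), n_eff=100)
        np.testing.assert_allclose(m.values, 1.0)

    def test_two_level_arithmetic(self):
        a, b = 0.6, np.sqrt(2 - 0.36)  # a^2 + b^2 = 2, already normalized
        m = sample_moments([a, b] * 4, n_eff=8)
        assert m.values[0] == pytest.approx((a + b) / 2)
        assert m.values[1] == pytest.approx((a**3 + b**3) / 2)

    def test_rejects_unnormalized_input(self):
        with pytest.raises(ContractError):
            sample_moments(np.full(50, 2.0), n_eff=50)

    def test_rejects_n_eff_above_raw_count(self):
        with pytest.raises(ContractError):
            MomentVector(values=np.ones(4), n_eff=100, n_raw=50)


class TestMomentCovariance:
    def test_scales_inversely_with_n_eff(self):
        ray = MRAModel.rayleigh()
        c1 = moment_covariance(ray, 500).matrix
        c2 = moment_covariance(ray, 1000).matrix
        np.testing.assert_allclose(c1, 2 * c2, rtol=1e-12)

    def test_symmetric(self, three_component_model):
        c = moment_covariance(three_component_model, 100).matrix
        np.testing.assert_array_equal(c, c.T)

    def test_matches_empirical_covariance(self, rng):
        # Monte-Carlo oracle: covariance of normalized Rayleigh ROI moments
        n, n_roi = 500, 8000
        emp = np.cov(_simulate_moment_vectors(rng, n_roi, n).T)
        pred = moment_covariance(MRAModel.rayleigh(), n).matrix
        np.testing.assert_allclose(emp, pred, rtol=0.15)

    def test_delta_correction_improves_null_calibration(self, rng):
        # the same simulated ROIs, scored with and without the
        # normalization correction: corrected type-I error must be closer
        # to the nominal 5%
        n, n_roi = 500, 4000
        vals = _simulate_moment_vectors(rng, n_roi, n)
        ray = MRAModel.rayleigh()
        mu = theoretical_moments(ray, MOMENT_ORDERS)
        rates = {}
        for corrected in (True, False):
            cinv = np.linalg.inv(
                moment_covariance(ray, n, normalization_correction=corrected).matrix
            )
            d = vals - mu
            d2 = np.einsum("ij,jk,ik->i", d, cinv, d)
            rates[corrected] = np.mean(d2 > 9.49)
        assert abs(rates[True] - 0.05) < abs(rates[False] - 0.05)


class TestMahalanobis:
    def test_zero_at_theoretical_moments(self, three_component_model):
        m = MomentVector(
            values=theoretical_moments(three_component_model, MOMENT_ORDERS),
            n_eff=500,
            n_raw=500,
        )
        assert mahalanobis_sq(m, three_component_model) == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_scaling(self):
        ray = MRAModel.rayleigh()
        mu = theoretical_moments(ray, MOMENT_ORDERS)
        step = np.array([0.01, 0.02, 0.03, 0.05])
        d_1 = mahalanobis_sq(MomentVector(mu + step, 500, 500), ray)
        d_2 = mahalanobis_sq(MomentVector(mu + 2 * step, 500, 500), ray)
        assert d_2 == pytest.approx(4 * d_1, rel=1e-9)

    def test_invariant_to_common_rescaling(self, rng):
        raw = rng.exponential(1.0, size=2000) ** 0.5 * 37.2
        ray = MRAModel.rayleigh()
        d2 = []
        for scale in (1.0, 0.01, 250.0):
            x = normalize_envelope(raw * scale)
            d2.append(mahalanobis_sq(sample_moments(x, n_eff=2000), ray))
        assert d2[0] == pytest.approx(d2[1], rel=1e-9) == pytest.approx(d2[2], rel=1e-9)

    def test_vectorized_matches_scalar(self, rng):
        vals = _simulate_moment_vectors(rng, 5, 300)
        ray = MRAModel.rayleigh()
        batch = mahalanobis_sq_values(vals, ray, 300)
        single = [mahalanobis_sq(MomentVector(v, 300, 300), ray) for v in vals]
        np.testing.assert_allclose(batch, single, rtol=1e-9)
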