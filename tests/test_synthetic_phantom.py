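"""Phantom generator: samplers, label maps, speckle statistics."""

import numpy as np
import pytest
from scipy.stats import kstest

from envmra import (
    MRAModel,
    make_label_map,
    sample_healthy_reference,
    sample_mra,
    sample_rician,
    simulate_envelope,
    simulate_frame,
)
from envmra.synthetic_phantom import (
    FatSpec,
    LABEL_CODES,
    NoduleSpec,
    StrandSpec,
    TissuePhantomSpec,
)
from envmra.errors import InvalidSpecError


class TestSamplers:
    def test_mean_square_matches_model_power(self):
        x = sample_mra(MRAModel.rayleigh(), 1_000_000, seed=0)
        # E[x^2]=1, Var(x^2)=1 for the unit Rayleigh
        assert abs(np.mean(x**2) - 1.0) < 4 / np.sqrt(1_000_000)

    def test_equal_scale_mixture_is_rayleigh(self):
        model = MRAModel(scales=(1.0, 1.0, 1.0), rates=(0.5, 0.5, 0.0))
        ps = []
        for seed in range(5):
            x = sample_mra(model, 20_000, seed)
            ps.append(kstest(x, "rayleigh", args=(0, np.sqrt(0.5))).pvalue)
        assert min(ps) > 0.01

    def test_seeded_streams_are_identical(self):
        a = sample_mra(MRAModel.rayleigh(), 1000, seed=42)
        b = sample_mra(MRAModel.rayleigh(), 1000, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_rician_reduces_to_rayleigh_at_zero_amplitude(self):
        x = sample_rician(0.0, 50_000, seed=1)
        assert kstest(x, "rayleigh", args=(0, np.sqrt(0.5))).pvalue > 0.01

    def test_healthy_reference_has_origin_mass(self):
        pts = sample_healthy_reference(2000, 5)
        at_origin = sum(p.theta == 0.0 and p.r == 0.0 for p in pts)
        assert 0.4 < at_origin / len(pts) < 0.6


class TestLabelMap:
    def test_plain_spec_is_all_parenchyma(self):
        labels = make_label_map(TissuePhantomSpec.healthy(), seed=0)
        assert np.all(labels == LABEL_CODES["M"])

    def test_fat_coverage_within_tolerance(self):
        spec = TissuePhantomSpec.fatty(coverage=0.3)
        labels = make_label_map(spec, seed=3)
        frac = np.mean(labels == LABEL_CODES["FAT"])
        assert 0.24 <= frac <= 0.36

    def test_strands_and_nodules_present(self):
        spec = TissuePhantomSpec(
            strands=StrandSpec(count=4), nodules=NoduleSpec(count=3, radius_mm=2.0)
        )
        labels = make_label_map(spec, seed=1)
        assert np.any(labels == LABEL_CODES["H"])
        assert np.any(labels == LABEL_CODES["L"])

    def test_seeded_determinism(self):
        spec = TissuePhantomSpec.fibrotic()
        np.testing.assert_array_equal(make_label_map(spec, 9), make_label_map(spec, 9))

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(InvalidSpecError):
            TissuePhantomSpec(nodules=NoduleSpec(count=1, radius_mm=100.0))


class TestSimulateEnvelope:
    def test_homogeneous_region_is_rayleigh_without_psf(self):
        spec = TissuePhantomSpec.healthy(psf_on=False)
        frame = simulate_envelope(make_label_map(spec, 0), spec, seed=0)
        x = frame.amplitudes.ravel()
        assert kstest(x, "rayleigh", args=(0, np.sqrt(0.5))).pvalue > 0.005

    def test_power_bookkeeping_per_class(self):
        spec = TissuePhantomSpec.fibrotic(psf_on=False)
        labels = make_label_map(spec, 4)
        frame = simulate_envelope(labels, spec, seed=4)
        intensity = frame.amplitudes**2
        m_power = intensity[labels == LABEL_CODES["M"]].mean()
        h_power = intensity[labels == LABEL_CODES["H"]].mean()
        assert m_power == pytest.approx(spec.powers[1], rel=0.05)
        assert h_power == pytest.approx(spec.powers[2], rel=0.05)

    def test_psf_correlates_neighbouring_pixels(self):
        spec = TissuePhantomSpec.healthy()
        frame = simulate_envelope(make_label_map(spec, 0), spec, seed=0)
        intensity = frame.amplitudes**2
        a, b = intensity[:-1, :].ravel(), intensity[1:, :].ravel()
        lag1 = np.corrcoef(a, b)[0, 1]
        assert lag1 > 0.5  # pixel pitch far below the pulse length

    def test_fat_region_has_coherent_moment_signature(self):
        from scipy.special import gamma

        spec = TissuePhantomSpec.fatty(coverage=0.5)
        for seed in (0, 1, 2):
            frame = simulate_frame(spec, seed)
            fat = frame.amplitudes[frame.labels == LABEL_CODES["FAT"]]
            x = fat / np.sqrt(np.mean(fat**2))
            assert np.mean(x) > np.sqrt(np.pi) / 2
            assert np.mean(x**3) < gamma(2.5)

    def test_quantization_limits_distinct_levels(self):
        spec = TissuePhantomSpec.healthy(quantize_8bit=True)
        frame = simulate_frame(spec, 2)
        assert len(np.unique(frame.amplitudes)) <= 256

    def test_end_to_end_determinism(self):
        a = simulate_frame(TissuePhantomSpec.fibrotic(), 77)
        b = simulate_frame(TissuePhantomSpec.fibrotic(), 77)
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_fibrosis_spreads_points_radially(self, healthy_frame, fibrotic_frame):
        # the qualitative parametric-plane trend: fibrotic phantoms reach
        # larger power-ratio radii than healthy ones
        from envmra import analyze_frame, frame_points

        rh = np.mean([p.r for p in frame_points(analyze_frame(healthy_frame)[0])])
        rf = np.mean([p.r for p in frame_points(analyze_frame(fibrotic_frame)[0])])
        assert rf > rh
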