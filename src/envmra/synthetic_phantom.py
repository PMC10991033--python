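"""Synthetic speckle phantoms with known tissue ground truth.

The generator emulates the envelope statistics of liver parenchyma the way
a speckle-physics simulation would at the resolution-cell scale, without
full acoustic propagation: each pixel carries a circular complex Gaussian
scatterer amplitude whose power is set by its tissue class, the complex
field is convolved with a Gaussian point-spread function, and the envelope
is the magnitude. This reproduces fully developed speckle (Rayleigh
envelope) in homogeneous regions, multi-Rayleigh mixtures where classes
mix within an ROI, and a controllable speckle correlation length.

Tissue classes
--------------
* ``M`` — normal parenchyma (background, reference power 1),
* ``L`` — hypoechoic nodules (discs, power < 1),
* ``H`` — fibrotic strands (curvilinear structures, power > 1),
* ``FAT`` — aggregated-lipid patches (blobs) that add a deterministic
  coherent phasor of magnitude ``A * sqrt(local power)`` to the diffuse
  field, giving a Rician envelope: the normalized first moment rises above
  and the third moment falls below the Rayleigh values, the non-MRA
  signature.

Defaults follow the analysis geometry: a 1.9 x 2.4 mm resolution cell
(axial x lateral), frames a few centimetres across, and class powers
{L: 0.25, M: 1, H: 6} giving a fibrosis-to-parenchyma power ratio of 6.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .envelope_model import MRAModel
from .errors import InvalidInputError, InvalidSpecError
from .roi_pipeline import EnvelopeFrame

__all__ = [
    "StrandSpec",
    "NoduleSpec",
    "FatSpec",
    "TissuePhantomSpec",
    "LABEL_CODES",
    "sample_mra",
    "sample_rician",
    "make_label_map",
    "simulate_envelope",
    "simulate_frame",
]

#: Integer codes of the tissue label raster.
LABEL_CODES = {"M": 0, "L": 1, "H": 2, "FAT": 3}


@dataclass(frozen=True)
class StrandSpec:
    """Fibrotic strands: connected curvilinear structures of class H."""

    count: int = 0
    width_mm: float = 0.8
    orientation_jitter: float = 0.35  # rad, per-step direction jitter


@dataclass(frozen=True)
class NoduleSpec:
    """Hypoechoic nodules: discs of class L."""

    count: int = 0
    radius_mm: float = 2.0


@dataclass(frozen=True)
class FatSpec:
    """Lipid-aggregate patches: blobs of class FAT with a coherent component."""

    coverage: float = 0.0  # requested area fraction of the frame
    amplitude_ratio: float = 2.0  # coherent amplitude A relative to local Rayleigh sigma
    # patches larger than the 5.7 x 7.2 mm ROI, so the non-MRA area fraction
    # can track coverage (regional lipid aggregation, not isolated droplets)
    blob_radius_mm: tuple[float, float] = (6.0, 10.0)


@dataclass(frozen=True)
class TissuePhantomSpec:
    frame_mm: tuple[float, float] = (30.0, 40.0)  # (depth, lateral)
    pixel_mm: tuple[float, float] = (0.15, 0.15)
    powers: tuple[float, float, float] = (0.25, 1.0, 6.0)  # (L, M, H) relative to M
    strands: StrandSpec = field(default_factory=StrandSpec)
    nodules: NoduleSpec = field(default_factory=NoduleSpec)
    fat: FatSpec = field(default_factory=FatSpec)
    psf_mm: tuple[float, float] = (1.9, 2.4)  # resolution cell (axial, lateral), FWHM
    psf_on: bool = True
    quantize_8bit: bool = False

    def __post_init__(self) -> None:
        if any(v <= 0 for v in (*self.frame_mm, *self.pixel_mm, *self.powers, *self.psf_mm)):
            raise InvalidSpecError("frame, pixel, power and PSF values must be positive")
        if not 0.0 <= self.fat.coverage <= 1.0:
            raise InvalidSpecError(f"fat coverage must lie in [0, 1], got {self.fat.coverage}")
        if self.strands.count and self.strands.width_mm >= min(self.frame_mm):
            raise InvalidSpecError("strand width does not fit in the frame")
        if self.nodules.count and 2 * self.nodules.radius_mm >= min(self.frame_mm):
            raise InvalidSpecError("nodule diameter does not fit in the frame")

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.frame_mm[0] / self.pixel_mm[0])),
            int(round(self.frame_mm[1] / self.pixel_mm[1])),
        )

    # convenience study conditions
    @classmethod
    def healthy(cls, **kw) -> "TissuePhantomSpec":
        """Homogeneous parenchyma: fully developed speckle only."""
        return cls(**kw)

    @classmethod
    def fibrotic(cls, strand_count: int = 10, **kw) -> "TissuePhantomSpec":
        """Parenchyma crossed by hyperechoic strands (power ratio 6)."""
        return cls(strands=StrandSpec(count=strand_count), **kw)

    @classmethod
    def fatty(cls, coverage: float = 0.3, amplitude_ratio: float = 2.0, **kw) -> "TissuePhantomSpec":
        """Parenchyma with coherent-component lipid patches."""
        return cls(fat=FatSpec(coverage=coverage, amplitude_ratio=amplitude_ratio), **kw)


# ---------------------------------------------------------------------------
# direct distribution samplers (unit-test oracles and ROI-level studies)
# ---------------------------------------------------------------------------


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_mra(model: MRAModel, n: int, seed) -> np.ndarray:
    """Draw envelope amplitudes from a multi-Rayleigh mixture.

    Each draw picks a component with probability ``alpha_c`` and then draws
    a Rayleigh amplitude with power ``sigma_c^2`` (square root of an
    exponential with that mean).
    """
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    rng = _rng(seed)
    comp = rng.choice(3, size=n, p=np.asarray(model.rates) / sum(model.rates))
    scale = np.asarray(model.scales)[comp]
    return np.sqrt(rng.exponential(scale))


def sample_healthy_reference(n: int, seed) -> list:
    """Fibrosis-parameter points emulating a healthy-liver reference scatter.

    Healthy parenchyma mostly yields Rayleigh-labelled ROIs (points at the
    origin of the polar fibrosis-parameter plane), with a minority of
    three-component fits carrying small spurious fibrotic rates and power
    ratios near one. Used to build and validate healthy-liver structure
    filters without a clinical reference cohort: half at the exact origin,
    half with ``alpha_H ~ Beta(1.2, 4)`` and ``r ~ Gamma(1.5, 0.7)``.
    """
    from .hlsf import FibrosisPoint

    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    rng = _rng(seed)
    at_origin = rng.random(n) < 0.5
    alpha_h = np.where(at_origin, 0.0, rng.beta(1.2, 4.0, size=n))
    r = np.where(at_origin, 0.0, rng.gamma(1.5, 0.7, size=n))
    return [FibrosisPoint(theta=2.0 * np.pi * a, r=float(ri)) for a, ri in zip(alpha_h, r)]


def sample_rician(a_over_sigma: float, n: int, seed, power: float = 1.0) -> np.ndarray:
    """Rician envelope: coherent phasor plus circular complex Gaussian.

    ``a_over_sigma`` is the coherent amplitude relative to the Rayleigh
    sigma of the diffuse part (which has total power ``power``);
    ``a_over_sigma = 0`` reduces to Rayleigh.
    """
    rng = _rng(seed)
    sigma = np.sqrt(power)
    z = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) * (sigma / np.sqrt(2.0))
    return np.abs(a_over_sigma * sigma + z)


# ---------------------------------------------------------------------------
# label maps
# ---------------------------------------------------------------------------


def _paint_disc(labels: np.ndarray, center_px, radius_px, code: int) -> None:
    rr, cc = np.ogrid[: labels.shape[0], : labels.shape[1]]
    d2 = ((rr - center_px[0]) / radius_px[0]) ** 2 + ((cc - center_px[1]) / radius_px[1]) ** 2
    labels[d2 <= 1.0] = code


def _paint_strand(labels: np.ndarray, spec: TissuePhantomSpec, rng: np.random.Generator) -> None:
    """One connected curvilinear H structure crossing the frame laterally."""
    rows, cols = labels.shape
    half_w = (
        0.5 * spec.strands.width_mm / spec.pixel_mm[0],
        0.5 * spec.strands.width_mm / spec.pixel_mm[1],
    )
    r = rng.uniform(0.1, 0.9) * rows
    angle = rng.uniform(-0.3, 0.3)
    step = max(1.0, half_w[1])
    c = 0.0
    while c < cols:
        _paint_disc(labels, (r, c), half_w, LABEL_CODES["H"])
        angle += rng.uniform(-spec.strands.orientation_jitter, spec.strands.orientation_jitter)
        angle = float(np.clip(angle, -1.0, 1.0))
        r += step * np.tan(angle)
        r = float(np.clip(r, 0, rows - 1))
        c += step


def make_label_map(spec: TissuePhantomSpec, seed) -> np.ndarray:
    """Tissue label raster over {M, L, H, FAT} for a phantom specification.

    Fat coverage is enforced to within +-20% of the request by rejection
    resampling of the blob layout; strand and nodule layouts are geometric
    (count, width/radius) and not coverage-constrained.
    """
    rng = _rng(seed)
    rows, cols = spec.shape
    labels = np.full((rows, cols), LABEL_CODES["M"], dtype=np.int8)
    for _ in range(spec.strands.count):
        _paint_strand(labels, spec, rng)
    rad_px = (spec.nodules.radius_mm / spec.pixel_mm[0], spec.nodules.radius_mm / spec.pixel_mm[1])
    for _ in range(spec.nodules.count):
        center = (rng.uniform(0, rows), rng.uniform(0, cols))
        _paint_disc(labels, center, rad_px, LABEL_CODES["L"])
    if spec.fat.coverage > 0:
        target = spec.fat.coverage
        for _attempt in range(20):
            trial = labels.copy()
            # place blobs on parenchyma until the requested coverage is reached
            for _ in range(10000):
                frac = np.mean(trial == LABEL_CODES["FAT"])
                if frac >= target:
                    break
                radius_mm = rng.uniform(*spec.fat.blob_radius_mm)
                rad = (radius_mm / spec.pixel_mm[0], radius_mm / spec.pixel_mm[1])
                center = (rng.uniform(0, rows), rng.uniform(0, cols))
                blob = np.zeros_like(trial, dtype=bool)
                rr, cc = np.ogrid[:rows, :cols]
                d2 = ((rr - center[0]) / rad[0]) ** 2 + ((cc - center[1]) / rad[1]) ** 2
                blob[d2 <= 1.0] = True
                trial[blob & (trial == LABEL_CODES["M"])] = LABEL_CODES["FAT"]
            frac = np.mean(trial == LABEL_CODES["FAT"])
            if abs(frac - target) <= 0.2 * target:
                labels = trial
                break
        else:
            raise InvalidSpecError(
                f"could not realize fat coverage {target} within +-20% "
                f"(too little parenchyma left?)"
            )
    return labels


# ---------------------------------------------------------------------------
# envelope simulation
# ---------------------------------------------------------------------------


def _psf_kernel(spec: TissuePhantomSpec) -> np.ndarray:
    """Unit-L2 Gaussian kernel so PSF convolution preserves stationary power."""
    sig_px = (
        spec.psf_mm[0] / 2.355 / spec.pixel_mm[0],
        spec.psf_mm[1] / 2.355 / spec.pixel_mm[1],
    )
    half = (int(np.ceil(3 * sig_px[0])), int(np.ceil(3 * sig_px[1])))
    r = np.arange(-half[0], half[0] + 1)[:, None]
    c = np.arange(-half[1], half[1] + 1)[None, :]
    k = np.exp(-0.5 * ((r / sig_px[0]) ** 2 + (c / sig_px[1]) ** 2))
    return k / np.sqrt(np.sum(k**2))


def simulate_envelope(label_map: np.ndarray, spec: TissuePhantomSpec, seed) -> EnvelopeFrame:
    """Envelope frame from a label map: diffuse field + coherent fat + PSF.

    Every pixel gets an independent circular complex Gaussian amplitude with
    power set by its class; FAT pixels additionally receive a deterministic
    coherent phasor of magnitude ``A * sqrt(local power)``. The complex
    field is convolved with the (unit-energy) Gaussian PSF, and the envelope
    is its magnitude, optionally quantized to 8 bits after max-scaling.
    """
    label_map = np.asarray(label_map)
    if label_map.shape != spec.shape:
        raise InvalidSpecError(
            f"label map shape {label_map.shape} does not match spec shape {spec.shape}"
        )
    rng = _rng(seed)
    power_of = {
        LABEL_CODES["L"]: spec.powers[0],
        LABEL_CODES["M"]: spec.powers[1],
        LABEL_CODES["H"]: spec.powers[2],
        LABEL_CODES["FAT"]: spec.powers[1],  # lipid patches sit in parenchyma
    }
    power = np.vectorize(power_of.get, otypes=[float])(label_map)
    amp = np.sqrt(power / 2.0)
    field = amp * (rng.standard_normal(label_map.shape) + 1j * rng.standard_normal(label_map.shape))
    if spec.psf_on:
        kernel = _psf_kernel(spec)
        field = fftconvolve(field.real, kernel, mode="same") + 1j * fftconvolve(
            field.imag, kernel, mode="same"
        )
    fat = label_map == LABEL_CODES["FAT"]
    if np.any(fat):
        # coherent lipid echo: added after the PSF acts on the diffuse field so
        # the local coherent-to-diffuse ratio A/sigma stays as specified (the
        # system gain on a spatially uniform coherent region is absorbed into A)
        field[fat] += spec.fat.amplitude_ratio * np.sqrt(power[fat])
    envelope = np.abs(field)
    if spec.quantize_8bit:
        peak = envelope.max()
        envelope = np.round(envelope / peak * 255.0) * (peak / 255.0)
    return EnvelopeFrame(
        amplitudes=envelope,
        spacing=spec.pixel_mm,
        labels=label_map,
        meta={"phantom_spec": asdict(spec), "seed": int(seed) if np.isscalar(seed) else None},
    )


def simulate_frame(spec: TissuePhantomSpec, seed: int) -> EnvelopeFrame:
    """Label map + envelope in one call, with sub-seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    s_label, s_field = ss.spawn(2)
    labels = make_label_map(spec, np.random.default_rng(s_label))
    frame = simulate_envelope(labels, spec, np.random.default_rng(s_field))
    frame.meta["seed"] = int(seed)
    return frame
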