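"""Frame-level analysis: ROI tiling, per-ROI decisions, parametric maps.

A frame of envelope amplitudes is tiled into ROIs of fixed *physical* size
(default 5.7 x 7.2 mm, three by three resolution cells), each ROI is
normalized and classified by the component-count flow, the two-component
tissue assignments are resolved against the neighbourhood normal-tissue
power in a second pass, and the frame is summarised by its non-MRA
fraction (steatosis index) and — given a healthy-liver filter — its
non-healthy area fraction (fibrosis index).

The effective number of independent samples per ROI is, by default,
derived from geometry: the ROI area divided by the speckle-cell (PSF)
area, because PSF convolution correlates neighbouring pixels and the
moment covariance must count independent speckle realisations, not
pixels. Set ``n_eff_policy="raw"`` for uncorrelated (pixel-iid) data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .component_select import ComponentDecision, Label, decide_from_moments, assign_two_component
from .config import AnalysisConfig
from .envelope_model import MRAModel
from .errors import (
    EnvMRAError,
    InvalidInputError,
    SchemaError,
    UndefinedMetricError,
)
from .hlsf import FibrosisPoint, HLSFEvaluation, HLSFilter, non_healthy_fraction, to_fibrosis_point
from .moment_stats import normalize_envelope, sample_moments

__all__ = [
    "EnvelopeFrame",
    "ROIWindow",
    "ROIResult",
    "FrameMetrics",
    "tile_rois",
    "effective_sample_count",
    "neighborhood_sigma_m",
    "analyze_frame",
    "frame_points",
    "results_table",
    "parametric_maps",
    "write_results",
    "write_frame",
    "read_frame",
]

log = logging.getLogger(__name__)


@dataclass
class EnvelopeFrame:
    """A 2-D envelope-amplitude raster with physical pixel spacing.

    Row 0 is the shallowest depth; ``spacing`` is (axial, lateral) in
    mm/pixel. ``labels`` is an optional same-shape ground-truth tissue map
    (synthetic frames only).
    """

    amplitudes: np.ndarray
    spacing: tuple[float, float]
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 2:
            raise InvalidInputError(f"amplitudes must be 2-D, got shape {self.amplitudes.shape}")
        if np.any(self.amplitudes < 0):
            raise InvalidInputError("amplitudes must be non-negative")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if any(s <= 0 for s in self.spacing):
            raise InvalidInputError(f"spacing must be positive, got {self.spacing}")
        if self.labels is not None and np.shape(self.labels) != self.amplitudes.shape:
            raise InvalidInputError("labels must match the amplitude raster shape")

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (
            self.amplitudes.shape[0] * self.spacing[0],
            self.amplitudes.shape[1] * self.spacing[1],
        )


@dataclass(frozen=True)
class ROIWindow:
    """One analysis window on the pixel grid, with its mm position."""

    grid_row: int
    grid_col: int
    row0: int
    col0: int
    n_rows: int
    n_cols: int
    depth_mm: float
    lateral_mm: float

    def slice(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.n_rows), slice(self.col0, self.col0 + self.n_cols))


@dataclass
class ROIResult:
    """Decision and fibrosis point of one ROI."""

    window: ROIWindow
    decision: ComponentDecision
    point: FibrosisPoint | None
    sigma_m_ref: float


@dataclass
class FrameMetrics:
    """Frame-level summary of the analysis.

    ``non_mra_fraction`` is the steatosis index (share of analyzed ROIs
    with the coherent-component signature); ``hlsf`` holds the non-healthy
    area fraction when a filter was supplied.
    """

    n_rois: int
    n_non_mra: int
    n_failed: int
    label_counts: dict
    hlsf: HLSFEvaluation | None = None

    @property
    def non_mra_fraction(self) -> float:
        return self.n_non_mra / self.n_rois

    @property
    def non_healthy_fraction(self) -> float | None:
        return None if self.hlsf is None else self.hlsf.fraction


def tile_rois(
    frame: EnvelopeFrame,
    roi_mm: tuple[float, float] = (5.7, 7.2),
    stride_fraction: float = 0.5,
    mask: np.ndarray | None = None,
) -> list[ROIWindow]:
    """Tile a frame into constant-physical-size windows.

    Windows are ``roi_mm`` (depth, lateral), stepped by
    ``stride_fraction * roi_mm``; partial windows at the frame edge are
    dropped. A boolean ``mask`` restricts analysis to windows lying
    entirely inside it (vessel exclusion is a user-supplied mask, not
    automated segmentation).
    """
    if any(v <= 0 for v in roi_mm) or stride_fraction <= 0:
        raise InvalidInputError("roi_mm and stride_fraction must be positive")
    rows, cols = frame.amplitudes.shape
    roi_px = (int(round(roi_mm[0] / frame.spacing[0])), int(round(roi_mm[1] / frame.spacing[1])))
    if roi_px[0] > rows or roi_px[1] > cols or roi_px[0] < 1 or roi_px[1] < 1:
        raise InvalidInputError(
            f"frame of {rows}x{cols} px cannot hold a {roi_px[0]}x{roi_px[1]} px ROI"
        )
    step = (max(1, int(round(stride_fraction * roi_px[0]))), max(1, int(round(stride_fraction * roi_px[1]))))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != frame.amplitudes.shape:
            raise InvalidInputError("mask must match the amplitude raster shape")
    windows = []
    for gi, r0 in enumerate(range(0, rows - roi_px[0] + 1, step[0])):
        for gj, c0 in enumerate(range(0, cols - roi_px[1] + 1, step[1])):
            if mask is not None and not mask[r0 : r0 + roi_px[0], c0 : c0 + roi_px[1]].all():
                continue
            windows.append(
                ROIWindow(
                    grid_row=gi,
                    grid_col=gj,
                    row0=r0,
                    col0=c0,
                    n_rows=roi_px[0],
                    n_cols=roi_px[1],
                    depth_mm=r0 * frame.spacing[0],
                    lateral_mm=c0 * frame.spacing[1],
                )
            )
    return windows


def effective_sample_count(
    window: ROIWindow, spacing: tuple[float, float], config: AnalysisConfig
) -> float:
    """Effective independent sample count of one ROI under the config policy.

    ``geometry``: ROI area divided by the speckle-cell area (pixel-size
    invariant), times the ``n_eff_scale`` calibration factor for the
    normalized-moment statistic; ``raw``: the pixel count (iid pixels).
    """
    if config.n_eff_policy == "raw":
        return float(window.n_rows * window.n_cols)
    roi_area = (window.n_rows * spacing[0]) * (window.n_cols * spacing[1])
    cell_area = config.speckle_cell_mm[0] * config.speckle_cell_mm[1]
    return config.n_eff_scale * roi_area / cell_area


def calibrate_n_eff_scale(
    frames, config: AnalysisConfig | None = None, quantile: float = 0.95
) -> float:
    """Calibrate the effective-sample-count scale on homogeneous speckle.

    Computes the one-component statistic D1 for every ROI of the given
    fully-developed-speckle frames at the *unscaled* geometric cell count,
    and returns the factor that maps its empirical ``quantile`` onto the
    chi-square decision threshold (D1 is linear in the effective count, so
    one quantile pins the scale). Matching at the threshold quantile makes
    the stage-1 rejection rate nominal at the decision point, which is what
    the component-count flow uses the covariance for.
    """
    from dataclasses import replace

    from .component_select import threshold_d1
    from .envelope_model import MRAModel
    from .moment_stats import mahalanobis_sq

    config = config or AnalysisConfig()
    unit = replace(config, n_eff_scale=1.0)
    d1s = []
    for frame in frames:
        for w in tile_rois(frame, config.roi_mm, config.stride_fraction):
            roi = frame.amplitudes[w.slice()]
            x = normalize_envelope(roi)
            m = sample_moments(x, n_eff=effective_sample_count(w, frame.spacing, unit), n_raw=roi.size)
            d1s.append(mahalanobis_sq(m, MRAModel.rayleigh()))
    if not d1s:
        raise UndefinedMetricError("no ROI available for calibration")
    thr = threshold_d1() if config.d1_threshold is None else config.d1_threshold
    return float(thr / np.quantile(d1s, quantile))


def _qualifying_sigma_m(result: ROIResult) -> float | None:
    # decisions that pin down the normal-tissue power: Rayleigh (power 1 by
    # normalization) and accepted 3-component fits (their sigma_M^2)
    if result.decision.label is Label.RAYLEIGH:
        return 1.0
    if result.decision.label is Label.MRA3:
        return result.decision.model.scales[1]
    return None


def neighborhood_sigma_m(results: dict, position: tuple[int, int]) -> float:
    """Median normal-tissue power over the 8-neighbourhood of a grid position.

    Falls back to the frame-global median over qualifying ROIs, then to 1.0
    (the normalized Rayleigh power) when no qualifying ROI exists.
    """
    gi, gj = position
    neigh = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            res = results.get((gi + di, gj + dj))
            if res is not None:
                s = _qualifying_sigma_m(res)
                if s is not None:
                    neigh.append(s)
    if neigh:
        return float(np.median(neigh))
    global_s = [s for res in results.values() if (s := _qualifying_sigma_m(res)) is not None]
    if global_s:
        return float(np.median(global_s))
    return 1.0


def _point_of(decision: ComponentDecision) -> FibrosisPoint | None:
    if decision.label is Label.NON_MRA:
        return None
    return to_fibrosis_point(decision.model)


def _reassign_two_component(result: ROIResult, sigma_m_ref: float) -> ROIResult:
    """Re-run the combination assignment of an MRA2 ROI against a new reference."""
    dec = result.decision
    model = dec.model
    if dec.label is Label.MRA2_LM:
        rate_lo, s_lo, s_hi = model.rates[0], model.scales[0], model.scales[1]
    else:
        rate_lo, s_lo, s_hi = model.rates[1], model.scales[1], model.scales[2]
    if s_lo >= s_hi:  # degenerate boundary fit collapsed to Rayleigh; nothing to assign
        return ROIResult(result.window, dec, result.point, sigma_m_ref)
    new_label = assign_two_component(s_lo, s_hi, sigma_m_ref)
    if new_label is dec.label:
        return ROIResult(result.window, dec, result.point, sigma_m_ref)
    combo = "LM" if new_label is Label.MRA2_LM else "MH"
    new_model = MRAModel.two_component(rate_lo, s_lo, s_hi, combination=combo)
    new_dec = ComponentDecision(label=new_label, d1=dec.d1, d2=dec.d2, model=new_model)
    return ROIResult(result.window, new_dec, _point_of(new_dec), sigma_m_ref)


def analyze_frame(
    frame: EnvelopeFrame,
    config: AnalysisConfig | None = None,
    hlsf_filter: HLSFilter | None = None,
    mask: np.ndarray | None = None,
) -> tuple[list[ROIResult], FrameMetrics]:
    """Classify every ROI of a frame and summarise it.

    Two passes: pass 1 computes provisional decisions with a unit
    normal-tissue reference power; pass 2 re-resolves the two-component
    tissue assignments using the median normal-tissue power of each ROI's
    8-neighbourhood from pass 1. Per-ROI failures are logged and excluded
    from both numerator and denominator of every fraction.
    """
    config = config or AnalysisConfig()
    amplitudes = frame.amplitudes
    if config.quantize_8bit and amplitudes.max() > 0:
        peak = amplitudes.max()
        amplitudes = np.round(amplitudes / peak * 255.0) * (peak / 255.0)
    windows = tile_rois(frame, config.roi_mm, config.stride_fraction, mask)
    if not windows:
        raise UndefinedMetricError("no analyzable ROI in the frame")

    by_pos: dict[tuple[int, int], ROIResult] = {}
    n_failed = 0
    for w in windows:
        n_eff = effective_sample_count(w, frame.spacing, config)
        roi = amplitudes[w.slice()]
        try:
            x = normalize_envelope(roi)
            m = sample_moments(x, n_eff=n_eff, n_raw=roi.size)
            dec = decide_from_moments(
                m,
                sigma_m_ref=1.0,
                d1_threshold=config.d1_threshold,
                d2_threshold=config.d2_threshold,
                grid=config.grid,
                eps=config.non_mra_eps,
            )
        except EnvMRAError as exc:
            log.warning("ROI (%d, %d) failed and is excluded: %s", w.grid_row, w.grid_col, exc)
            n_failed += 1
            continue
        by_pos[(w.grid_row, w.grid_col)] = ROIResult(w, dec, _point_of(dec), 1.0)

    for pos, res in list(by_pos.items()):
        if res.decision.label in (Label.MRA2_LM, Label.MRA2_MH):
            ref = neighborhood_sigma_m(by_pos, pos)
            by_pos[pos] = _reassign_two_component(res, ref)

    results = [by_pos[k] for k in sorted(by_pos)]
    if not results:
        raise UndefinedMetricError("all ROIs failed; frame metrics are undefined")
    label_counts: dict[str, int] = {}
    for res in results:
        label_counts[res.decision.label.value] = label_counts.get(res.decision.label.value, 0) + 1
    n_non_mra = label_counts.get(Label.NON_MRA.value, 0)
    hlsf_eval = None
    if hlsf_filter is not None:
        points = [res.point for res in results if res.point is not None]
        if points:
            hlsf_eval = non_healthy_fraction(hlsf_filter, points, config.density_floor)
    metrics = FrameMetrics(
        n_rois=len(results),
        n_non_mra=n_non_mra,
        n_failed=n_failed,
        label_counts=label_counts,
        hlsf=hlsf_eval,
    )
    return results, metrics


def frame_points(results: list[ROIResult]) -> list[FibrosisPoint]:
    """Fibrosis points of all ROIs not labelled non-MRA."""
    return [res.point for res in results if res.point is not None]


# ---------------------------------------------------------------------------
# results tables, maps, I/O
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "roi_row", "roi_col", "depth_mm", "lateral_mm", "label", "d1", "d2",
    "alpha_L", "alpha_M", "alpha_H", "sigma2_L", "sigma2_M", "sigma2_H",
    "sigma_m_ref", "theta", "r", "inside_hlsf",
]


def results_table(results: list[ROIResult], hlsf_filter: HLSFilter | None = None) -> pd.DataFrame:
    """One row per analyzed ROI with decision, parameters and fibrosis point."""
    from .hlsf import is_inside

    rows = []
    for res in results:
        model = res.decision.model
        point = res.point
        rows.append(
            {
                "roi_row": res.window.grid_row,
                "roi_col": res.window.grid_col,
                "depth_mm": res.window.depth_mm,
                "lateral_mm": res.window.lateral_mm,
                "label": res.decision.label.value,
                "d1": res.decision.d1,
                "d2": res.decision.d2,
                "alpha_L": model.rates[0],
                "alpha_M": model.rates[1],
                "alpha_H": model.rates[2],
                "sigma2_L": model.scales[0],
                "sigma2_M": model.scales[1],
                "sigma2_H": model.scales[2],
                "sigma_m_ref": res.sigma_m_ref,
                "theta": None if point is None else point.theta,
                "r": None if point is None else point.r,
                "inside_hlsf": (
                    None if (point is None or hlsf_filter is None) else is_inside(hlsf_filter, point)
                ),
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


_LABEL_CODE = {lab: i for i, lab in enumerate(Label)}


def parametric_maps(results: list[ROIResult]) -> dict[str, np.ndarray]:
    """Grid-shaped maps of alpha_H, the power ratio, and the decision label.

    Non-MRA ROIs carry NaN in the two fibrosis-parameter maps (they are
    excluded from MRA-parameter products); unanalyzed grid cells are NaN
    everywhere.
    """
    if not results:
        raise UndefinedMetricError("no results to map")
    n_r = max(res.window.grid_row for res in results) + 1
    n_c = max(res.window.grid_col for res in results) + 1
    alpha_h = np.full((n_r, n_c), np.nan)
    ratio = np.full((n_r, n_c), np.nan)
    labels = np.full((n_r, n_c), np.nan)
    for res in results:
        i, j = res.window.grid_row, res.window.grid_col
        labels[i, j] = _LABEL_CODE[res.decision.label]
        if res.decision.label is not Label.NON_MRA:
            alpha_h[i, j] = res.decision.model.rates[2]
            ratio[i, j] = res.decision.model.ratio_h_m
    return {"alpha_h": alpha_h, "power_ratio": ratio, "label": labels}


def write_results(
    results: list[ROIResult],
    metrics: FrameMetrics,
    out_dir,
    hlsf_filter: HLSFilter | None = None,
) -> None:
    """Write the results table, metrics JSON, and parametric maps (CSV + PNG)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_table(results, hlsf_filter).to_csv(out / "results.csv", index=False)
    payload = {
        "n_rois": metrics.n_rois,
        "n_failed": metrics.n_failed,
        "label_counts": metrics.label_counts,
        "non_mra_fraction": metrics.non_mra_fraction,
        "n_total": None if metrics.hlsf is None else metrics.hlsf.n_total,
        "n_outside": None if metrics.hlsf is None else metrics.hlsf.n_outside,
        "non_healthy_fraction": metrics.non_healthy_fraction,
    }
    (out / "metrics.json").write_text(json.dumps(payload, indent=1))
    maps = parametric_maps(results)
    for name, arr in maps.items():
        np.savetxt(out / f"{name}.csv", arr, delimiter=",", fmt="%.6g")
    _write_map_pngs(maps, out)


def _write_map_pngs(maps: dict[str, np.ndarray], out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    # fixed colour scales so maps are comparable across frames
    scales = {"alpha_h": (0.0, 1.0), "power_ratio": (1.0, 10.0), "label": (0, len(Label) - 1)}
    for name, arr in maps.items():
        vmin, vmax = scales[name]
        plt.imsave(out / f"{name}.png", np.nan_to_num(arr, nan=vmin), vmin=vmin, vmax=vmax, cmap="magma")


def write_frame(frame: EnvelopeFrame, stem) -> Path:
    """Write a frame as raw little-endian float32 plus a JSON sidecar.

    Returns the sidecar path. The raster round-trips bit-exactly; the
    optional ground-truth label map goes to an integer CSV next to it.
    """
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    bin_path = stem.with_suffix(".bin")
    frame.amplitudes.astype("<f4").tofile(bin_path)
    labels_name = None
    if frame.labels is not None:
        labels_name = stem.with_suffix(".labels.csv").name
        np.savetxt(stem.with_suffix(".labels.csv"), frame.labels, delimiter=",", fmt="%d")
    sidecar = {
        "rows": frame.amplitudes.shape[0],
        "cols": frame.amplitudes.shape[1],
        "axial_mm_per_px": frame.spacing[0],
        "lateral_mm_per_px": frame.spacing[1],
        "data_file": bin_path.name,
        "labels_file": labels_name,
        "meta": frame.meta,
    }
    side_path = stem.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar, indent=1, default=str))
    return side_path


def read_frame(path, spacing: tuple[float, float] | None = None) -> EnvelopeFrame:
    """Read a frame from a JSON sidecar (+ raw float32) or a bare CSV.

    For CSV input the pixel ``spacing`` must be supplied by the caller.
    """
    path = Path(path)
    if path.suffix == ".csv":
        if spacing is None:
            raise SchemaError("CSV frame input requires an explicit pixel spacing")
        return EnvelopeFrame(amplitudes=np.loadtxt(path, delimiter=","), spacing=spacing)
    if path.suffix == ".bin":
        path = path.with_suffix(".json")
    sidecar = json.loads(path.read_text())
    for field_name in ("rows", "cols", "axial_mm_per_px", "lateral_mm_per_px", "data_file"):
        if field_name not in sidecar:
            raise SchemaError(f"frame sidecar missing field {field_name!r}")
    raw = np.fromfile(path.parent / sidecar["data_file"], dtype="<f4")
    if raw.size != sidecar["rows"] * sidecar["cols"]:
        raise SchemaError(
            f"data file holds {raw.size} samples, sidecar promises "
            f"{sidecar['rows']}x{sidecar['cols']}"
        )
    labels = None
    if sidecar.get("labels_file"):
        labels = np.loadtxt(path.parent / sidecar["labels_file"], delimiter=",", dtype=int)
    return EnvelopeFrame(
        amplitudes=raw.reshape(sidecar["rows"], sidecar["cols"]).astype(float),
        spacing=(sidecar["axial_mm_per_px"], sidecar["lateral_mm_per_px"]),
        labels=labels,
        meta=sidecar.get("meta", {}),
    )
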