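"""Healthy-liver structure filter (HLSF) over the fibrosis-parameter plane.

The two fibrosis parameters of a fitted mixture — the fibrotic-tissue
mixture rate ``alpha_H`` and the echo power ratio ``sigma_H^2/sigma_M^2`` —
are mapped to polar coordinates

    theta = 2 pi alpha_H,        r = sigma_H^2 / sigma_M^2 - 1,

so that a healthy liver (little fibrosis, power ratio near one) clusters
near the origin. A reference set of healthy-liver ROIs is histogrammed on a
rectilinear grid of 0.5 x 0.5 cells in the cartesian (x, y) plane; the
smallest set of cells covering the top 90% of the reference probability
mass, taken in descending density order, is the filter. The share of an
examination's points falling outside the filter is its non-healthy area
fraction, the fibrosis index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .envelope_model import MRAModel
from .errors import InvalidInputError, InvalidParameterError, SchemaError, UndefinedMetricError

__all__ = [
    "FibrosisPoint",
    "HLSFilter",
    "HLSFEvaluation",
    "to_fibrosis_point",
    "build_hlsf",
    "is_inside",
    "non_healthy_fraction",
]

SCHEMA_TAG = "envmra.hlsf/1"


@dataclass(frozen=True)
class FibrosisPoint:
    """A fitted ROI in the polar fibrosis-parameter plane."""

    theta: float
    r: float

    @property
    def x(self) -> float:
        return self.r * np.cos(self.theta)

    @property
    def y(self) -> float:
        return self.r * np.sin(self.theta)


def to_fibrosis_point(model: MRAModel) -> FibrosisPoint:
    """Map a fitted mixture to (theta, r) = (2 pi alpha_H, sigma_H^2/sigma_M^2 - 1).

    Models without a fibrosis component (``alpha_H = 0``) map to the origin
    by convention; they carry no power-ratio information.
    """
    if not (model.scales[1] > 0):
        raise InvalidParameterError("sigma_M^2 must be positive")
    alpha_h = model.rates[2]
    if alpha_h == 0.0:
        return FibrosisPoint(theta=0.0, r=0.0)
    return FibrosisPoint(theta=2.0 * np.pi * alpha_h, r=model.ratio_h_m - 1.0)


def _cell_indices(points, cell_size: float) -> np.ndarray:
    """Half-open cell [k*s, (k+1)*s) containing each point's (x, y)."""
    xy = np.array([[p.x, p.y] for p in points], dtype=float).reshape(-1, 2)
    return np.floor(xy / cell_size + 1e-9).astype(int)


@dataclass(frozen=True)
class HLSFilter:
    """The set of grid cells covering the top probability mass of healthy livers.

    Attributes
    ----------
    cell_size : float
        Grid spacing in the cartesian fibrosis-parameter plane.
    mass : float
        Target covered probability (0.90 by default).
    cells : frozenset of (int, int)
        Cell indices belonging to the filter.
    density : dict
        Per-cell reference probability, over *all* occupied cells.
    n_reference : int
        Number of reference ROIs the filter was built from.
    """

    cell_size: float
    mass: float
    cells: frozenset
    density: dict
    n_reference: int

    def covered_mass(self) -> float:
        """Reference probability mass inside the filter (>= mass by construction)."""
        return float(sum(self.density[c] for c in self.cells))

    # -- serialization ----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "schema": SCHEMA_TAG,
            "cell_size": self.cell_size,
            "mass": self.mass,
            "n_reference": self.n_reference,
            "cells": sorted([i, j, self.density[(i, j)]] for (i, j) in self.density),
            "filter_cells": sorted([i, j] for (i, j) in self.cells),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "HLSFilter":
        payload = json.loads(Path(path).read_text())
        for field_name in ("schema", "cell_size", "mass", "n_reference", "cells", "filter_cells"):
            if field_name not in payload:
                raise SchemaError(f"HLSF file missing field {field_name!r}")
        if payload["schema"] != SCHEMA_TAG:
            raise SchemaError(f"unsupported HLSF schema {payload['schema']!r}")
        density = {(int(i), int(j)): float(d) for i, j, d in payload["cells"]}
        cells = frozenset((int(i), int(j)) for i, j in payload["filter_cells"])
        return cls(
            cell_size=float(payload["cell_size"]),
            mass=float(payload["mass"]),
            cells=cells,
            density=density,
            n_reference=int(payload["n_reference"]),
        )


def build_hlsf(reference_points, cell_size: float = 0.5, mass: float = 0.90) -> HLSFilter:
    """Build the filter from healthy-liver reference fibrosis points.

    Bins the cartesian coordinates into ``cell_size`` squares anchored at
    the origin (half-open), converts counts to a probability density, and
    greedily accumulates cells in descending density order (ties broken by
    cell index) until the covered mass reaches ``mass``.
    """
    points = list(reference_points)
    if not points:
        raise InvalidInputError("reference set is empty")
    if len(points) < 100:
        warnings.warn(
            f"only {len(points)} reference points; the filter density will be coarse",
            stacklevel=2,
        )
    idx = _cell_indices(points, cell_size)
    cells_arr, counts = np.unique(idx, axis=0, return_counts=True)
    density = {
        (int(i), int(j)): float(c) / len(points) for (i, j), c in zip(cells_arr, counts)
    }
    ordered = sorted(density.items(), key=lambda kv: (-kv[1], kv[0]))
    selected = []
    cum = 0.0
    for cell, d in ordered:
        selected.append(cell)
        cum += d
        if cum >= mass - 1e-12:
            break
    return HLSFilter(
        cell_size=float(cell_size),
        mass=float(mass),
        cells=frozenset(selected),
        density=density,
        n_reference=len(points),
    )


def is_inside(hlsf: HLSFilter, point: FibrosisPoint) -> bool:
    """Whether the cell containing the point belongs to the filter."""
    (i, j) = map(int, _cell_indices([point], hlsf.cell_size)[0])
    return (i, j) in hlsf.cells


@dataclass(frozen=True)
class HLSFEvaluation:
    """Non-healthy area fraction of one examination's fibrosis points."""

    n_total: int
    n_outside: int

    @property
    def fraction(self) -> float:
        return self.n_outside / self.n_total


def non_healthy_fraction(
    hlsf: HLSFilter, points, density_floor: float = 0.001
) -> HLSFEvaluation:
    """Fraction of points outside the filter, after a low-density exclusion.

    The evaluated sample's own per-cell density is computed on the filter
    grid; points in cells of sample density strictly below ``density_floor``
    are removed from both numerator and denominator (isolated outliers do
    not count as tissue evidence). Raises
    :class:`UndefinedMetricError` when nothing survives the exclusion.
    """
    points = list(points)
    if not points:
        raise UndefinedMetricError("no fibrosis points to evaluate")
    idx = _cell_indices(points, hlsf.cell_size)
    cells_arr, inverse, counts = np.unique(idx, axis=0, return_inverse=True, return_counts=True)
    sample_density = counts / len(points)
    keep = sample_density[inverse] >= density_floor
    if not np.any(keep):
        raise UndefinedMetricError("all points excluded by the density floor")
    kept_cells = idx[keep]
    inside = np.array([(int(i), int(j)) in hlsf.cells for i, j in kept_cells])
    n_total = int(keep.sum())
    return HLSFEvaluation(n_total=n_total, n_outside=int(n_total - inside.sum()))
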