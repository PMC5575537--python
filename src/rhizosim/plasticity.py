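"""Root growth plasticity: reaction norms on local soil conditions.

A reaction norm maps a locally sensed scalar (nutrient concentration, soil
compaction, ...) to a multiplier on one behaviour: branching density,
elongation rate or gravitropism strength.  Only absolute local values are
sensed — no gradients or tensors.  Scattered environmental data are
interpolated in 3D by inverse-distance weighting; grid-backed fields
(solutes, water) interpolate trilinearly.  A second, whole-plant reaction
norm can scale the strength of the local response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["SpatialField", "GridField", "ReactionNorm",
           "local_value", "apply_norm"]


class SpatialField:
    """Scattered 3D data points with inverse-distance-weighted interpolation.

    Exact at the data points; IDW power 2 over the k nearest neighbours
    (default 8) elsewhere.
    """

    def __init__(self, points: np.ndarray, values: np.ndarray,
                 power: float = 2.0, k: int = 8):
        self.points = np.atleast_2d(np.asarray(points, dtype=float))
        self.values = np.asarray(values, dtype=float)
        if len(self.points) == 0:
            raise ValueError("spatial field needs at least one data point")
        if len(self.points) != len(self.values):
            raise ValueError("points and values length mismatch")
        self.power = power
        self.k = min(k, len(self.points))
        self._tree = cKDTree(self.points)

    def __call__(self, p) -> float:
        d, i = self._tree.query(np.asarray(p, dtype=float), k=self.k)
        d = np.atleast_1d(d)
        i = np.atleast_1d(i)
        if d[0] < 1e-12 or len(i) == 1:
            return float(self.values[i[0]])
        w = d ** (-self.power)
        return float(np.sum(w * self.values[i]) / np.sum(w))


class GridField:
    """Trilinear interpolation of a cell-centred soil-grid array."""

    def __init__(self, grid, values: np.ndarray):
        from scipy.interpolate import RegularGridInterpolator
        self.grid = grid
        xs = (np.arange(grid.nx) - grid.nx / 2.0 + 0.5) * grid.dx
        ys = (np.arange(grid.ny) - grid.ny / 2.0 + 0.5) * grid.dy
        zs = grid.z_centers()[::-1]
        self._interp = RegularGridInterpolator(
            (xs, ys, zs), np.asarray(values, dtype=float)[:, :, ::-1],
            bounds_error=False, fill_value=None)

    def __call__(self, p) -> float:
        return float(self._interp(np.asarray(p, dtype=float))[0])


def local_value(field, p) -> float:
    """Environmental scalar at a 3D point (root surface position)."""
    return field(p)


@dataclass
class ReactionNorm:
    """Piecewise-linear response of one behaviour to a local scalar.

    ``target`` names what the multiplier scales: ``branch_spacing`` (the
    spacing is divided by the multiplier, so multiplier > 1 means denser
    branching), ``elongation`` or ``gravitropism_weight``.  Values outside
    the curve's domain clamp to the end multipliers.  An optional strength
    modulator — another curve on a whole-plant variable — scales the
    response multiplicatively.
    """
    curve: Sequence[tuple[float, float]]
    target: str = "branch_spacing"
    strength_modulator: Sequence[tuple[float, float]] | None = None

    def __post_init__(self):
        if any(m < 0 for _, m in self.curve):
            raise ValueError("reaction norm multipliers must be >= 0")
        if self.target not in ("branch_spacing", "elongation",
                               "gravitropism_weight"):
            raise ValueError(f"unknown plasticity target {self.target!r}")


def apply_norm(norm: ReactionNorm, local: float,
               plant_value: float | None = None) -> float:
    """Multiplier for the norm's target given the locally sensed value."""
    xs = [p[0] for p in norm.curve]
    ys = [p[1] for p in norm.curve]
    m = float(np.interp(local, xs, ys))
    if norm.strength_modulator is not None and plant_value is not None:
        sx = [p[0] for p in norm.strength_modulator]
        sy = [p[1] for p in norm.strength_modulator]
        s = float(np.interp(plant_value, sx, sy))
        m = 1.0 + (m - 1.0) * s
    return m
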