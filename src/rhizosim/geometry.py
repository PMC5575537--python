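"""Geometric phenotype descriptors of a grown root system.

All metrics clip segment *chords* (straight lines between vertices) against
bins, cylinders or planes, then scale the clipped chord length by the
segment's grown-to-chord length ratio, so that totals always refer to true
root length and the depth profile sums exactly to the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CoreSpec", "depth_profile", "virtual_core", "d90_depth",
           "class_totals", "depletion_zone_overlap"]


@dataclass
class CoreSpec:
    """A virtual soil core: vertical cylinder at center_xy with a radius,
    optionally restricted to a depth range (z values, negative down)."""
    center_xy: tuple[float, float] = (0.0, 0.0)
    radius: float = 2.5
    depth_range: tuple[float, float] | None = None   # (z_top, z_bottom)

    def validate(self):
        if self.radius <= 0:
            raise ValueError("core radius must be > 0")


def _segment_chords(rs, include_tip=True):
    for seg in rs.iter_segments(include_tip=include_tip):
        a, b = seg.head.position, seg.tail.position
        chord = float(np.linalg.norm(b - a))
        ratio = seg.grown_length / chord if chord > 1e-12 else 0.0
        yield seg, a, b, chord, ratio


def depth_profile(rs, bin_size: float, reference_area: float | None = None
                  ) -> dict:
    """Root length (and optionally RLD) per depth bin.

    Each chord is split pro rata across the depth bins it crosses and its
    share scaled back to grown length, so the bins sum to the total root
    length exactly.  Bin i covers z in [-(i+1)*bin, -i*bin).

    Returns dict with ``edges`` (bin top depths), ``length`` (cm per bin)
    and ``rld`` (cm/cm^3) when a reference area (cm^2) is given.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be > 0")
    lengths: dict[int, float] = {}
    point_mass = 0.0
    for seg, a, b, chord, ratio in _segment_chords(rs):
        if chord <= 1e-12:
            point_mass += seg.grown_length
            continue
        z0, z1 = a[2], b[2]
        lo_bin = int(math.floor(-max(z0, z1) / bin_size))
        hi_bin = int(math.floor(-min(z0, z1) / bin_size + 1e-12))
        if abs(z1 - z0) < 1e-12:
            i = int(math.floor(-z0 / bin_size))
            lengths[i] = lengths.get(i, 0.0) + seg.grown_length
            continue
        for i in range(max(lo_bin, 0), hi_bin + 1):
            top, bot = -i * bin_size, -(i + 1) * bin_size
            zc0 = min(max(min(z0, z1), bot), top)
            zc1 = min(max(max(z0, z1), bot), top)
            frac = (zc1 - zc0) / abs(z1 - z0)
            if frac > 0:
                lengths[i] = lengths.get(i, 0.0) + frac * seg.grown_length
    if point_mass > 0:
        lengths[0] = lengths.get(0, 0.0) + point_mass
    if not lengths:
        return {"edges": np.array([]), "length": np.array([]), "rld": None}
    n = max(lengths) + 1
    L = np.zeros(n)
    for i, v in lengths.items():
        if i >= 0:
            L[i] = v
    edges = -np.arange(n) * bin_size
    rld = None
    if reference_area is not None:
        rld = L / (reference_area * bin_size)
    return {"edges": edges, "length": L, "rld": rld}


def virtual_core(rs, core: CoreSpec) -> float:
    """Root length inside a vertical cylinder (true length, cm)."""
    core.validate()
    cx, cy = core.center_xy
    r2 = core.radius ** 2
    total = 0.0
    for seg, a, b, chord, ratio in _segment_chords(rs):
        if chord <= 1e-12:
            if (a[0] - cx) ** 2 + (a[1] - cy) ** 2 <= r2:
                total += seg.grown_length
            continue
        # clip the chord to the infinite vertical cylinder: solve the
        # quadratic for the xy-projection entering/leaving the circle
        d = b - a
        px, py = a[0] - cx, a[1] - cy
        A = d[0] ** 2 + d[1] ** 2
        B = 2.0 * (px * d[0] + py * d[1])
        C = px * px + py * py - r2
        if A < 1e-16:
            inside = C <= 0
            t0, t1 = (0.0, 1.0) if inside else (0.0, 0.0)
        else:
            disc = B * B - 4 * A * C
            if disc <= 0:
                continue
            s = math.sqrt(disc)
            t0 = max(0.0, (-B - s) / (2 * A))
            t1 = min(1.0, (-B + s) / (2 * A))
            if t1 <= t0:
                continue
        if core.depth_range is not None:
            z_top, z_bot = max(core.depth_range), min(core.depth_range)
            if abs(d[2]) > 1e-15:
                tz0 = (z_bot - a[2]) / d[2]
                tz1 = (z_top - a[2]) / d[2]
                tz0, tz1 = min(tz0, tz1), max(tz0, tz1)
                t0, t1 = max(t0, tz0), min(t1, tz1)
            elif not (z_bot <= a[2] <= z_top):
                continue
            if t1 <= t0:
                continue
        total += (t1 - t0) * chord * ratio
    return total


def d90_depth(rs, bin_size: float = 0.1) -> tuple[float, float]:
    """Depth above which 90% of the total root length lies.

    Returns (depth cm, length below that depth cm).  Interpolates linearly
    within the bin where the cumulative length crosses 90%.
    """
    prof = depth_profile(rs, bin_size)
    L = prof["length"]
    total = float(L.sum())
    if total <= 0:
        raise ValueError("empty root system")
    target = 0.9 * total
    cum = np.cumsum(L)
    i = int(np.searchsorted(cum, target))
    prev = cum[i - 1] if i > 0 else 0.0
    frac = (target - prev) / L[i] if L[i] > 0 else 0.0
    depth = -(i + frac) * bin_size
    return depth, total - target


def class_totals(rs) -> dict[str, dict[str, float]]:
    """Per-class total length, lateral surface area and volume."""
    out: dict[str, dict[str, float]] = {}
    for seg in rs.iter_segments(include_tip=True):
        d = out.setdefault(seg.root_class,
                           {"length": 0.0, "surface_area": 0.0, "volume": 0.0})
        d["length"] += seg.grown_length
        d["surface_area"] += seg.surface_area()
        d["volume"] += seg.volume()
    return out


def depletion_zone_overlap(rs, rx: float) -> float:
    """Fraction of segments whose depletion annulus (radius rx around the
    segment midpoint) intersects a neighbour's.  A coarse pairwise metric
    on segment midpoints, intended as a relative indicator only."""
    mids = np.array([s.midpoint for s in rs.iter_segments()])
    if len(mids) < 2:
        return 0.0
    from scipy.spatial import cKDTree
    tree = cKDTree(mids)
    pairs = tree.query_pairs(2.0 * rx)
    touched = set()
    for i, j in pairs:
        touched.add(i)
        touched.add(j)
    return len(touched) / len(mids)
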