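"""Shoot carbon economy: fixation, costs, labile pool and allocation.

The shoot is non-geometric: leaf area plus leaf and stem dry weight.
Carbon fixation follows a radiation-use-efficiency model — intercepted
light, computed from the leaf area index through Beer's law, converts
linearly to fixed carbon — assuming a homogeneous canopy of identical,
equally spaced plants.  Fixed carbon minus maintenance costs feeds organ
growth; a surplus fills a labile (non-structural) pool, a deficit drains
it, and once the pool is empty an allocation rule decides who is cut:
either a priority waterfall (shoot first, then root thickening, then main
axes, branch roots last) or uniform proportional scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ShootState", "CarbonPools", "CanopyParams", "CostParams",
    "fix_carbon", "sink_strength", "allocate", "grow_shoot",
    "allometric_cap", "carbon_costs", "segment_growth_demand",
]

#: default carbon fraction of dry weight, g C per g DW
C_FRACTION = 0.40


def _interp(table: Sequence[tuple[float, float]], x: float) -> float:
    xs = [p[0] for p in table]
    ys = [p[1] for p in table]
    return float(np.interp(x, xs, ys))


@dataclass
class ShootState:
    leaf_area: float = 0.0            # cm^2
    leaf_dw: float = 0.0              # g
    stem_dw: float = 0.0              # g
    potential_leaf_area: float = 0.0  # cm^2, the unstressed track
    sla: Sequence[tuple[float, float]] = ((0.0, 200.0),)   # d -> cm^2/g
    dw_per_C: float = 1.0 / C_FRACTION                     # g DW per g C

    def validate(self):
        if min(self.leaf_area, self.leaf_dw, self.stem_dw) < 0:
            raise ValueError("shoot pools must be >= 0")


@dataclass
class CarbonPools:
    labile: float = 0.0        # g C
    seed_reserve: float = 0.0  # g C remaining
    fixed_today: float = 0.0   # g C/d

    def validate(self):
        if self.labile < -1e-12:
            raise ValueError("labile pool went negative")


@dataclass
class CanopyParams:
    rue: float = 2.5            # g C per MJ intercepted
    k_ext: float = 0.65         # canopy extinction coefficient
    plant_density: float = 10.0  # plants per m^2
    # time d -> (leaf, stem, root) fractions, each row sums to 1
    partitioning: Sequence[tuple[float, tuple[float, float, float]]] = (
        (0.0, (0.5, 0.2, 0.3)),)

    def fractions(self, t: float) -> tuple[float, float, float]:
        ts = [p[0] for p in self.partitioning]
        rows = np.array([p[1] for p in self.partitioning], dtype=float)
        out = tuple(float(np.interp(t, ts, rows[:, i])) for i in range(3))
        s = sum(out)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"partitioning fractions sum to {s}, not 1")
        return out


@dataclass
class CostParams:
    # per root class: age d -> g C per cm^3 living volume per d
    respiration: dict[str, Sequence[tuple[float, float]]] = field(default_factory=dict)
    # per root class: age d -> g C per cm root per d
    exudation: dict[str, Sequence[tuple[float, float]]] = field(default_factory=dict)
    nitrate_uptake_cost: float = 0.0   # g C per umol N taken up from soil


def fix_carbon(shoot: ShootState, canopy: CanopyParams, light: float,
               photosynthesis_stress: float = 1.0) -> float:
    """Daily carbon fixation (g C/d) of one plant.

    LAI = leaf area x plant density (cm^2 -> m^2); the intercepted fraction
    is 1 - exp(-k LAI); interception times RUE and incident light, divided
    by plant density, is the per-plant fixation, scaled by the nutrient
    stress factor on photosynthesis.
    """
    if light < 0:
        raise ValueError("light must be >= 0")
    lai = shoot.leaf_area * canopy.plant_density / 1.0e4
    intercepted = 1.0 - math.exp(-canopy.k_ext * lai)
    return canopy.rue * light * intercepted / canopy.plant_density \
        * photosynthesis_stress


def segment_growth_demand(delta_volume: float, specific_root_volume: float,
                          c_fraction: float = C_FRACTION) -> float:
    """Carbon demand (g C) of a volumetric increase of one root segment."""
    return delta_volume * specific_root_volume * c_fraction


def sink_strength(organ_demands: dict[str, float],
                  maintenance: float = 0.0) -> float:
    """Total potential carbon demand: sum of organ growth demands plus
    maintenance costs (g C)."""
    if any(d < -1e-15 for d in organ_demands.values()):
        raise ValueError("negative organ demand")
    return sum(organ_demands.values()) + maintenance


#: waterfall order of the priority allocation rule
PRIORITY_ORDER = ("shoot", "secondary_growth", "main_axes", "branch_roots")


def allocate(pools: CarbonPools, source: float, sinks: dict[str, float],
             rule: str = "priority",
             order: Sequence[str] = PRIORITY_ORDER) -> dict[str, float]:
    """Split available carbon among sink classes; update the labile pool.

    When source + labile covers the total demand, every sink is satisfied
    and the surplus is stored.  Otherwise the labile pool drains to zero
    and the rule applies: ``priority`` fills classes in the stated order
    (the class where the money runs out is scaled pro rata, later classes
    get nothing); ``proportional`` scales every class by the same factor.
    """
    if source < 0:
        raise ValueError("source must be >= 0")
    if any(v < 0 for v in sinks.values()):
        raise ValueError("demands must be >= 0")
    demand = sum(sinks.values())
    available = source + pools.labile
    out: dict[str, float] = {}
    if available >= demand:
        out = dict(sinks)
        pools.labile = available - demand
    else:
        pools.labile = 0.0
        if rule == "proportional":
            f = available / demand if demand > 0 else 0.0
            out = {k: v * f for k, v in sinks.items()}
        elif rule == "priority":
            remaining = available
            for k in order:
                d = sinks.get(k, 0.0)
                a = min(d, remaining)
                out[k] = a
                remaining -= a
            for k in sinks:
                out.setdefault(k, 0.0)
        else:
            raise ValueError(f"unknown allocation rule {rule!r}")
    if any(v < -1e-12 for v in out.values()):
        raise AssertionError("internal error: negative allocation")
    return out


def grow_shoot(shoot: ShootState, allocation: float, t: float,
               canopy: CanopyParams) -> None:
    """Convert allocated carbon into leaf/stem dry weight and leaf area."""
    if allocation < 0:
        raise ValueError("allocation must be >= 0")
    f_leaf, f_stem, f_root = canopy.fractions(t)
    shoot_frac = f_leaf + f_stem
    if shoot_frac <= 0:
        return
    ddw = allocation * shoot.dw_per_C
    d_leaf = ddw * f_leaf / shoot_frac
    d_stem = ddw * f_stem / shoot_frac
    shoot.leaf_dw += d_leaf
    shoot.stem_dw += d_stem
    shoot.leaf_area += d_leaf * _interp(shoot.sla, t)


def allometric_cap(shoot: ShootState, recovery_rate: float = 0.1) -> float:
    """Growth multiplier from the actual-to-potential leaf-area ratio.

    A stressed plant (ratio < 1) grows proportionally slower and forms
    branches more slowly; the recovery rate bounds how much faster than the
    potential track it may grow once resources return (0 means stress is
    never fully recovered from).
    """
    if shoot.potential_leaf_area <= 0:
        raise ValueError("potential_leaf_area must be > 0")
    ratio = shoot.leaf_area / shoot.potential_leaf_area
    return min(1.0 + recovery_rate, ratio)


def carbon_costs(segments, costs: CostParams, t: float, dt: float,
                 nitrate_uptake: float = 0.0) -> dict[str, float]:
    """Maintenance costs over dt: respiration on living segment volume,
    exudation per root length, and the nitrate uptake cost (all g C)."""
    from .architecture import anatomy_modifiers
    resp = 0.0
    exud = 0.0
    for seg in segments:
        cls = seg.root_class
        mods = anatomy_modifiers(seg.anatomy)
        if cls in costs.respiration:
            rate = _interp(costs.respiration[cls], seg.age(t))
            resp += rate * seg.volume() * mods["living_volume_fraction"] * dt
        if cls in costs.exudation:
            rate = _interp(costs.exudation[cls], seg.age(t))
            exud += rate * seg.grown_length * dt
    return {
        "respiration": resp,
        "exudation": exud,
        "nitrate_uptake_cost": costs.nitrate_uptake_cost * nitrate_uptake,
    }


def release_seed_reserve(pools: CarbonPools, t: float, dt: float,
                         total: float, duration: float = 7.0) -> float:
    """Linear release of the seed carbon reserve over the first days."""
    if total <= 0 or t >= duration:
        return 0.0
    rate = total / duration
    release = min(pools.seed_reserve, rate * min(dt, duration - t))
    pools.seed_reserve -= release
    return release
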