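"""Multi-solute nutrient dynamics.

Each nutrient is simulated independently: a plant-side budget (requirement,
content, satisfaction) coupled to a soil-side supply model chosen by
mobility.  Immobile nutrients (P, K) use a radial one-dimensional
depletion-zone model around every root segment: convection-diffusion in a
buffered annulus with Michaelis-Menten uptake at the root surface and a
zero-flux outer boundary at half the inter-root distance.  Mobile nutrients
(nitrate) use a whole-domain convection-dispersion-diffusion solver on the
soil grid, fed by the water fluxes of the hydrology module and by
node-level mineralization.

Shortfalls relative to the optimal requirement translate into per-process
stress multipliers (photosynthesis, leaf expansion, root elongation, ...)
through response curves, aggregated over nutrients by a maximum-stress or
averaging rule.

Units: concentrations umol/cm^3 solution, amounts umol, lengths cm,
time days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NutrientSpec", "RadialProfile", "SoluteField", "MineralizationPool",
    "PlantNutrientState", "mm_flux", "barber_cushman_step",
    "grid_solute_step", "mineralize_step", "requirements", "stress_factors",
    "fixation", "exude",
]


@dataclass
class NutrientSpec:
    """Uptake kinetics, plant demand curves and stress responses."""
    name: str
    mobility: str = "barber_cushman"   # or "grid_solute"
    Imax: float = 1.0e-3               # umol/cm^2/d
    Km: float = 5.0e-3                 # umol/cm^3
    Cmin: float = 0.0                  # umol/cm^3, uptake cutoff
    optimal_conc: Sequence[tuple[float, float]] = ((0.0, 100.0),)  # d -> umol/g DW
    minimal_conc: Sequence[tuple[float, float]] = ((0.0, 50.0),)
    # process name -> piecewise-linear curve (satisfaction -> multiplier)
    stress_responses: dict[str, Sequence[tuple[float, float]]] = field(
        default_factory=dict)

    def validate(self):
        if self.Imax <= 0 or self.Km <= 0:
            raise ValueError("Imax and Km must be > 0")


def mm_flux(C_surface: float, spec: NutrientSpec, area: float,
            uptake_area_multiplier: float = 1.0) -> float:
    """Michaelis-Menten uptake rate (umol/d) at a root surface.

    The effective concentration is reduced by the cutoff Cmin below which
    uptake stops; root hairs and anatomy enter through the area multiplier.
    """
    spec.validate()
    if C_surface < 0:
        C_surface = 0.0
    c = max(0.0, C_surface - spec.Cmin)
    return spec.Imax * c / (spec.Km + c) * area * uptake_area_multiplier


# ---------------------------------------------------------------------------
# radial depletion model (immobile nutrients)

class RadialProfile:
    """Radial solute profile in the annulus r0..rx around one segment.

    Finite volumes on log-spaced radii; concentrations are per cm^3 of
    solution, the buffer power b relates total to solution concentration.
    All amounts are per cm of root length.
    """

    def __init__(self, r0: float, rx: float, C_init: float,
                 b: float = 10.0, De: float = 1e-3, v0: float = 0.0,
                 n_nodes: int = 20):
        if not 0 < r0 < rx:
            raise ValueError("need 0 < r0 < rx")
        self.r0, self.rx = float(r0), float(rx)
        self.b = float(b)
        self.De = float(De)
        self.v0 = float(v0)       # inward water flux at the root surface, cm/d
        self.faces = np.geomspace(r0, rx, n_nodes + 1)
        self.centers = np.sqrt(self.faces[:-1] * self.faces[1:])
        self.volumes = math.pi * (self.faces[1:] ** 2 - self.faces[:-1] ** 2)
        self.C = np.full(n_nodes, float(C_init))
        self.cumulative_uptake = 0.0   # umol per cm root length
        self.insoluble = 0.0           # umol/cm, solubilisable pool

    def mass(self) -> float:
        """Total solute in the annulus, umol per cm root (buffered)."""
        return float(np.sum(self.b * self.C * self.volumes))

    def surface_concentration(self) -> float:
        """Concentration at the root surface r0, extrapolated in log r from
        the innermost two cells (clamped at zero)."""
        if len(self.C) < 2:
            return float(self.C[0])
        c0, c1 = self.centers[0], self.centers[1]
        slope = (self.C[1] - self.C[0]) / math.log(c1 / c0)
        return max(0.0, float(self.C[0] + slope * math.log(self.r0 / c0)))


def barber_cushman_step(profile: RadialProfile, spec: NutrientSpec,
                        dt: float, uptake_area_multiplier: float = 1.0,
                        _depth: int = 0) -> float:
    """Advance the radial profile by dt; returns uptake (umol/cm root).

    Interior transport (diffusion through the buffered solution plus the
    inward convective drag of root water uptake) is Crank-Nicolson; the
    Michaelis-Menten surface uptake is applied explicitly, which makes the
    discrete mass balance close to solver precision.  A step producing
    negative concentrations is halved and retried.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n = len(profile.C)
    C0 = profile.C
    b, De, v0, r0 = profile.b, profile.De, profile.v0, profile.r0
    V = profile.volumes * b
    f = profile.faces

    # Flux-consistent surface concentration: the diffusive (+ convective)
    # transport through the inner half-cell must equal the Michaelis-Menten
    # uptake at r0.  Solved by a few Newton steps on the scalar balance;
    # the uptake itself stays explicit in the start-of-step state, which
    # keeps the discrete mass balance exact.
    area_per_cm = 2.0 * math.pi * r0
    g = area_per_cm * De * b / (profile.centers[0] - r0)  # umol/cm/d per conc
    conv = area_per_cm * v0
    cs = C0[0]
    for _ in range(20):
        up = mm_flux(cs, spec, area_per_cm, uptake_area_multiplier)
        bal = g * (C0[0] - cs) + conv * cs - up
        c_eff = max(0.0, cs - spec.Cmin)
        dup = spec.Imax * spec.Km / (spec.Km + c_eff) ** 2 \
            * area_per_cm * uptake_area_multiplier if c_eff > 0 else 0.0
        dbal = -g + conv - dup
        step = bal / dbal
        cs_new = min(max(cs - step, 0.0), max(C0[0], 0.0))
        if abs(cs_new - cs) < 1e-14:
            cs = cs_new
            break
        cs = cs_new
    uptake_rate = mm_flux(cs, spec, area_per_cm, uptake_area_multiplier)
    # linearized implicit boundary: uptake = alpha * C0_new, with alpha the
    # chord of the Michaelis-Menten curve at the current surface state —
    # unconditionally stable, and the discrete mass balance stays exact
    # because the same alpha*C0_new term is both removed from cell 0 and
    # credited as uptake
    alpha = uptake_rate / C0[0] if C0[0] > 1e-30 else 0.0

    # interior face transport operator: inward flux at face j (1..n-1)
    #   G_j = 2 pi f_j De b dC/dr + 2 pi v0 r0 C_upwind
    # tridiagonal operator L with dM_i/dt = (L C)_i; cached on the profile
    cache = getattr(profile, "_op_cache", None)
    if cache is not None and cache[0] == (De, v0, b):
        lo, di, up = cache[1]
    else:
        lo = np.zeros(n)   # L[i, i-1]
        di = np.zeros(n)   # L[i, i]
        up = np.zeros(n)   # L[i, i+1]
        dr = np.diff(profile.centers)
        g_d = 2.0 * math.pi * f[1:n] * De * b / dr
        # diffusive inward flux at face j = g_d * (C_j - C_{j-1})
        up[:-1] += g_d
        di[:-1] -= g_d
        di[1:] -= g_d
        lo[1:] += g_d
        if v0 != 0.0:
            g_c = 2.0 * math.pi * v0 * r0
            # water flows inward (v0 > 0): upwind cell is the outer one
            if v0 > 0:
                up[:-1] += g_c
                di[1:] -= g_c
            else:
                di[:-1] += g_c
                lo[1:] -= g_c
        profile._op_cache = ((De, v0, b), (lo, di, up))

    # Crank-Nicolson interior, implicit boundary:
    # (V/dt - L/2 + alpha e0 e0^T) C1 = (V/dt + L/2) C0
    Vd = V / dt
    rhs = Vd * C0 + 0.5 * (np.roll(C0, 1) * lo + C0 * di
                           + np.roll(C0, -1) * up)
    ab_cache = getattr(profile, "_ab_cache", None)
    if ab_cache is not None and ab_cache[0] == (De, v0, b, dt):
        ab = ab_cache[1].copy()
    else:
        ab = np.zeros((3, n))
        ab[0, 1:] = -0.5 * up[:-1]
        ab[1, :] = Vd - 0.5 * di
        ab[2, :-1] = -0.5 * lo[1:]
        profile._ab_cache = ((De, v0, b, dt), ab.copy())
    ab[1, 0] += alpha
    from scipy.linalg import solve_banded
    C1 = solve_banded((1, 1), ab, rhs)
    uptake_rate = alpha * float(C1[0])
    if np.any(C1 < -1e-12):
        if _depth > 12:
            raise RuntimeError(
                "radial depletion step kept producing negative concentrations")
        u = barber_cushman_step(profile, spec, dt / 2, uptake_area_multiplier,
                                _depth + 1)
        u += barber_cushman_step(profile, spec, dt / 2, uptake_area_multiplier,
                                 _depth + 1)
        return u
    profile.C = np.maximum(C1, 0.0)
    uptake = uptake_rate * dt
    profile.cumulative_uptake += uptake
    return uptake


def outer_radius_from_rld(rld: float) -> float:
    """Half inter-root distance from local root length density (cm/cm^3)."""
    if rld <= 0:
        raise ValueError("root length density must be > 0")
    return (math.pi * rld) ** -0.5


def effective_diffusion(D0: float, theta: float, theta_s: float,
                        b: float) -> float:
    """Effective diffusion in soil: free-water D0 times the water content
    and a tortuosity factor, divided by the buffer power."""
    tortuosity = theta ** (7.0 / 3.0) / theta_s ** 2
    return D0 * theta * tortuosity / b


# ---------------------------------------------------------------------------
# grid solute model (mobile nutrients)

class SoluteField:
    """Solution concentration per soil cell plus transport parameters."""

    def __init__(self, grid, C_init: float = 1.0, D0: float = 1.0,
                 dispersivity: float = 0.5, adsorption: float = 0.0):
        self.grid = grid
        self.C = np.full((grid.nx, grid.ny, grid.nz), float(C_init))
        self.D0 = float(D0)               # cm^2/d in free water
        self.dispersivity = float(dispersivity)  # cm
        self.adsorption = float(adsorption)      # linear buffer, adds to theta

    def total_mass(self) -> float:
        g = self.grid
        return float(np.sum((g.theta + self.adsorption) * self.C)) * g.cell_volume


def grid_solute_step(field: SoluteField, water_fluxes: dict | None,
                     uptake_sinks: np.ndarray | None,
                     source_terms: np.ndarray | None, dt: float) -> float:
    """Explicit upwind finite-volume convection + diffusion over dt.

    ``water_fluxes`` are the face Darcy fluxes (cm^3/d) from the Richards
    step; ``uptake_sinks`` (umol/d per cell) and ``source_terms``
    (umol/cm^3 solution/d) modify the budget.  The step sub-cycles to
    respect the Courant limit.  Returns total uptake removed (umol).
    """
    g = field.grid
    vol = g.cell_volume
    storage = (g.theta + field.adsorption) * vol           # cm^3 water equiv.
    theta_s = g.vg.theta_s
    removed = 0.0

    # stability limit from advection and diffusion
    max_q = 0.0
    if water_fluxes:
        for a in water_fluxes.values():
            if a.size:
                max_q = max(max_q, float(np.max(np.abs(a))))
    theta_f = float(np.min(g.theta))
    D_eff = field.D0 * theta_f ** (7.0 / 3.0) / theta_s ** 2 \
        + field.dispersivity * max_q / vol * min(g.dx, g.dy, g.dz)
    dt_adv = 0.25 * float(np.min(storage)) / max_q if max_q > 0 else np.inf
    dmin = min(g.dx, g.dy, g.dz)
    dt_dif = 0.25 * dmin * dmin * theta_f / D_eff if D_eff > 0 else np.inf
    n_sub = max(1, int(math.ceil(dt / min(dt_adv, dt_dif, dt))))
    sub = dt / n_sub

    for _ in range(n_sub):
        M = (g.theta + field.adsorption) * field.C * vol  # umol per cell
        dM = np.zeros_like(M)
        for axis, d, key in ((0, g.dx, "x"), (1, g.dy, "y"), (2, g.dz, "z")):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(0, -1)
            sl_hi[axis] = slice(1, None)
            sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
            C_lo, C_hi = field.C[sl_lo], field.C[sl_hi]
            # advection: upwind in the direction of the water flux
            if water_fluxes is not None and key in water_fluxes:
                Q = water_fluxes[key]          # cm^3/d, positive toward hi
                adv = np.where(Q >= 0, Q * C_lo, Q * C_hi)
            else:
                adv = 0.0
            theta_face = 0.5 * (g.theta[sl_lo] + g.theta[sl_hi])
            q_face = np.abs(Q) / (vol / d) if water_fluxes is not None \
                and key in water_fluxes else 0.0
            De = field.D0 * theta_face ** (7.0 / 3.0) / theta_s ** 2 \
                + field.dispersivity * q_face
            dif = De * theta_face * (vol / d) * (C_hi - C_lo) / d
            F = adv - dif                      # umol/d toward hi
            dM[sl_lo] -= F * sub
            dM[sl_hi] += F * sub
        if source_terms is not None:
            dM += source_terms * g.theta * vol * sub
        if uptake_sinks is not None:
            take = np.minimum(uptake_sinks * sub, np.maximum(M + dM, 0.0))
            dM -= take
            removed += float(take.sum())
        M_new = M + dM
        field.C = M_new / ((g.theta + field.adsorption) * vol)
        field.C = np.maximum(field.C, 0.0)
    return removed


# ---------------------------------------------------------------------------
# mineralization

@dataclass
class MineralizationPool:
    """Decomposing organic-matter pool at one soil node.

    The relative decomposition rate declines with substrate age,
    k(t) = k1 * t^(-S); the net mineral N released per unit of decomposed C
    follows from the C:N ratios of substrate and microbial biomass and the
    assimilation efficiency (negative values mean immobilization).  Soil
    moisture and temperature are ignored.
    """
    C_substrate: float = 1.0e-3   # g C/cm^3
    CN_substrate: float = 15.0
    CN_microbial: float = 10.0
    k1: float = 0.02              # 1/d at t = 1 d
    S: float = 0.5                # aging exponent
    e: float = 0.45               # microbial assimilation efficiency
    age: float = 0.0              # d since substrate deposition
    #: umol N per g N
    _UMOL_PER_G_N = 1.0e6 / 14.0


def mineralize_step(pool: MineralizationPool, dt: float,
                    t: float | None = None) -> float:
    """Decompose over dt; returns the net mineral N source (umol/cm^3).

    The aging rate k(t) = k1 t^(-S) is integrated exactly over the step
    (it is singular at t = 0, so stepwise evaluation would depend on dt):
    C(t) = C(0) exp(-k1 t^(1-S) / (1-S)).  Positive values feed the
    nitrate pool (ammonium is taken to nitrify immediately); negative
    values are an immobilization sink.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    a0 = pool.age if t is None else max(t - dt, 0.0)
    a1 = a0 + dt
    if pool.S == 1.0:
        k_int = pool.k1 * math.log(max(a1, 1e-12) / max(a0, 1e-12))
    else:
        p = 1.0 - pool.S
        k_int = pool.k1 / p * (a1 ** p - a0 ** p)
    dC = pool.C_substrate * (1.0 - math.exp(-k_int))
    pool.C_substrate -= dC
    pool.age = a1
    net_N_g = dC * (1.0 / pool.CN_substrate - pool.e / pool.CN_microbial)
    return net_N_g * pool._UMOL_PER_G_N


# ---------------------------------------------------------------------------
# plant-side budget

@dataclass
class PlantNutrientState:
    content: float = 0.0               # umol, incl. seed reserve released
    requirement_optimal: float = 0.0   # umol
    requirement_minimal: float = 0.0   # umol
    fixation_fraction: float = 0.0     # N only
    satisfaction: float = 1.0

    def update_satisfaction(self) -> float:
        if self.requirement_optimal <= 0:
            self.satisfaction = 1.0
        else:
            self.satisfaction = min(
                1.0, self.content / self.requirement_optimal)
        return self.satisfaction


def requirements(organ_dw: dict[str, float], spec: NutrientSpec, t: float,
                 root_content_multiplier: float = 1.0) -> dict[str, float]:
    """Optimal and minimal whole-plant requirements (umol).

    Integrates predefined concentration targets over organ dry weights;
    cortical senescence/aerenchyma lowers the root contribution through the
    anatomy nutrient-content multiplier.
    """
    def conc(table):
        xs = [p[0] for p in table]
        ys = [p[1] for p in table]
        return float(np.interp(t, xs, ys))

    copt, cmin = conc(spec.optimal_conc), conc(spec.minimal_conc)
    opt = mini = 0.0
    for organ, dw in organ_dw.items():
        m = root_content_multiplier if organ.startswith("root") else 1.0
        opt += dw * copt * m
        mini += dw * cmin * m
    return {"optimal": opt, "minimal": mini}


DEFAULT_STRESS_PROCESSES = (
    "photosynthesis", "leaf_expansion", "respiration",
    "root_elongation", "secondary_growth",
)


def _curve(table: Sequence[tuple[float, float]], x: float) -> float:
    xs = [p[0] for p in table]
    ys = [p[1] for p in table]
    return float(np.interp(x, xs, ys))


def stress_factors(states: dict[str, PlantNutrientState],
                   specs: dict[str, NutrientSpec],
                   aggregation: str = "max",
                   processes: Sequence[str] = DEFAULT_STRESS_PROCESSES
                   ) -> dict[str, float]:
    """Per-process growth multipliers aggregated over nutrients.

    Each nutrient maps its satisfaction through its per-process response
    curve (default: multiplier equals satisfaction, clamped to [0, 1]);
    ``max`` aggregation takes the strongest stress (smallest multiplier),
    ``mean`` averages.  All organs experience the same stress.
    """
    out: dict[str, float] = {}
    for proc in processes:
        vals = []
        for name, st in states.items():
            spec = specs[name]
            if proc in spec.stress_responses:
                m = _curve(spec.stress_responses[proc], st.satisfaction)
            else:
                m = min(1.0, max(0.0, st.satisfaction))
            vals.append(m)
        if not vals:
            out[proc] = 1.0
        elif aggregation == "max":
            out[proc] = min(vals)
        elif aggregation == "mean":
            out[proc] = float(np.mean(vals))
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
    return out


def fixation(state: PlantNutrientState) -> float:
    """Credit biological N fixation as a fraction of the optimal requirement.

    The credit improves plant N status without reducing soil uptake.
    """
    if not 0.0 <= state.fixation_fraction <= 1.0:
        raise ValueError("fixation fraction must be in [0, 1]")
    credit = state.fixation_fraction * state.requirement_optimal
    state.content += credit
    return credit


def exude(profile: RadialProfile, rate: float, dt: float) -> float:
    """Solubilize nutrient from the insoluble pool into the radial profile.

    Transfers ``rate`` (umol/cm root/d) from the insoluble fraction into
    the solution of the innermost cells; total mass is conserved.  Returns
    the amount moved (umol/cm).
    """
    if rate <= 0 or dt <= 0:
        return 0.0
    moved = min(rate * dt, profile.insoluble)
    profile.insoluble -= moved
    # deposit into the innermost cell's solution
    profile.C[0] += moved / (profile.b * profile.volumes[0])
    return moved
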