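"""Soil water, xylem transport and evapotranspiration.

One water step couples three models:

1. Penman-Monteith evapotranspiration splits the atmospheric demand into a
   potential transpiration (canopy-covered fraction) and potential soil
   evaporation.
2. A linear hydraulic network over the root graph distributes the collar
   flux over the root system: each segment conducts axially (xylem) and
   exchanges radially with the soil at its location.  Radial flow may
   reverse (hydraulic lift) where the soil is drier than the xylem.
3. The Richards equation, solved in mixed form with modified Picard
   iteration on a regular finite-volume lattice, moves water through the
   soil with the root radial fluxes as sinks and evaporation as a
   supply-limited top boundary flux.

Units: lengths and heads in cm, time in days, fluxes in cm^3/d.
z points up; the soil surface is z = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "VanGenuchten", "SoilGrid", "XylemNetwork", "Weather",
    "van_genuchten", "richards_step", "xylem_solve", "penman_monteith",
    "water_step", "build_xylem_network",
]

#: permitted minimum collar water potential (total head, cm); wilting point
MIN_COLLAR_POTENTIAL = -15000.0
#: internal sub-step ceiling of the water model, days
WATER_MAX_DT = 0.05


@dataclass
class VanGenuchten:
    """van Genuchten-Mualem soil hydraulic parameters."""
    theta_r: float = 0.05
    theta_s: float = 0.45
    alpha: float = 0.02   # 1/cm
    n: float = 1.8
    Ks: float = 50.0      # cm/d

    def validate(self):
        if self.n <= 1:
            raise ValueError("van Genuchten n must be > 1")
        if not self.theta_r < self.theta_s:
            raise ValueError("theta_r must be < theta_s")


def van_genuchten(h, vg: VanGenuchten):
    """Water content and conductivity from pressure head (cm).

    Saturated (h >= 0) soil returns (theta_s, Ks); otherwise the closed-form
    retention curve with m = 1 - 1/n and Mualem conductivity.
    """
    vg.validate()
    h = np.asarray(h, dtype=float)
    m = 1.0 - 1.0 / vg.n
    ah = np.abs(vg.alpha * h)
    se = np.where(h < 0, (1.0 + ah ** vg.n) ** (-m), 1.0)
    theta = vg.theta_r + (vg.theta_s - vg.theta_r) * se
    K = vg.Ks * np.sqrt(se) * (1.0 - (1.0 - se ** (1.0 / m)) ** m) ** 2
    K = np.maximum(K, 1e-30)
    return theta, K


def _capacity(h, vg: VanGenuchten):
    """Specific moisture capacity dtheta/dh (1/cm), analytic."""
    h = np.asarray(h, dtype=float)
    m = 1.0 - 1.0 / vg.n
    ah = np.abs(vg.alpha * h)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (vg.theta_s - vg.theta_r) * m * vg.n * vg.alpha * ah ** (vg.n - 1.0) \
            * (1.0 + ah ** vg.n) ** (-m - 1.0)
    return np.where(h < 0, c, 0.0)


class SoilGrid:
    """Regular hexahedral lattice of soil cells.

    Arrays are indexed ``[ix, iy, iz]`` with iz = 0 the top layer; cell
    centres sit at z = -(iz + 1/2) dz.  Side and bottom boundaries are
    closed (no flux), so a domain with zero top flux conserves mass exactly.
    """

    def __init__(self, nx: int, ny: int, nz: int,
                 dx: float = 5.0, dy: float = 5.0, dz: float = 5.0,
                 vg: VanGenuchten | None = None,
                 h_init: float | np.ndarray = -100.0):
        self.nx, self.ny, self.nz = nx, ny, nz
        self.dx, self.dy, self.dz = float(dx), float(dy), float(dz)
        self.vg = vg if vg is not None else VanGenuchten()
        self.h = np.broadcast_to(np.asarray(h_init, dtype=float),
                                 (nx, ny, nz)).copy()
        self.theta, _ = van_genuchten(self.h, self.vg)
        self.sink = np.zeros((nx, ny, nz))  # cm^3/d extracted per cell

    @property
    def cell_volume(self) -> float:
        return self.dx * self.dy * self.dz

    def z_centers(self) -> np.ndarray:
        return -(np.arange(self.nz) + 0.5) * self.dz

    def cell_of(self, p: np.ndarray) -> tuple[int, int, int]:
        """Containing cell of a point; x, y fold into the domain
        periodically (the lattice represents one plant's share of a
        homogeneous stand), z clips to the profile."""
        ix = int(np.floor(p[0] / self.dx + self.nx / 2.0)) % self.nx
        iy = int(np.floor(p[1] / self.dy + self.ny / 2.0)) % self.ny
        iz = min(self.nz - 1, max(0, int(np.floor(-p[2] / self.dz))))
        return ix, iy, iz

    def water_volume(self) -> float:
        return float(self.theta.sum()) * self.cell_volume


def richards_step(grid: SoilGrid, sinks: np.ndarray | None,
                  top_flux_bc: float, dt: float,
                  picard_tol: float = 1e-8, max_picard: int = 60,
                  return_fluxes: bool = False):
    """Advance soil water by dt using mixed-form modified Picard iteration.

    ``sinks`` (cm^3/d per cell, positive = extraction) come from the xylem
    solve; ``top_flux_bc`` (cm/d, positive = infiltration) applies uniformly
    to the top layer.  The hydraulic driving force is the total head h + z,
    so a hydrostatic profile is a fixed point to machine precision.  On
    non-convergence the step halves recursively.

    Returns the boundary volume added (cm^3); with ``return_fluxes`` also a
    dict of face Darcy fluxes for solute convection.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    nx, ny, nz = grid.nx, grid.ny, grid.nz
    ncell = nx * ny * nz
    vg = grid.vg
    vol = grid.cell_volume
    if sinks is None:
        sinks = np.zeros((nx, ny, nz))
    z = np.broadcast_to(grid.z_centers(), (nx, ny, nz))

    h_old = grid.h.copy()
    theta_old = grid.theta.copy()
    h_m = h_old.copy()

    def idx(ix, iy, iz):
        return (ix * ny + iy) * nz + iz

    II = np.arange(ncell).reshape(nx, ny, nz)
    top_area = grid.dx * grid.dy

    for it in range(max_picard):
        theta_m, K_m = van_genuchten(h_m, vg)
        C_m = _capacity(h_m, vg)
        # face conductivities: arithmetic mean of the adjacent cells
        rows, cols, vals = [], [], []
        diag = C_m.ravel() * vol / dt
        rhs = (C_m * h_m / dt - (theta_m - theta_old) / dt).ravel() * vol
        rhs -= sinks.ravel()
        rhs[II[:, :, 0].ravel()] += top_flux_bc * top_area

        def add_faces(axis, d):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(0, -1)
            sl_hi[axis] = slice(1, None)
            sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
            Kf = 0.5 * (K_m[sl_lo] + K_m[sl_hi])
            area = vol / d
            g = (Kf * area / d).ravel()
            i_lo = II[sl_lo].ravel()
            i_hi = II[sl_hi].ravel()
            # flux_lo<-hi = g * (H_hi - H_lo); H = h + z
            rows.extend([i_lo, i_lo, i_hi, i_hi])
            cols.extend([i_lo, i_hi, i_hi, i_lo])
            vals.extend([g, -g, g, -g])
            # gravity part of the driving force goes to the RHS
            dz_term = g * (z[sl_hi].ravel() - z[sl_lo].ravel())
            np.add.at(rhs, i_lo, dz_term)
            np.add.at(rhs, i_hi, -dz_term)

        add_faces(0, grid.dx)
        add_faces(1, grid.dy)
        add_faces(2, grid.dz)

        rows = np.concatenate([np.arange(ncell)] + rows)
        cols = np.concatenate([np.arange(ncell)] + cols)
        vals = np.concatenate([diag] + vals)
        A = sp.csr_matrix((vals, (rows, cols)), shape=(ncell, ncell))
        h_new = spla.spsolve(A, rhs).reshape(nx, ny, nz)
        change = float(np.max(np.abs(h_new - h_m)))
        h_m = h_new
        if change < picard_tol:
            break
    else:
        if dt <= 1e-5:
            raise RuntimeError(
                f"Richards Picard iteration failed to converge at dt={dt}")
        added = 0.0
        grid.h = h_old
        grid.theta = theta_old
        for _ in range(2):
            added += richards_step(grid, sinks, top_flux_bc, dt / 2.0,
                                   picard_tol, max_picard)
        return added

    # mass-conservative update: theta from the retention curve
    grid.h = h_m
    grid.theta, _ = van_genuchten(h_m, vg)
    added = top_flux_bc * top_area * nx * ny * dt
    if not return_fluxes:
        return added
    # face Darcy fluxes (cm^3/d, positive toward increasing index)
    _, K = van_genuchten(grid.h, vg)
    H = grid.h + z
    fluxes = {}
    for axis, d, key in ((0, grid.dx, "x"), (1, grid.dy, "y"), (2, grid.dz, "z")):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        Kf = 0.5 * (K[sl_lo] + K[sl_hi])
        area = vol / d
        fluxes[key] = -Kf * area * (H[sl_hi] - H[sl_lo]) / d
    return added, fluxes


# ---------------------------------------------------------------------------
# xylem hydraulic network

@dataclass
class XylemNetwork:
    """Sparse linear description of the root hydraulic network.

    ``axial``: (i, j, conductance cm^3/d per cm head) edges.
    ``radial``: per segment (node index, Lp*A conductance, segment id).
    Node 0 is the collar by convention unless ``collar`` says otherwise.
    """
    n_nodes: int
    axial: list[tuple[int, int, float]]
    radial: list[tuple[int, float]]       # (node, Lp*A)
    collar: int = 0
    segments: list = field(default_factory=list)   # parallel to radial


def build_xylem_network(root_system, Lp: dict[str, float],
                        Kx: dict[str, float]) -> XylemNetwork:
    """Assemble the hydraulic network from a grown root system.

    Each root contributes a chain of nodes (its vertices, including the
    tip); branch bases tie into the parent node nearest their attachment
    arc length, and axes without a parent tie into the collar.  Axial
    conductance of a segment is Kx / grown length; each segment's radial
    exchange (Lp times lateral surface, anatomy-adjusted) acts at its
    distal node.
    """
    from .architecture import anatomy_modifiers
    node_pos: list[np.ndarray] = [None]  # collar placeholder
    axial: list[tuple[int, int, float]] = []
    radial: list[tuple[int, float]] = []
    seg_list: list = []
    root_nodes: dict[int, list[int]] = {}

    collar_z = 0.0
    node_pos[0] = np.array([0.0, 0.0, collar_z])

    def nearest_parent_node(parent, s):
        cum = parent.cumulative_grown()
        i = int(np.searchsorted(cum, s))
        i = min(max(i, 0), len(root_nodes[id(parent)]) - 1)
        return root_nodes[id(parent)][i]

    for root in root_system.roots:
        segs = list(root.segments)
        # include the live tip piece so every root has at least one edge
        tip_piece = None
        if root.tip is not None and root.tip.since_vertex > 1e-12:
            tip_piece = root.tip
        ids = []
        base_id = len(node_pos)
        node_pos.append(root.nodes[0].position.copy())
        ids.append(base_id)
        prev = base_id
        kx = Kx.get(root.params.name, Kx.get("default", 0.1))
        lp = Lp.get(root.params.name, Lp.get("default", 1e-3))
        for seg in segs:
            nid = len(node_pos)
            node_pos.append(seg.tail.position.copy())
            ids.append(nid)
            g_ax = kx / max(seg.grown_length, 1e-9)
            axial.append((prev, nid, g_ax))
            mods = anatomy_modifiers(seg.anatomy)
            gr = lp * seg.surface_area() * mods["radial_conductivity_multiplier"]
            radial.append((nid, gr))
            seg_list.append(seg)
            prev = nid
        if tip_piece is not None:
            # synthetic distal piece up to the moving tip vertex
            from .architecture import RootNode, RootSegment
            nid = len(node_pos)
            node_pos.append(tip_piece.vertex.position.copy())
            ids.append(nid)
            L = tip_piece.since_vertex
            axial.append((prev, nid, kx / max(L, 1e-9)))
            head = root.nodes[-1]
            tseg = RootSegment(
                head=head,
                tail=RootNode(tip_piece.vertex.position.copy(),
                              root.base_time + tip_piece.age),
                grown_length=L, diameter_base=root.diameter,
                diameter_tip=root.diameter, root_class=root.params.name,
                parent_root=root,
                distance_along_root=root.grown_length - L,
                anatomy=root.params.anatomy)
            mods = anatomy_modifiers(tseg.anatomy)
            radial.append((nid, lp * tseg.surface_area()
                           * mods["radial_conductivity_multiplier"]))
            seg_list.append(tseg)
        root_nodes[id(root)] = ids
        # connect the base
        if root.parent is None:
            # stem/hypocotyl axial path to the collar
            dist = max(float(np.linalg.norm(node_pos[base_id] - node_pos[0])), 1.0)
            axial.append((0, base_id, kx / dist))
        else:
            pn = nearest_parent_node(root.parent, root.attach_distance)
            axial.append((pn, base_id, kx / 0.1))
    net = XylemNetwork(n_nodes=len(node_pos), axial=axial, radial=radial,
                       collar=0, segments=seg_list)
    net.node_positions = node_pos  # type: ignore[attr-defined]
    return net


def xylem_solve(net: XylemNetwork, psi_soil: np.ndarray,
                collar_bc: tuple[str, float]):
    """Solve the linear network for xylem potentials and radial fluxes.

    Node balance: sum of axial conduction plus the radial exchange
    Lp*A*(psi_soil - psi_node) equals zero everywhere except the collar,
    which carries either a fixed potential ("potential", cm total head) or
    a fixed extraction flux ("flux", cm^3/d, positive = transpiration).

    Returns (psi per node, radial flux per segment: positive = uptake).
    """
    n = net.n_nodes
    psi_soil = np.asarray(psi_soil, dtype=float)
    if len(psi_soil) != len(net.radial):
        raise ValueError("psi_soil must have one entry per radial segment")
    A = sp.lil_matrix((n, n))
    b = np.zeros(n)
    for i, j, g in net.axial:
        A[i, i] += g
        A[j, j] += g
        A[i, j] -= g
        A[j, i] -= g
    for (node, g), ps in zip(net.radial, psi_soil):
        A[node, node] += g
        b[node] += g * ps
    kind, value = collar_bc
    if kind == "flux":
        b[net.collar] -= value
    elif kind == "potential":
        A.rows[net.collar] = [net.collar]
        A.data[net.collar] = [1.0]
        b[net.collar] = value
        # remove the collar column symmetrically
        for i in range(n):
            if i != net.collar:
                row = A.rows[i]
                if net.collar in row:
                    k = row.index(net.collar)
                    g = A.data[i][k]
                    b[i] -= g * value
                    A.data[i][k] = 0.0
    else:
        raise ValueError(f"unknown collar boundary kind {kind!r}")
    A = A.tocsr()
    try:
        psi = spla.spsolve(A, b)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError("singular xylem system (disconnected subtree?)") from exc
    if not np.all(np.isfinite(psi)):
        raise RuntimeError("singular xylem system (disconnected subtree?)")
    flux = np.array([g * (ps - psi[node])
                     for (node, g), ps in zip(net.radial, psi_soil)])
    return psi, flux


def kirchhoff_residual(net: XylemNetwork, psi: np.ndarray,
                       psi_soil: np.ndarray,
                       collar_bc: tuple[str, float]) -> float:
    """Largest relative node-balance violation of a solved network."""
    n = net.n_nodes
    resid = np.zeros(n)
    scale = np.zeros(n)
    for i, j, g in net.axial:
        f = g * (psi[j] - psi[i])
        resid[i] += f
        resid[j] -= f
        scale[i] += abs(f)
        scale[j] += abs(f)
    for (node, g), ps in zip(net.radial, psi_soil):
        f = g * (ps - psi[node])
        resid[node] += f
        scale[node] += abs(f)
    kind, value = collar_bc
    if kind == "flux":
        resid[net.collar] -= value
        scale[net.collar] += abs(value)
    else:
        resid[net.collar] = 0.0
    scale = np.maximum(scale, 1e-12)
    internal = np.ones(n, dtype=bool)
    if kind == "potential":
        internal[net.collar] = False
    return float(np.max(np.abs(resid[internal]) / scale[internal]))


# ---------------------------------------------------------------------------
# evapotranspiration

@dataclass
class Weather:
    """One day of weather driving evapotranspiration."""
    Rn: float = 15.0    # net radiation, MJ/m^2/d
    G: float = 0.0      # soil heat flux, MJ/m^2/d
    T: float = 20.0     # air temperature, C
    RH: float = 60.0    # relative humidity, %
    u2: float = 2.0     # wind speed at 2 m, m/s
    rs: float = 70.0    # surface resistance, s/m
    pressure: float = 101.3  # kPa

    def validate(self):
        if not 0.0 <= self.RH <= 100.0:
            raise ValueError("RH must be within [0, 100]")


def penman_monteith(w: Weather, canopy_cover: float) -> dict[str, float]:
    """Potential transpiration and soil evaporation (cm/d).

    The combination equation
    lambda ET = (Delta (Rn - G) + rho_a c_p VPD / r_a) / (Delta + gamma (1 + r_s/r_a))
    is evaluated with the saturation-slope, psychrometric-constant and
    aerodynamic-resistance formulations standard for a short reference
    surface (r_a = 208/u2 s/m).  The result partitions by canopy cover:
    transpiration over the covered fraction, soil evaporation (bare-soil
    surface resistance) over the rest.
    """
    w.validate()
    if not 0.0 <= canopy_cover <= 1.0:
        raise ValueError("canopy_cover must be in [0, 1]")
    T = w.T
    es = 0.6108 * math.exp(17.27 * T / (T + 237.3))      # kPa
    ea = es * w.RH / 100.0
    delta = 4098.0 * es / (T + 237.3) ** 2               # kPa/C
    lam = 2.45e6                                          # J/kg
    gamma = 1013.0 * w.pressure / (0.622 * lam / 1000.0) / 1000.0  # kPa/C
    rho_a = w.pressure * 1000.0 / (287.0 * (T + 273.15))  # kg/m^3
    ra = 208.0 / max(w.u2, 0.1)                           # s/m

    def et(rs_: float) -> float:
        rad = (w.Rn - w.G) * 1.0e6 / 86400.0              # W/m^2
        num = delta * rad + rho_a * 1013.0 * (es - ea) * 1000.0 / ra
        den = delta + gamma * (1.0 + rs_ / ra)
        lam_et = num / den                                # W/m^2
        return max(0.0, lam_et * 86400.0 / lam / 10.0)    # cm/d

    return {
        "transpiration_potential": et(w.rs) * canopy_cover,
        "evaporation_potential": et(w.rs * 2.0) * (1.0 - canopy_cover),
    }


# ---------------------------------------------------------------------------
# the coupled water step

def water_step(root_system, grid: SoilGrid, Lp: dict[str, float],
               Kx: dict[str, float], weather: Weather, dt: float,
               canopy_cover: float = 0.5,
               min_collar_potential: float = MIN_COLLAR_POTENTIAL,
               plant_area_fraction: float = 1.0) -> dict[str, float]:
    """Operator-split coupled soil-plant-atmosphere water update over dt.

    Per sub-step (<= 0.05 d): (1) atmospheric potentials; (2) xylem solve
    with the collar flux equal to the potential transpiration, switched to
    a potential-controlled solve when any xylem potential would fall below
    the permitted minimum; (3) radial fluxes become Richards sinks;
    (4) Richards step with evaporation as a supply-limited top flux.

    Returns cumulative actual transpiration and evaporation (cm^3).
    """
    out = {"transpiration": 0.0, "evaporation": 0.0, "hydraulic_lift": 0.0}
    pm = penman_monteith(weather, canopy_cover)
    domain_area = grid.dx * grid.dy * grid.nx * grid.ny * plant_area_fraction
    T_pot = pm["transpiration_potential"] * domain_area     # cm^3/d
    E_pot = pm["evaporation_potential"]                     # cm/d

    remaining = dt
    while remaining > 1e-12:
        sub = min(WATER_MAX_DT, remaining)
        net = build_xylem_network(root_system, Lp, Kx)
        if not net.radial:
            break
        z = grid.z_centers()
        psi_soil = np.empty(len(net.radial))
        cells = []
        for k, seg in enumerate(net.segments):
            c = grid.cell_of(seg.midpoint)
            cells.append(c)
            psi_soil[k] = grid.h[c] + z[c[2]]               # total head
        psi, flux = xylem_solve(net, psi_soil, ("flux", T_pot))
        if psi.min() < min_collar_potential:
            psi, flux = xylem_solve(net, psi_soil,
                                    ("potential", min_collar_potential))
        uptake = float(flux.sum())                          # cm^3/d
        sinks = np.zeros_like(grid.h)
        for c, f in zip(cells, flux):
            sinks[c] += f
        # supply-limited evaporation from the top layer
        _, K_top = van_genuchten(grid.h[:, :, 0], grid.vg)
        e_limit = float(np.mean(K_top))
        E_act = min(E_pot, e_limit)
        richards_step(grid, sinks, -E_act, sub)
        out["transpiration"] += uptake * sub
        out["evaporation"] += E_act * grid.dx * grid.dy * grid.nx * grid.ny * sub
        out["hydraulic_lift"] += float(-flux[flux < 0].sum()) * sub
        remaining -= sub
    return out
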