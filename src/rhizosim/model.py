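"""The coupled whole-plant simulation.

``build_simulation`` interprets a parsed parameter document into typed
configuration and a :class:`Simulation`, which advances the plant with an
operator-split loop: per global step it (1) derives stress multipliers from
the previous nutrient status, (2) fixes carbon, charges maintenance costs
and allocates the remainder among shoot, secondary growth, main axes and
branch roots, (3) grows the architecture with the composed multipliers
(vigor x carbon x nutrient stress x plasticity), (4) runs the soil-plant-
atmosphere water step when hydrology is configured, and (5) advances the
nutrient models and the plant nutrient ledgers.

The step keeps an explicit carbon ledger; fixation plus seed release equals
structural growth plus maintenance plus the labile-pool change at every
step, which the test suite checks to 1e-6 relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import architecture as arch
from . import carbon as cb
from . import hydrology as hyd
from . import nutrients as nut
from . import plasticity as pl
from .engine import ConfigurationError, StateVariable, StateVariableTree

__all__ = ["Simulation", "build_simulation", "run_minimal_model"]


# ---------------------------------------------------------------------------
# reading the parameter tree

def _get(node: StateVariable, name: str, default=None):
    if name in node.children:
        c = node.children[name]
        if c.kind == "table":
            return list(c.table)
        return c.value
    return default


def _req(node: StateVariable, name: str):
    v = _get(node, name)
    if v is None:
        raise ConfigurationError(
            f"{node.path()!r} is missing required entry {name!r}")
    return v


def build_root_classes(tree: StateVariableTree) -> dict[str, arch.RootClassParams]:
    classes: dict[str, arch.RootClassParams] = {}
    if "rootClasses" not in tree.root.children:
        return classes
    for name, node in tree.root.children["rootClasses"].children.items():
        if node.value_type != "group":
            continue
        branches = _get(node, "branchClasses", "")
        anatomy = arch.RootAnatomy(
            rca_fraction=float(_get(node, "rcaFraction", 0.0)),
            rcs_fraction=float(_get(node, "rcsFraction", 0.0)),
            root_hair_length=float(_get(node, "rootHairLength", 0.0)),
            root_hair_diameter=float(_get(node, "rootHairDiameter", 0.0)),
            root_hair_density=float(_get(node, "rootHairDensity", 0.0)))
        classes[name] = arch.RootClassParams(
            name=name,
            elongation_rate=_req(node, "elongationRate"),
            initial_diameter=float(_req(node, "initialDiameter")),
            segment_length=float(_get(node, "segmentLength", 0.5)),
            branch_spacing=(float(_get(node, "branchSpacing"))
                            if _get(node, "branchSpacing") is not None else None),
            branch_interval=(float(_get(node, "branchInterval"))
                             if _get(node, "branchInterval") is not None else None),
            axial_branch_angle=float(_get(node, "axialBranchAngle", 80.0)),
            n_poles=int(_get(node, "nPoles", 1)),
            branch_classes=tuple(b for b in str(branches).split(",") if b),
            gravitropism_weight=float(_get(node, "gravitropism", 0.0)),
            impedance_weight=float(_get(node, "impedance", 0.0)),
            secondary_growth_rate=_get(node, "secondaryGrowthRate"),
            vigor_sigma=float(_get(node, "vigorSigma", 0.0)),
            apical_nonbranching_zone=float(_get(node, "apicalZone", 0.0)),
            basal_nonbranching_zone=float(_get(node, "basalZone", 0.0)),
            branch_delay=float(_get(node, "branchDelay", 0.0)),
            anatomy=anatomy)
    return classes


@dataclass
class NutrientConfig:
    spec: nut.NutrientSpec
    initial_concentration: float
    buffer_power: float = 100.0
    D0: float = 1.0
    dispersivity: float = 0.5


@dataclass
class PlasticityConfig:
    norm: pl.ReactionNorm
    field_fn: object            # callable: position -> local scalar


class Simulation:
    """A configured, steppable plant-and-soil model."""

    def __init__(self, tree: StateVariableTree, seed: int = 0):
        self.tree = tree
        root = tree.root
        sim = root.children.get("simulation")
        self.duration = float(_get(sim, "duration", 10.0)) if sim else 10.0
        self.dt = float(_get(sim, "timeStep", 0.1)) if sim else 0.1
        self.seed = seed if seed else int(_get(sim, "randomSeed", 0) or 0)
        self.time = 0.0

        classes = build_root_classes(tree)
        plant = root.children.get("plant")
        if plant is None:
            raise ConfigurationError("parameter document has no plant section")
        self.seed_depth = float(_get(plant, "seedDepth", -2.0))
        self.rs = arch.RootSystem(classes, seed=self.seed,
                                  seed_depth=self.seed_depth)
        for cname in str(_req(plant, "primaryAxes")).split(","):
            if cname:
                self.rs.add_axis(cname)

        # shoot and carbon
        sla = _get(plant, "specificLeafArea", [(0.0, 200.0)])
        self.c_fraction = float(_get(plant, "carbonFraction", cb.C_FRACTION))
        self.shoot = cb.ShootState(
            leaf_area=float(_get(plant, "initialLeafArea", 2.0)),
            leaf_dw=float(_get(plant, "initialLeafArea", 2.0))
            / float(np.interp(0.0, *zip(*sla))) if sla else 0.01,
            stem_dw=0.005,
            potential_leaf_area=float(_get(plant, "initialLeafArea", 2.0)),
            sla=sla, dw_per_C=1.0 / self.c_fraction)
        self.potential_la_table = _get(plant, "potentialLeafArea",
                                       [(0.0, 2.0), (30.0, 500.0)])
        f_leaf = _get(plant, "partitioningLeaf", [(0.0, 0.45)])
        f_stem = _get(plant, "partitioningStem", [(0.0, 0.15)])
        times = sorted({t for t, _ in f_leaf} | {t for t, _ in f_stem})
        part = []
        for t in times:
            fl = float(np.interp(t, *zip(*f_leaf)))
            fs = float(np.interp(t, *zip(*f_stem)))
            part.append((t, (fl, fs, 1.0 - fl - fs)))
        self.canopy = cb.CanopyParams(
            rue=float(_get(plant, "radiationUseEfficiency", 2.5)),
            k_ext=float(_get(plant, "extinctionCoefficient", 0.65)),
            plant_density=float(_get(plant, "plantDensity", 25.0)),
            partitioning=part)
        self.light = float(_get(plant, "dailyLight", 12.0))
        self.pools = cb.CarbonPools(
            labile=0.0, seed_reserve=float(_get(plant, "seedCarbonReserve", 0.08)))
        self.seed_c_total = self.pools.seed_reserve
        self.srv = float(_get(plant, "specificRootVolume", 0.05))
        self.allocation_rule = str(_get(plant, "allocationRule", "priority"))
        self.recovery_rate = float(_get(plant, "recoveryRate", 0.1))
        resp = float(_get(plant, "respirationRate", 0.0))
        exud = float(_get(plant, "exudationRate", 0.0))
        self.costs = cb.CostParams(
            respiration={c: [(0.0, resp)] for c in classes} if resp else {},
            exudation={c: [(0.0, exud)] for c in classes} if exud else {},
            nitrate_uptake_cost=float(_get(plant, "nitrateUptakeCost", 0.0)))

        # whorls and tillers
        self.whorls: list[arch.WhorlSpec] = []
        for wnode_name in ("whorls", ):
            wroot = plant.children.get(wnode_name)
            if wroot is None and "rootClasses" in root.children:
                wroot = root.children["rootClasses"].children.get("basalWhorls")
            if wroot is not None:
                for w in wroot.children.values():
                    self.whorls.append(arch.WhorlSpec(
                        start_time=float(_req(w, "startTime")),
                        position_on_stem=float(_get(w, "positionOnStem", 0.5)),
                        n_roots=int(_req(w, "nRoots")),
                        root_class=str(_req(w, "rootClass")),
                        shoot_size_rule=bool(_get(w, "shootSizeRule", False))))
        td = _get(plant, "tillerDelay")
        self.tiller_spec = arch.TillerSpec(td) if td else None
        self.n_tillers = 0

        # plasticity
        self.plasticity: PlasticityConfig | None = None
        pnode = root.children.get("plasticity")
        if pnode is not None:
            curve = _req(pnode, "responseCurve")
            target = str(_get(pnode, "target", "branch_spacing"))
            norm = pl.ReactionNorm(curve=curve, target=target)
            prof = _get(pnode, "phosphorusDepthProfile")
            if prof is not None:
                depths = [p[0] for p in prof]
                vals = [p[1] for p in prof]

                def field_fn(pos, depths=depths, vals=vals):
                    return float(np.interp(-pos[2], depths, vals))
            else:
                raise ConfigurationError(
                    "plasticity section needs an environment field")
            self.plasticity = PlasticityConfig(norm=norm, field_fn=field_fn)

        # hydrology
        self.grid: hyd.SoilGrid | None = None
        self.weather: hyd.Weather | None = None
        self.Lp: dict[str, float] = {}
        self.Kx: dict[str, float] = {}
        self.last_water_fluxes = None
        snode = root.children.get("soil")
        if snode is not None:
            vgn = snode.children.get("vanGenuchten")
            vg = hyd.VanGenuchten(
                theta_r=float(_get(vgn, "thetaR", 0.05)),
                theta_s=float(_get(vgn, "thetaS", 0.45)),
                alpha=float(_get(vgn, "alpha", 0.02)),
                n=float(_get(vgn, "n", 1.8)),
                Ks=float(_get(vgn, "Ks", 50.0))) if vgn else hyd.VanGenuchten()
            self.grid = hyd.SoilGrid(
                nx=int(_get(snode, "nx", 8)), ny=int(_get(snode, "ny", 8)),
                nz=int(_get(snode, "nz", 10)),
                dx=float(_get(snode, "dx", 5.0)),
                dy=float(_get(snode, "dy", 5.0)),
                dz=float(_get(snode, "dz", 5.0)), vg=vg,
                h_init=float(_get(snode, "initialHydraulicHead", -300.0)))
            self.Lp = {"default": float(_get(snode, "radialConductivity", 5e-5))}
            self.Kx = {"default": float(_get(snode, "axialConductance", 0.05))}
            wnode = snode.children.get("weather")
            self.weather = hyd.Weather(
                Rn=float(_get(wnode, "netRadiation", 14.0)),
                T=float(_get(wnode, "temperature", 22.0)),
                RH=float(_get(wnode, "relativeHumidity", 55.0)),
                u2=float(_get(wnode, "windSpeed", 2.0)),
                rs=float(_get(wnode, "surfaceResistance", 70.0))
            ) if wnode else hyd.Weather()

        # nutrients
        self.nutrients: dict[str, NutrientConfig] = {}
        self.nutrient_states: dict[str, nut.PlantNutrientState] = {}
        self.solute_fields: dict[str, nut.SoluteField] = {}
        self.profiles: dict[str, dict[int, nut.RadialProfile]] = {}
        self.uptake_history: dict[str, list[float]] = {}
        self.stress_enabled = True
        nnode = root.children.get("nutrients")
        if nnode is not None:
            for name, sub in nnode.children.items():
                spec = nut.NutrientSpec(
                    name=name,
                    mobility=str(_get(sub, "mobility", "barber_cushman")),
                    Imax=float(_req(sub, "Imax")),
                    Km=float(_req(sub, "Km")),
                    Cmin=float(_get(sub, "Cmin", 0.0)),
                    optimal_conc=_get(sub, "optimalConcentration", [(0.0, 100.0)]),
                    minimal_conc=_get(sub, "minimalConcentration", [(0.0, 50.0)]))
                cfg = NutrientConfig(
                    spec=spec,
                    initial_concentration=float(_get(sub, "initialConcentration", 0.01)),
                    buffer_power=float(_get(sub, "bufferPower", 100.0)),
                    D0=float(_get(sub, "diffusionCoefficient", 1.0)),
                    dispersivity=float(_get(sub, "dispersivity", 0.5)))
                self.nutrients[name] = cfg
                st = nut.PlantNutrientState(
                    content=float(_get(sub, "seedReserve", 0.0)),
                    fixation_fraction=float(_get(sub, "fixationFraction", 0.0)))
                self.nutrient_states[name] = st
                self.uptake_history[name] = []
                if spec.mobility == "grid_solute":
                    if self.grid is None:
                        # a mobile nutrient needs a grid even without hydrology
                        self.grid = hyd.SoilGrid(8, 8, 10)
                    self.solute_fields[name] = nut.SoluteField(
                        self.grid, C_init=cfg.initial_concentration,
                        D0=cfg.D0, dispersivity=cfg.dispersivity)
                else:
                    self.profiles[name] = {}

        self.ledger: list[dict[str, float]] = []
        self.history: list[dict[str, float]] = []
        self._stress = {p: 1.0 for p in nut.DEFAULT_STRESS_PROCESSES}

    # -- helpers ----------------------------------------------------------

    def _is_branch_class(self, name: str) -> bool:
        return any(name in c.branch_classes
                   for c in self.rs.class_params.values())

    def _sink_group(self, root: arch.Root) -> str:
        return "branch_roots" if self._is_branch_class(root.params.name) \
            else "main_axes"

    def _elongation_multiplier(self, root: arch.Root,
                               carbon_mults: dict[str, float]) -> float:
        m = carbon_mults.get(self._sink_group(root), 1.0)
        if self.stress_enabled:
            m *= self._stress.get("root_elongation", 1.0)
        if self.plasticity is not None and \
                self.plasticity.norm.target == "elongation" and \
                root.tip is not None:
            local = self.plasticity.field_fn(root.tip.vertex.position)
            m *= pl.apply_norm(self.plasticity.norm, local)
        return m

    def _root_step(self, root: arch.Root) -> float:
        """Effective elongation time of this root within the next step."""
        if root.tip is None:
            return 0.0
        if root.base_time > self.time:
            return max(0.0, self.time + self.dt - root.base_time)
        return self.dt

    def _potential_root_demands(self) -> dict[str, float]:
        """Carbon demand of root elongation per sink group, this step."""
        demands = {"main_axes": 0.0, "branch_roots": 0.0}
        for root in self.rs.roots:
            step = self._root_step(root)
            if step <= 0 or root.tip is None:
                continue
            m = self._elongation_multiplier(root, {})
            inc = arch.elongate_tip(root.tip, step, m)
            area = math.pi * (root.diameter / 2.0) ** 2
            demands[self._sink_group(root)] += \
                cb.segment_growth_demand(inc * area, self.srv, self.c_fraction)
        return demands

    def _secondary_demand(self) -> float:
        total = 0.0
        for root in self.rs.roots:
            table = root.params.secondary_growth_rate
            if table is None:
                continue
            for seg in root.segments:
                rate = float(np.interp(seg.age(self.time),
                                       [p[0] for p in table],
                                       [p[1] for p in table]))
                dd = 2.0 * rate * self.dt
                r0 = seg.diameter_base / 2.0
                dv = math.pi * seg.grown_length * ((r0 + dd / 2.0) ** 2 - r0 ** 2)
                total += cb.segment_growth_demand(dv, self.srv, self.c_fraction)
        return total

    # -- the step ---------------------------------------------------------

    def step(self) -> dict[str, float]:
        t, dt = self.time, self.dt
        labile_before = self.pools.labile

        # 1. stress multipliers from the previous nutrient status
        if self.nutrients and self.stress_enabled:
            self._stress = nut.stress_factors(self.nutrient_states,
                                              {k: v.spec for k, v in
                                               self.nutrients.items()})
        photo_stress = self._stress.get("photosynthesis", 1.0) \
            if self.stress_enabled else 1.0

        # 2. carbon income and maintenance
        fixed = cb.fix_carbon(self.shoot, self.canopy, self.light,
                              photo_stress) * dt
        seed_rel = cb.release_seed_reserve(self.pools, t, dt,
                                           self.seed_c_total)
        n_uptake_prev = self.uptake_history.get("nitrate", [])
        ncost_uptake = n_uptake_prev[-1] if n_uptake_prev else 0.0
        costs = cb.carbon_costs(self.rs.iter_segments(), self.costs, t, dt,
                                nitrate_uptake=ncost_uptake)
        cost_total = sum(costs.values())
        income = fixed + seed_rel
        paid = min(cost_total, income + labile_before)
        net_source = income - paid
        if net_source < 0:   # maintenance partly from the labile pool
            self.pools.labile = max(0.0, self.pools.labile + net_source)
            net_source = 0.0

        # 3. sinks and allocation
        self.shoot.potential_leaf_area = float(np.interp(
            t + dt, *zip(*self.potential_la_table)))
        cap = cb.allometric_cap(self.shoot, self.recovery_rate)
        pla_rate = float(np.interp(t + dt, *zip(*self.potential_la_table))) - \
            float(np.interp(t, *zip(*self.potential_la_table)))
        leaf_stress = self._stress.get("leaf_expansion", 1.0) \
            if self.stress_enabled else 1.0
        sla_now = float(np.interp(t, *zip(*[(a, b) for a, b in self.shoot.sla])))
        f_leaf, f_stem, _ = self.canopy.fractions(t)
        shoot_frac = max(f_leaf + f_stem, 1e-9)
        d_leaf_dw = pla_rate * cap * leaf_stress / max(sla_now, 1e-9)
        d_shoot_dw = d_leaf_dw * shoot_frac / max(f_leaf, 1e-9)
        shoot_demand = d_shoot_dw * self.c_fraction
        root_demands = self._potential_root_demands()
        sec_demand = self._secondary_demand()
        sinks = {"shoot": shoot_demand, "secondary_growth": sec_demand,
                 **root_demands}
        allocs = cb.allocate(self.pools, net_source, sinks,
                             rule=self.allocation_rule)

        # 4. grow shoot
        cb.grow_shoot(self.shoot, allocs["shoot"], t, self.canopy)
        spent = allocs["shoot"]

        # 5. grow roots with the composed multipliers
        carbon_mults = {}
        for g in ("main_axes", "branch_roots"):
            d = sinks[g]
            carbon_mults[g] = allocs[g] / d if d > 0 else 1.0
        spacing_mult = None
        if self.plasticity is not None and \
                self.plasticity.norm.target == "branch_spacing":
            norm, ffn = self.plasticity.norm, self.plasticity.field_fn
            spacing_mult = lambda pos: pl.apply_norm(norm, ffn(pos))
        grav_mult = None
        if self.plasticity is not None and \
                self.plasticity.norm.target == "gravitropism_weight":
            norm, ffn = self.plasticity.norm, self.plasticity.field_fn
            grav_mult = lambda pos: pl.apply_norm(norm, ffn(pos))
        self.rs.grow(
            dt,
            growth_multiplier=lambda r: self._elongation_multiplier(
                r, carbon_mults),
            spacing_multiplier=spacing_mult,
            gravitropism_multiplier=grav_mult,
            branch_rate_multiplier=min(1.0, cap),
            whorls=self.whorls,
            shoot_ratio=min(1.0, self.shoot.leaf_area
                            / max(self.shoot.potential_leaf_area, 1e-9)))
        spent += allocs["main_axes"] + allocs["branch_roots"]

        # 6. secondary growth, charged at actual volume increase
        sec_mult = allocs["secondary_growth"] / sec_demand \
            if sec_demand > 0 else 1.0
        sec_stress = self._stress.get("secondary_growth", 1.0) \
            if self.stress_enabled else 1.0
        sec_spent = 0.0
        for root in self.rs.roots:
            if root.params.secondary_growth_rate is None:
                continue
            for seg in root.segments:
                dv = arch.secondary_thicken(seg, self.time, dt,
                                            carbon_multiplier=sec_mult * sec_stress)
                sec_spent += cb.segment_growth_demand(dv, self.srv,
                                                      self.c_fraction)
        self.pools.labile += max(0.0, allocs["secondary_growth"] - sec_spent)
        spent += min(sec_spent, allocs["secondary_growth"])

        # 7. tillers
        if self.tiller_spec is not None:
            def make_tiller(t_event):
                self.n_tillers += 1
                self.rs.add_axis("primary", base_time=t_event,
                                 plant_id=self.n_tillers)
            arch.form_tillers(self.rs, self.tiller_spec, t + dt, make_tiller)

        # 8. water
        water = {"transpiration": 0.0, "evaporation": 0.0, "hydraulic_lift": 0.0}
        if self.grid is not None and self.weather is not None and self.Lp:
            lai = self.shoot.leaf_area * self.canopy.plant_density / 1e4
            cover = 1.0 - math.exp(-self.canopy.k_ext * lai)
            water = hyd.water_step(self.rs, self.grid, self.Lp, self.Kx,
                                   self.weather, dt, canopy_cover=cover)

        # 9. nutrients
        self._nutrient_step(dt)

        # 10. bookkeeping
        self.time = t + dt
        d_labile = self.pools.labile - labile_before
        self.ledger.append({
            "t": self.time, "fixed": fixed, "seed_release": seed_rel,
            "growth": spent, "respiration": costs["respiration"],
            "exudation": costs["exudation"],
            "uptake_cost": costs["nitrate_uptake_cost"],
            "paid_costs": paid, "d_labile": d_labile,
            "residual": fixed + seed_rel - spent - paid - d_labile,
        })
        row = {
            "time": self.time, "leaf_area": self.shoot.leaf_area,
            "root_length": self.rs.total_length(),
            "labile": self.pools.labile, "fixed": fixed,
            "n_roots": len(self.rs.roots), **water,
        }
        for name, st in self.nutrient_states.items():
            row[f"{name}_content"] = st.content
            row[f"{name}_satisfaction"] = st.satisfaction
        self.history.append(row)
        return row

    def _nutrient_step(self, dt: float) -> None:
        from .geometry import class_totals
        if not self.nutrients:
            return
        totals = class_totals(self.rs)
        root_volume = sum(v["volume"] for v in totals.values())
        organ_dw = {
            "leaf": self.shoot.leaf_dw, "stem": self.shoot.stem_dw,
            "root": root_volume * self.srv,
        }
        total_len = self.rs.total_length()
        rld = total_len / 8.0e3 if total_len > 0 else 0.1   # rough, cm/cm^3
        for name, cfg in self.nutrients.items():
            spec = cfg.spec
            st = self.nutrient_states[name]
            uptake = 0.0
            if spec.mobility == "barber_cushman":
                profs = self.profiles[name]
                theta = 0.3 if self.grid is None else float(np.mean(self.grid.theta))
                theta_s = 0.45 if self.grid is None else self.grid.vg.theta_s
                De = nut.effective_diffusion(cfg.D0, theta, theta_s,
                                             cfg.buffer_power)
                rx = min(2.0, max(0.2, nut.outer_radius_from_rld(max(rld, 1e-3))))
                for seg in list(self._committed_segments()):
                    key = id(seg)
                    if key not in profs:
                        r0 = max(seg.diameter_base / 2.0, 1e-3)
                        profs[key] = nut.RadialProfile(
                            r0, max(rx, r0 * 3.0), cfg.initial_concentration,
                            b=cfg.buffer_power, De=De)
                    prof = profs[key]
                    mods = arch.anatomy_modifiers(seg.anatomy)
                    u = nut.barber_cushman_step(
                        prof, spec, dt,
                        uptake_area_multiplier=mods["uptake_area_multiplier"])
                    uptake += u * seg.grown_length
            else:
                fieldc = self.solute_fields[name]
                g = self.grid
                sinks = np.zeros((g.nx, g.ny, g.nz))
                z = g.z_centers()
                for seg in self.rs.iter_segments():
                    c = g.cell_of(seg.midpoint)
                    mods = arch.anatomy_modifiers(seg.anatomy)
                    sinks[c] += nut.mm_flux(
                        fieldc.C[c], spec, seg.surface_area(),
                        mods["uptake_area_multiplier"])
                uptake = nut.grid_solute_step(
                    fieldc, self.last_water_fluxes, sinks, None, dt)
            st.content += uptake
            req = nut.requirements(organ_dw, spec, self.time)
            st.requirement_optimal = req["optimal"]
            st.requirement_minimal = req["minimal"]
            if st.fixation_fraction > 0:
                nut.fixation(st)
            st.update_satisfaction()
            self.uptake_history[name].append(uptake)

    def _committed_segments(self):
        for root in self.rs.roots:
            yield from root.segments

    def run(self, until: float | None = None):
        """Run to ``until`` (default: configured duration); returns the
        per-step summary as a pandas DataFrame."""
        import pandas as pd
        until = self.duration if until is None else until
        n = int(round((until - self.time) / self.dt))
        for _ in range(n):
            self.step()
        return pd.DataFrame(self.history)


def build_simulation(tree_or_doc, seed: int = 0) -> Simulation:
    """Build a runnable simulation from a parameter document or tree."""
    if isinstance(tree_or_doc, str):
        from .io import parse_parameters
        tree = parse_parameters(tree_or_doc, seed=seed)
    else:
        tree = tree_or_doc
    return Simulation(tree, seed=seed)


def run_minimal_model(doc: str, until: float = 10.0, dt: float = 0.1,
                      variable: str = "rootGrowth") -> float:
    """Parse and integrate a pure ODE parameter document (no plant section);
    returns the named variable at ``until``."""
    from .engine import advance, evaluate_at, resolve_reference
    from .io import parse_parameters
    tree = parse_parameters(doc, global_max_dt=dt)
    tree.step_tolerance = float("inf")
    advance(tree, until)
    var = resolve_reference(tree, tree.root, variable)
    return evaluate_at(var, until, tree)
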