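"""3D root system architecture: tips, tropism, branching, secondary growth.

The root system is a graph of vertices (3D points with creation times) and
segments (edges).  Every growing root has a tip vertex with dynamic
coordinates; all other vertices are stationary once placed.  Coordinates are
in cm with z pointing up and the soil surface at z = 0, so depths are
negative.

A root segment stores its *grown* length — the true distance the tip
travelled — which can exceed the chord between its two vertices when the
trajectory wiggles.  Discretisation therefore never loses root length:
total grown length equals the sum of elongation increments exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "RootNode", "RootSegment", "RootTip", "RootAnatomy", "RootClassParams",
    "WhorlSpec", "TillerSpec", "Root", "RootSystem",
    "elongate_tip", "update_direction", "place_vertex", "create_primordia",
    "emit_whorl", "secondary_thicken", "form_tillers", "anatomy_modifiers",
]

DOWN = np.array([0.0, 0.0, -1.0])


@dataclass
class RootNode:
    """A stationary vertex: 3D point (cm) plus creation time (days)."""
    position: np.ndarray
    creation_time: float

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class RootAnatomy:
    """Scalar anatomical traits of a root segment.

    Cortical conversions (aerenchyma, senescence) lower the living tissue
    fraction; root hairs add absorbing surface.
    """
    stele_diameter: float = 0.0          # cm
    cortex_thickness: float = 0.0        # cm
    rca_fraction: float = 0.0            # cortical aerenchyma, 0..1
    rcs_fraction: float = 0.0            # cortical senescence, 0..1
    root_hair_length: float = 0.0        # cm
    root_hair_diameter: float = 0.0      # cm
    root_hair_density: float = 0.0       # hairs per cm^2 of root surface

    def validate(self) -> None:
        for name in ("rca_fraction", "rcs_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.rca_fraction + self.rcs_fraction > 1.0 + 1e-12:
            raise ValueError("rca_fraction + rcs_fraction > 1")


def anatomy_modifiers(anatomy: RootAnatomy) -> dict[str, float]:
    """Process-level multipliers implied by segment anatomy.

    living_volume_fraction scales respiration and nutrient content;
    uptake_area_multiplier adds root-hair lateral surface per unit root
    surface; radial_conductivity_multiplier defaults to the living fraction
    (senesced/aerenchymatous cortex conducts less radially).
    """
    anatomy.validate()
    living = 1.0 - anatomy.rca_fraction - anatomy.rcs_fraction
    hair_area = (anatomy.root_hair_density * math.pi *
                 anatomy.root_hair_diameter * anatomy.root_hair_length)
    return {
        "living_volume_fraction": living,
        "uptake_area_multiplier": 1.0 + hair_area,
        "radial_conductivity_multiplier": living if (
            anatomy.rca_fraction or anatomy.rcs_fraction) else 1.0,
        "nutrient_content_multiplier": living,
    }


@dataclass
class RootSegment:
    """Edge between two vertices; volume model is a truncated cone."""
    head: RootNode                 # basal vertex
    tail: RootNode                 # distal vertex
    grown_length: float            # cm, true trajectory length
    diameter_base: float           # cm
    diameter_tip: float            # cm
    root_class: str
    parent_root: "Root"
    distance_along_root: float     # cm from root base to segment head
    anatomy: RootAnatomy = field(default_factory=RootAnatomy)

    @property
    def creation_time(self) -> float:
        return self.tail.creation_time

    def age(self, t: float) -> float:
        return max(0.0, t - self.creation_time)

    @property
    def chord(self) -> float:
        return float(np.linalg.norm(self.tail.position - self.head.position))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.head.position + self.tail.position)

    def volume(self) -> float:
        r0, r1 = self.diameter_base / 2.0, self.diameter_tip / 2.0
        return math.pi * self.grown_length * (r0 * r0 + r0 * r1 + r1 * r1) / 3.0

    def surface_area(self) -> float:
        # lateral area of the truncated cone along the grown length
        r0, r1 = self.diameter_base / 2.0, self.diameter_tip / 2.0
        slant = math.hypot(self.grown_length, r0 - r1)
        return math.pi * (r0 + r1) * slant


@dataclass
class RootClassParams:
    """Per-class growth and branching parameters."""
    name: str = "root"
    elongation_rate: Sequence[tuple[float, float]] = ((0.0, 1.0),)  # age d -> cm/d
    initial_diameter: float = 0.05                                  # cm
    segment_length: float = 0.5                                     # cm discretisation
    branch_spacing: float | None = None                             # cm
    branch_interval: float | None = None                            # d
    axial_branch_angle: float = 80.0                                # degrees
    n_poles: int = 1
    branch_classes: tuple[str, ...] = ()
    gravitropism_weight: float = 0.0
    impedance_weight: float = 0.0
    nutrient_tropism_weight: float = 0.0
    secondary_growth_rate: Sequence[tuple[float, float]] | None = None  # age d -> cm/d radial
    vigor_sigma: float = 0.0        # lognormal sigma; mean scaled to 1
    vigor_scales_diameter: bool = False
    allometric_diameter_exponent: float = 1.0
    apical_nonbranching_zone: float = 0.0   # cm
    basal_nonbranching_zone: float = 0.0    # cm
    branch_delay: float = 0.0       # d after parent tip passes
    anatomy: RootAnatomy = field(default_factory=RootAnatomy)

    def validate(self) -> None:
        if self.n_poles < 1:
            raise ValueError("n_poles must be >= 1")
        if self.branch_spacing is not None and self.branch_spacing <= 0:
            raise ValueError("branch spacing must be > 0")
        if self.branch_interval is not None and self.branch_interval <= 0:
            raise ValueError("branch interval must be > 0")
        if any(r < 0 for _, r in self.elongation_rate):
            raise ValueError("elongation rates must be >= 0")


@dataclass
class WhorlSpec:
    """One ring of adventitious (nodal/crown) roots on the stem."""
    start_time: float            # d
    position_on_stem: float      # cm above the seed along the hypocotyl
    n_roots: int
    root_class: str
    shoot_size_rule: bool = False   # scale count with actual/potential leaf area
    axial_angle: float = 100.0      # degrees from the (upward) stem axis


@dataclass
class TillerSpec:
    delay_table: Sequence[tuple[float, float]]  # time d -> delay to next tiller d


@dataclass
class RootTip:
    """The growing end of a root axis."""
    vertex: RootNode
    direction: np.ndarray
    vigor: float
    age: float
    distance_along_parent: float
    class_params: RootClassParams
    since_vertex: float = 0.0      # grown length not yet committed to a segment

    def __post_init__(self):
        self.direction = _normalize(np.asarray(self.direction, dtype=float))
        if self.vigor <= 0:
            raise ValueError("vigor must be > 0")


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def _interp_table(table: Sequence[tuple[float, float]], x: float) -> float:
    xs = [p[0] for p in table]
    ys = [p[1] for p in table]
    return float(np.interp(x, xs, ys))


def _table_integral(table: Sequence[tuple[float, float]], a: float, b: float) -> float:
    """Exact integral of the piecewise-linear table over [a, b] (end-clamped)."""
    if b <= a:
        return 0.0
    xs = [table[0][0] - 1.0] + [p[0] for p in table] + [table[-1][0] + 1.0]
    # sample at all breakpoints inside [a, b] plus the ends; trapezoid is
    # exact on a piecewise-linear integrand when breakpoints are included
    pts = sorted({a, b, *[x for x in xs if a < x < b]})
    vals = [_interp_table(table, x) for x in pts]
    return float(np.trapezoid(vals, pts))


class Root:
    """A single root axis: ordered vertices, segments and (maybe) a live tip."""

    def __init__(self, root_system: "RootSystem", class_params: RootClassParams,
                 base_position: np.ndarray, direction: np.ndarray,
                 base_time: float, vigor: float = 1.0,
                 parent: "Root | None" = None,
                 attach_distance: float = 0.0,
                 plant_id: int = 0):
        class_params.validate()
        self.system = root_system
        self.params = class_params
        self.parent = parent
        self.attach_distance = attach_distance
        self.plant_id = plant_id
        self.base_time = base_time
        self.vigor = vigor
        base = RootNode(np.array(base_position, dtype=float), base_time)
        self.nodes: list[RootNode] = [base]
        self.segments: list[RootSegment] = []
        self.tip: RootTip | None = RootTip(
            vertex=RootNode(base.position.copy(), base_time),
            direction=direction, vigor=vigor, age=0.0,
            distance_along_parent=attach_distance, class_params=class_params)
        self.grown_length = 0.0
        self.next_branch_distance: float | None = None  # set on first branching check
        self.children: list[Root] = []
        # per-root radial pole offset, drawn once
        self.phi0 = float(root_system.rng.uniform(
            0.0, 2.0 * math.pi / class_params.n_poles))
        d = class_params.initial_diameter
        if class_params.vigor_scales_diameter:
            d *= vigor ** class_params.allometric_diameter_exponent
        self.diameter = d

    # -- geometry helpers -------------------------------------------------

    def cumulative_grown(self) -> np.ndarray:
        out = np.zeros(len(self.segments) + 1)
        for i, s in enumerate(self.segments):
            out[i + 1] = out[i] + s.grown_length
        return out

    def point_at(self, s: float) -> tuple[np.ndarray, np.ndarray, float]:
        """Position, direction and passage time at grown-length distance s.

        The chord of each segment is mapped proportionally to its grown
        length, so positions stay consistent with true lengths.
        """
        cum = self.cumulative_grown()
        total = self.grown_length
        s = min(max(s, 0.0), total)
        for i, seg in enumerate(self.segments):
            if s <= cum[i + 1] + 1e-12:
                f = 0.0 if seg.grown_length == 0 else (s - cum[i]) / seg.grown_length
                p = seg.head.position + f * (seg.tail.position - seg.head.position)
                d = seg.tail.position - seg.head.position
                d = d / np.linalg.norm(d) if np.linalg.norm(d) > 0 else DOWN
                t_pass = seg.head.creation_time + f * (
                    seg.tail.creation_time - seg.head.creation_time)
                return p, d, t_pass
        if self.tip is not None:
            return self.tip.vertex.position.copy(), self.tip.direction.copy(), \
                self.base_time + self.tip.age
        last = self.nodes[-1]
        return last.position.copy(), DOWN.copy(), last.creation_time


# ---------------------------------------------------------------------------
# tip-level operations

def elongate_tip(tip: RootTip, dt: float, growth_multiplier: float = 1.0) -> float:
    """Length increment over dt: table rate integrated over age, times
    vigor and the composed growth multiplier.  Does not move the tip."""
    if growth_multiplier < 0:
        raise ValueError("growth multiplier must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    base = _table_integral(tip.class_params.elongation_rate, tip.age, tip.age + dt)
    return base * tip.vigor * growth_multiplier


def update_direction(tip: RootTip, rng: np.random.Generator,
                     nutrient_vector: np.ndarray | None = None,
                     gravitropism_multiplier: float = 1.0) -> np.ndarray:
    """Tropism update: sum of gravitropic, random-impedance and nutrient
    vectors added to the normalised direction, then renormalised.

    The impedance draw happens whenever the weight is positive, so runs with
    identical seeds stay aligned regardless of multiplier values.  A zero
    resultant keeps the previous direction.
    """
    p = tip.class_params
    d = tip.direction.copy()
    v = d.copy()
    v += p.gravitropism_weight * gravitropism_multiplier * DOWN
    if p.impedance_weight > 0:
        u = rng.standard_normal(3)
        nu = np.linalg.norm(u)
        if nu > 0:
            v += p.impedance_weight * u / nu
    if p.nutrient_tropism_weight > 0 and nutrient_vector is not None:
        v += p.nutrient_tropism_weight * np.asarray(nutrient_vector, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-14:
        return d
    tip.direction = v / n
    return tip.direction


def place_vertex(root: Root, t: float) -> list[RootSegment]:
    """Drop stationary vertices when the tip has grown a full segment length.

    Called after the tip moved; may emit several segments if the last move
    covered more than one segment length.  Each new segment records the true
    grown length it represents.
    """
    tip = root.tip
    if tip is None:
        return []
    seg_len = tip.class_params.segment_length
    if seg_len <= 0:
        raise ValueError("segment_length must be > 0")
    out = []
    while tip.since_vertex >= seg_len - 1e-12:
        frac = seg_len / tip.since_vertex
        prev = root.nodes[-1]
        # vertex at the current tip position when the budget is exhausted;
        # otherwise proportionally along the straight piece just travelled
        new_pos = prev.position + frac * (tip.vertex.position - prev.position)
        t_prev = root.segments[-1].tail.creation_time if root.segments else root.base_time
        t_new = t_prev + frac * ((root.base_time + tip.age) - t_prev)
        node = RootNode(new_pos, t_new)
        seg = RootSegment(
            head=prev, tail=node, grown_length=seg_len,
            diameter_base=root.diameter, diameter_tip=root.diameter,
            root_class=root.params.name, parent_root=root,
            distance_along_root=root.grown_length - tip.since_vertex,
            anatomy=root.params.anatomy)
        root.nodes.append(node)
        root.segments.append(seg)
        tip.since_vertex -= seg_len
        out.append(seg)
    return out


def create_primordia(root: Root, t: float,
                     spacing_multiplier: Callable[[np.ndarray], float] | None = None,
                     branch_rate_multiplier: float = 1.0) -> list["Root"]:
    """Instantiate branch roots along a parent axis.

    Branch positions appear every ``branch_spacing`` cm of grown length (or
    every ``branch_interval`` days converted through the parent growth rate).
    Radial angle of branch k is phi0 + k * 360/n_poles; the axial angle
    separates the branch from the parent direction.  A plasticity multiplier
    (> 1 means denser branching) divides the local spacing.
    """
    p = root.params
    if not p.branch_classes:
        return []
    spacing = p.branch_spacing
    if spacing is None:
        if p.branch_interval is None:
            return []
        # missing spacing computed from the parent growth rate
        rate_now = _interp_table(p.elongation_rate, root.tip.age if root.tip else 0.0)
        spacing = p.branch_interval * rate_now * root.vigor
        if spacing <= 0:
            return []
    new_roots: list[Root] = []
    sys_ = root.system
    if root.next_branch_distance is None:
        root.next_branch_distance = p.basal_nonbranching_zone + spacing
    limit = root.grown_length - p.apical_nonbranching_zone
    guard = 0
    while True:
        s = root.next_branch_distance
        if s > limit + 1e-9:
            break
        pos, pdir, t_pass = root.point_at(s)
        local_spacing = spacing
        if spacing_multiplier is not None:
            m = spacing_multiplier(pos)
            if m > 0:
                local_spacing = spacing / m
        # the allometric cap slows branch formation by widening the spacing
        if branch_rate_multiplier < 1.0:
            local_spacing = local_spacing / max(branch_rate_multiplier, 1e-9)
        birth = t_pass + p.branch_delay
        if birth > t + 1e-12:
            break
        k = len(root.children)
        phi = root.phi0 + k * (2.0 * math.pi / p.n_poles)
        cname = p.branch_classes[k % len(p.branch_classes)]
        cparams = sys_.class_params[cname]
        bdir = _branch_direction(pdir, phi, cparams.axial_branch_angle)
        vigor = sys_.draw_vigor(cparams)
        child = Root(sys_, cparams, pos, bdir, birth, vigor=vigor,
                     parent=root, attach_distance=s, plant_id=root.plant_id)
        root.children.append(child)
        sys_.roots.append(child)
        new_roots.append(child)
        root.next_branch_distance = s + local_spacing
        guard += 1
        if guard > 100000:
            raise RuntimeError("runaway branching; check spacing parameters")
    return new_roots


def _branch_direction(parent_dir: np.ndarray, phi: float,
                      axial_angle_deg: float) -> np.ndarray:
    """Rotate the parent direction by the axial angle toward radial pole phi."""
    d = _normalize(parent_dir)
    # orthonormal basis perpendicular to d
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, d)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = _normalize(np.cross(d, ref))
    e2 = np.cross(d, e1)
    th = math.radians(axial_angle_deg)
    radial = math.cos(phi) * e1 + math.sin(phi) * e2
    return _normalize(math.cos(th) * d + math.sin(th) * radial)


def emit_whorl(system: "RootSystem", spec: WhorlSpec, t: float,
               shoot_ratio: float = 1.0, seed_depth: float = -2.0,
               plant_id: int = 0) -> list[Root]:
    """Adventitious roots from the stem at one whorl position.

    With the shoot-size rule the configured count scales with the ratio of
    actual to potential leaf area (floor-rounded, minimum 0).
    """
    if t < spec.start_time:
        return []
    n = spec.n_roots
    if spec.shoot_size_rule:
        n = max(0, int(math.floor(spec.n_roots * min(1.0, max(0.0, shoot_ratio)))))
    out = []
    cparams = system.class_params[spec.root_class]
    base = np.array([0.0, 0.0, min(0.0, seed_depth + spec.position_on_stem)])
    phi0 = float(system.rng.uniform(0.0, 2.0 * math.pi / max(1, n)))
    for k in range(n):
        phi = phi0 + k * 2.0 * math.pi / n
        # axial angle measured from the upward stem axis
        d = _branch_direction(np.array([0.0, 0.0, 1.0]), phi, spec.axial_angle)
        vigor = system.draw_vigor(cparams)
        r = Root(system, cparams, base, d, t, vigor=vigor, plant_id=plant_id)
        system.roots.append(r)
        out.append(r)
    return out


def secondary_thicken(segment: RootSegment, t: float, dt: float,
                      carbon_multiplier: float = 1.0,
                      distance_scale: Callable[[float], float] | None = None
                      ) -> float:
    """Radial (cambial) growth: diameter grows at twice the radial rate,
    scaled by distance along the root and the carbon multiplier.

    Returns the volume increase (cm^3) so the carbon sink can be charged.
    """
    table = segment.parent_root.params.secondary_growth_rate
    if table is None:
        return 0.0
    rate = _interp_table(table, segment.age(t))
    scale = 1.0
    if distance_scale is not None:
        scale = distance_scale(segment.distance_along_root)
    dd = 2.0 * rate * scale * dt * carbon_multiplier
    v0 = segment.volume()
    segment.diameter_base += dd
    segment.diameter_tip += dd
    return segment.volume() - v0


# ---------------------------------------------------------------------------
# whole system

class RootSystem:
    """All roots of one (or several tillering) plants, plus the RNG."""

    def __init__(self, class_params: dict[str, RootClassParams],
                 seed: int = 0, seed_depth: float = -2.0):
        self.class_params = class_params
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)
        self.roots: list[Root] = []
        self.seed_depth = seed_depth
        self.time = 0.0
        self.fired_whorls: set[int] = set()
        self.tiller_times: list[float] = []

    # -- construction -----------------------------------------------------

    def draw_vigor(self, params: RootClassParams) -> float:
        """Per-root vigor from a lognormal scaled to unit mean."""
        if params.vigor_sigma <= 0:
            return 1.0
        sigma = params.vigor_sigma
        mu = -sigma * sigma / 2.0
        return float(self.rng.lognormal(mu, sigma))

    def add_axis(self, class_name: str, base_position=None, direction=DOWN,
                 base_time: float = 0.0, plant_id: int = 0) -> Root:
        p = self.class_params[class_name]
        if base_position is None:
            base_position = np.array([0.0, 0.0, self.seed_depth])
        vigor = self.draw_vigor(p)
        r = Root(self, p, base_position, direction, base_time,
                 vigor=vigor, plant_id=plant_id)
        self.roots.append(r)
        return r

    # -- stepping ---------------------------------------------------------

    def grow(self, dt: float,
             growth_multiplier: Callable[[Root], float] | None = None,
             spacing_multiplier: Callable[[np.ndarray], float] | None = None,
             gravitropism_multiplier: Callable[[np.ndarray], float] | None = None,
             branch_rate_multiplier: float = 1.0,
             whorls: Sequence[WhorlSpec] = (),
             shoot_ratio: float = 1.0) -> None:
        """Advance architecture by dt days.

        ``growth_multiplier(root)`` composes carbon limitation, nutrient
        stress and plasticity for each root; tropism and branching accept
        optional spatially varying multipliers from the plasticity module.
        """
        t_new = self.time + dt
        for i, spec in enumerate(whorls):
            if i not in self.fired_whorls and t_new >= spec.start_time:
                emit_whorl(self, spec, t_new, shoot_ratio,
                           seed_depth=self.seed_depth)
                self.fired_whorls.add(i)
        # iterate over a snapshot: branching appends new roots which start
        # growing next step (their birth may lie inside this step; they get
        # a partial first step)
        for root in list(self.roots):
            tip = root.tip
            if tip is None:
                continue
            step = dt
            if root.base_time > self.time:
                step = t_new - root.base_time
                if step <= 0:
                    continue
            gm = growth_multiplier(root) if growth_multiplier else 1.0
            inc = elongate_tip(tip, step, gm)
            grav_m = 1.0
            if gravitropism_multiplier is not None:
                grav_m = gravitropism_multiplier(tip.vertex.position)
            update_direction(tip, self.rng, gravitropism_multiplier=grav_m)
            tip.vertex.position = tip.vertex.position + inc * tip.direction
            tip.age += step
            tip.vertex.creation_time = root.base_time + tip.age
            tip.since_vertex += inc
            root.grown_length += inc
            place_vertex(root, t_new)
            create_primordia(root, t_new, spacing_multiplier,
                             branch_rate_multiplier)
        self.time = t_new

    # -- queries ----------------------------------------------------------

    def iter_segments(self, include_tip: bool = True) -> Iterator[RootSegment]:
        """All segments; optionally with a synthetic final segment per live
        tip so that totals account for growth not yet committed to a vertex."""
        for root in self.roots:
            yield from root.segments
            if include_tip and root.tip is not None and root.tip.since_vertex > 1e-12:
                tip = root.tip
                head = root.nodes[-1]
                tail = RootNode(tip.vertex.position.copy(),
                                root.base_time + tip.age)
                yield RootSegment(
                    head=head, tail=tail, grown_length=tip.since_vertex,
                    diameter_base=root.diameter, diameter_tip=root.diameter,
                    root_class=root.params.name, parent_root=root,
                    distance_along_root=root.grown_length - tip.since_vertex,
                    anatomy=root.params.anatomy)

    def total_length(self) -> float:
        return sum(r.grown_length for r in self.roots)


def form_tillers(system: RootSystem, spec: TillerSpec, t: float,
                 make_tiller: Callable[[float], None]) -> int:
    """Fire tiller formation events due by time t.

    The delay table gives the time-dependent wait until the next tiller;
    ``make_tiller(t_event)`` builds the new sub-plant (own leaf area and
    root axes, shared carbon/nutrient pools).  Returns the number formed.
    """
    formed = 0
    last = system.tiller_times[-1] if system.tiller_times else 0.0
    while True:
        delay = _interp_table(spec.delay_table, last)
        if not math.isfinite(delay) or delay <= 0:
            break
        nxt = last + delay
        if nxt > t + 1e-12:
            break
        make_tiller(nxt)
        system.tiller_times.append(nxt)
        last = nxt
        formed += 1
    return formed
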