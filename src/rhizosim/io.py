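"""Input and output: XML parameter documents, VTK export, tables,
predefined root architectures and fixture generation.

Parameter documents are hierarchical XML in a small declared dialect:

``SimulaConstant``
    a single value; attribute ``type`` may be ``string``, ``integer``,
    ``bool`` or ``double`` (default)
``SimulaTable``
    whitespace-separated ``time value`` pairs
``SimulaStochastic``
    a distribution name plus parameters, drawn once at instantiation
``SimulaDerivative``
    a registered function name, computed on request
``SimulaVariable``
    an ODE state with a rate function, an integration function and an
    initial value
``SimulaBase``
    a plain grouping container providing hierarchy/context

Every element carries ``name`` and (for physical quantities) ``unit``.
Unknown element tags are fatal.  ``dump_state`` writes a canonical form for
which parse -> dump is a byte-level fixed point.
"""

from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass
from xml.etree import ElementTree as ET

import numpy as np

from .engine import (ConfigurationError, StateVariable, StateVariableTree,
                     evaluate_at)

__all__ = [
    "parse_parameters", "dump_state", "write_vtk", "read_vtk_polylines",
    "write_tables", "PredefinedRoot", "load_predefined", "generate_fixture",
    "FIXTURE_KINDS",
]

_SIMULA_TAGS = ("SimulaConstant", "SimulaTable", "SimulaStochastic",
                "SimulaDerivative", "SimulaVariable", "SimulaBase")


# ---------------------------------------------------------------------------
# parsing

def parse_parameters(doc: str, seed: int = 0,
                     global_max_dt: float = 0.1) -> StateVariableTree:
    """Parse a parameter document (XML text) into a state-variable tree."""
    try:
        root_el = ET.fromstring(doc)
    except ET.ParseError as exc:
        raise ConfigurationError(f"malformed XML: {exc}") from exc
    root_var = StateVariable(root_el.get("name", "root"), "constant", "-", 0.0,
                             value_type="group")
    for child in root_el:
        root_var.add(_parse_element(child))
    tree = StateVariableTree(root_var, seed=seed, global_max_dt=global_max_dt)
    tree.validate_registry()
    return tree


def _parse_element(el: ET.Element) -> StateVariable:
    tag = el.tag
    if tag not in _SIMULA_TAGS:
        raise ConfigurationError(
            f"unknown element <{tag}>; the dialect accepts: "
            + ", ".join(_SIMULA_TAGS))
    name = el.get("name")
    if not name:
        raise ConfigurationError(f"<{tag}> without a name attribute")
    unit = el.get("unit", "-")
    text = (el.text or "").strip()
    if tag == "SimulaBase":
        var = StateVariable(name, "constant", unit, 0.0, value_type="group")
    elif tag == "SimulaConstant":
        vtype = el.get("type", "double")
        if vtype == "string":
            var = StateVariable(name, "constant", unit, text,
                                value_type="string")
        else:
            if unit == "-" and vtype == "double" and el.get("unit") is None:
                warnings.warn(
                    f"constant {name!r} has no unit; assuming dimensionless",
                    stacklevel=2)
            try:
                value = {"integer": int, "bool": lambda s: s.lower() == "true"
                         }.get(vtype, float)(text)
            except ValueError:
                raise ConfigurationError(
                    f"constant {name!r}: cannot parse value {text!r}") from None
            var = StateVariable(name, "constant", unit, value, value_type=vtype)
    elif tag == "SimulaTable":
        nums = text.split()
        if len(nums) < 2 or len(nums) % 2:
            raise ConfigurationError(
                f"table {name!r}: need an even number of entries, got {len(nums)}")
        try:
            vals = [float(x) for x in nums]
        except ValueError:
            raise ConfigurationError(
                f"table {name!r}: non-numeric entry in {text!r}") from None
        pairs = list(zip(vals[::2], vals[1::2]))
        var = StateVariable(name, "table", unit, table=pairs)
    elif tag == "SimulaStochastic":
        dist = el.get("distribution", "lognormal")
        params = {k: float(v) for k, v in el.attrib.items()
                  if k not in ("name", "unit", "distribution")}
        var = StateVariable(name, "stochastic", unit,
                            distribution=(dist, params))
    elif tag == "SimulaDerivative":
        fn = el.get("function")
        if not fn:
            raise ConfigurationError(f"derivative {name!r} needs a function")
        var = StateVariable(name, "derived", unit, rate_function=fn)
    else:  # SimulaVariable
        fn = el.get("function")
        intfn = el.get("integrationFunction", "RungeKutta4")
        if not fn:
            raise ConfigurationError(f"variable {name!r} needs a function")
        try:
            init = float(text) if text else 0.0
        except ValueError:
            raise ConfigurationError(
                f"variable {name!r}: bad initial value {text!r}") from None
        var = StateVariable(name, "integrated", unit, value=init,
                            rate_function=fn, integration_method=intfn)
    for sub in el:
        var.add(_parse_element(sub))
    return var


# ---------------------------------------------------------------------------
# canonical dump

def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, int):
        return str(v)
    return repr(float(v))


def dump_state(tree: StateVariableTree) -> str:
    """Serialise the tree back to the input dialect in canonical form.

    Canonical means: fixed attribute order, shortest-round-trip float
    formatting, two-space indentation — so parse(dump(x)) == x and
    dump(parse(dump(x))) is byte-identical.
    """
    buf = _stdio.StringIO()
    buf.write(f'<SimulationModel name="{tree.root.name}" unit="-">\n')
    for child in tree.root.children.values():
        _dump_var(buf, child, 1)
    buf.write("</SimulationModel>\n")
    return buf.getvalue()


def _dump_var(buf, var: StateVariable, depth: int) -> None:
    pad = "  " * depth
    unit_attr = f' unit="{var.unit}"'
    if var.kind == "constant" and var.value_type == "group":
        buf.write(f'{pad}<SimulaBase name="{var.name}"{unit_attr}>\n')
        for c in var.children.values():
            _dump_var(buf, c, depth + 1)
        buf.write(f"{pad}</SimulaBase>\n")
        return
    if var.kind == "constant":
        type_attr = "" if var.value_type == "double" \
            else f' type="{var.value_type}"'
        text = var.value if var.value_type == "string" else _fmt(var.value)
        open_tag = f'{pad}<SimulaConstant name="{var.name}"{type_attr}{unit_attr}>'
        if var.children:
            buf.write(open_tag + f"{text}\n")
            for c in var.children.values():
                _dump_var(buf, c, depth + 1)
            buf.write(f"{pad}</SimulaConstant>\n")
        else:
            buf.write(open_tag + f"{text}</SimulaConstant>\n")
        return
    if var.kind == "table":
        text = " ".join(f"{_fmt(t)} {_fmt(v)}" for t, v in var.table)
        buf.write(f'{pad}<SimulaTable name="{var.name}"{unit_attr}>'
                  f"{text}</SimulaTable>\n")
        return
    if var.kind == "stochastic":
        dist, params = var.distribution
        attrs = "".join(f' {k}="{_fmt(v)}"' for k, v in sorted(params.items()))
        buf.write(f'{pad}<SimulaStochastic name="{var.name}"'
                  f' distribution="{dist}"{attrs}{unit_attr}/>\n')
        return
    if var.kind == "derived":
        buf.write(f'{pad}<SimulaDerivative name="{var.name}"'
                  f' function="{var.rate_function}"{unit_attr}>\n')
        for c in var.children.values():
            _dump_var(buf, c, depth + 1)
        buf.write(f"{pad}</SimulaDerivative>\n")
        return
    # integrated
    init = var.timetable[0][1] if var.timetable else var.value
    buf.write(f'{pad}<SimulaVariable name="{var.name}"'
              f' function="{var.rate_function}"'
              f' integrationFunction="{var.integration_method}"{unit_attr}>'
              f"{_fmt(init)}")
    if var.children:
        buf.write("\n")
        for c in var.children.values():
            _dump_var(buf, c, depth + 1)
        buf.write(f"{pad}</SimulaVariable>\n")
    else:
        buf.write("</SimulaVariable>\n")


# ---------------------------------------------------------------------------
# VTK export (legacy ASCII polydata)


def write_vtk(rs, path, fields=("age", "diameter", "class")) -> None:
    """Write the root system as legacy ASCII VTK polydata.

    One polyline per root; per-point arrays carry node age and local
    diameter, a per-cell array carries a numeric root-class id.
    """
    points: list[np.ndarray] = []
    ages: list[float] = []
    diams: list[float] = []
    lines: list[list[int]] = []
    class_ids: list[int] = []
    classes = sorted({r.params.name for r in rs.roots})
    cid = {c: i for i, c in enumerate(classes)}
    for root in rs.roots:
        ids = []
        verts = list(root.nodes)
        if root.tip is not None and root.tip.since_vertex > 1e-12:
            verts.append(root.tip.vertex)
        for node in verts:
            ids.append(len(points))
            points.append(node.position)
            ages.append(rs.time - node.creation_time)
            diams.append(root.diameter)
        if len(ids) >= 2:
            lines.append(ids)
            class_ids.append(cid[root.params.name])
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("root system architecture\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for p in points:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        size = sum(len(l) + 1 for l in lines)
        fh.write(f"LINES {len(lines)} {size}\n")
        for l in lines:
            fh.write(" ".join([str(len(l))] + [str(i) for i in l]) + "\n")
        if points and ("age" in fields or "diameter" in fields):
            fh.write(f"POINT_DATA {len(points)}\n")
            if "age" in fields:
                fh.write("SCALARS age float 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{a:.6f}" for a in ages) + "\n")
            if "diameter" in fields:
                fh.write("SCALARS diameter float 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{d:.6f}" for d in diams) + "\n")
        if lines and "class" in fields:
            fh.write(f"CELL_DATA {len(lines)}\n")
            fh.write("SCALARS class_id int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(str(c) for c in class_ids) + "\n")


def read_vtk_polylines(path):
    """Minimal legacy-VTK polydata reader (points + lines), used for
    round-trip verification and for consuming files from other tools."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    points = []
    lines = []
    i = 0
    while i < len(tokens):
        t = tokens[i].split()
        if t and t[0] == "POINTS":
            n = int(t[1])
            for j in range(n):
                i += 1
                points.append([float(x) for x in tokens[i].split()])
        elif t and t[0] == "LINES":
            n = int(t[1])
            for j in range(n):
                i += 1
                vals = [int(x) for x in tokens[i].split()]
                lines.append(vals[1:1 + vals[0]])
        i += 1
    return np.array(points), lines


# ---------------------------------------------------------------------------
# tables

def write_tables(tree: StateVariableTree, variables, times, path) -> None:
    """CSV time series of the requested variables, with unit headers."""
    import pandas as pd
    from .engine import resolve_reference
    cols = {}
    for name in variables:
        try:
            var = resolve_reference(tree, tree.root, name)
        except ConfigurationError:
            candidates = [v.name for v in tree.root.walk()
                          if name.lower() in v.name.lower()]
            raise ConfigurationError(
                f"no variable {name!r}; nearest matches: {candidates}") from None
        cols[f"{var.name} ({var.unit})"] = [
            evaluate_at(var, t, tree) for t in times]
    df = pd.DataFrame({"time (day)": list(times), **cols})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# predefined architectures

@dataclass
class PredefinedRoot:
    """One measured root axis: an ordered polyline, optionally timestamped."""
    points: np.ndarray                       # (n, 3) cm
    root_class: str = "root"
    times: list[float] | None = None         # per-point, days
    parent: int | None = None                # index into the roots list
    attach_arc: float = 0.0                  # cm along the parent polyline
    observation_time: float = 14.0           # d, when the tip was imaged


def load_predefined(roots: list[PredefinedRoot], class_params,
                    lateral_delay: float = 2.0, seed: int = 0):
    """Build a static root system from measured polylines.

    When per-point timestamps are missing, node times are estimated from
    topology: a lateral's base time is the parent's passage time at the
    attachment point plus the lateral emergence delay; within a root, times
    interpolate linearly in arc length between the base time and the
    observation time at the tip.
    """
    from .architecture import Root, RootNode, RootSegment, RootSystem

    # cycle check: parents must form a DAG (indices referring backwards
    # or forwards but never circular)
    state = {}

    def visit(i):
        if state.get(i) == 1:
            raise ConfigurationError("cyclic root topology in predefined input")
        if state.get(i) == 2:
            return
        state[i] = 1
        p = roots[i].parent
        if p is not None:
            visit(p)
        state[i] = 2

    for i in range(len(roots)):
        visit(i)

    order = _topo_order(roots)   # parents first, transitively

    rs = RootSystem(class_params, seed=seed)
    built: dict[int, Root] = {}
    node_times: dict[int, np.ndarray] = {}

    for i in order:
        pr = roots[i]
        pts = np.asarray(pr.points, dtype=float)
        seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
        if pr.times is not None:
            times = np.asarray(pr.times, dtype=float)
        else:
            if pr.parent is None:
                base_time = 0.0
            else:
                parent = roots[pr.parent]
                ptimes = node_times[pr.parent]
                ppts = np.asarray(parent.points, dtype=float)
                parc = np.concatenate(
                    [[0.0], np.cumsum(np.linalg.norm(np.diff(ppts, axis=0),
                                                     axis=1))])
                passage = float(np.interp(pr.attach_arc, parc, ptimes))
                base_time = passage + lateral_delay
            times = base_time + (pr.observation_time - base_time) * (
                arc / arc[-1] if arc[-1] > 0 else arc)
        node_times[i] = times

        params = class_params[pr.root_class]
        r = Root.__new__(Root)
        r.system = rs
        r.params = params
        r.parent = built.get(pr.parent) if pr.parent is not None else None
        r.attach_distance = pr.attach_arc
        r.plant_id = 0
        r.base_time = float(times[0])
        r.vigor = 1.0
        r.phi0 = 0.0
        r.diameter = params.initial_diameter
        r.nodes = [RootNode(p, float(t)) for p, t in zip(pts, times)]
        r.segments = []
        r.children = []
        r.next_branch_distance = None
        dist = 0.0
        for a, b, L in zip(r.nodes[:-1], r.nodes[1:], seglen):
            r.segments.append(RootSegment(
                head=a, tail=b, grown_length=float(L),
                diameter_base=params.initial_diameter,
                diameter_tip=params.initial_diameter,
                root_class=pr.root_class, parent_root=r,
                distance_along_root=dist, anatomy=params.anatomy))
            dist += float(L)
        r.grown_length = dist
        r.tip = None      # static: growth may be resumed by giving it a tip
        built[i] = r
        rs.roots.append(r)
    rs.time = max(float(node_times[i][-1]) for i in node_times) if roots else 0.0
    return rs


def _topo_order(roots):
    seen: set[int] = set()
    order: list[int] = []

    def visit(i):
        if i in seen:
            return
        p = roots[i].parent
        if p is not None:
            visit(p)
        seen.add(i)
        order.append(i)

    for i in range(len(roots)):
        visit(i)
    return order


# ---------------------------------------------------------------------------
# fixture generation

FIXTURE_KINDS = ("minimal", "dicot_like", "monocot_like",
                 "plasticity_demo", "hydro_demo")

_MINIMAL = """<SimulationModel name="minimal">
  <SimulaDerivative name="rootGrowthRate" function="usePath" unit="cm/day">
    <SimulaConstant name="path" type="string">rootGrowth</SimulaConstant>
    <SimulaConstant name="multiplier" unit="1/day">0.1</SimulaConstant>
  </SimulaDerivative>
  <SimulaVariable name="rootGrowth" function="useName+Rate" integrationFunction="RungeKutta4" unit="cm">1.0</SimulaVariable>
</SimulationModel>
"""


def generate_fixture(kind: str, seed: int = 0) -> str:
    """Emit a complete, runnable parameter document of the given kind.

    ``minimal`` is the two-variable relative-growth model; the other kinds
    are small but complete plant/soil scenarios.  The output is a
    deterministic function of (kind, seed).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    if kind == "minimal":
        return _MINIMAL

    parts = [f'<SimulationModel name="{kind}">']
    parts.append(f"""  <SimulaBase name="simulation">
    <SimulaConstant name="duration" unit="day">10.0</SimulaConstant>
    <SimulaConstant name="timeStep" unit="day">0.1</SimulaConstant>
    <SimulaConstant name="randomSeed" type="integer">{seed}</SimulaConstant>
  </SimulaBase>""")

    monocot = kind == "monocot_like"
    primary = "primary" if monocot else "taproot"
    # the plasticity scenario is deliberately source-limited (low light,
    # small seed reserve, vigorous laterals): branch roots must compete
    # for carbon for the branching-density / lateral-length trade-off to
    # be expressed
    limited = kind == "plasticity_demo"
    light = 4.0 if limited else 12.0
    seed_c = 0.03 if limited else 0.08
    parts.append(f"""  <SimulaBase name="plant">
    <SimulaConstant name="seedDepth" unit="cm">-2.0</SimulaConstant>
    <SimulaConstant name="primaryAxes" type="string">{primary}</SimulaConstant>
    <SimulaConstant name="seedCarbonReserve" unit="gC">{seed_c}</SimulaConstant>
    <SimulaConstant name="specificRootVolume" unit="g/cm3">0.05</SimulaConstant>
    <SimulaConstant name="carbonFraction" unit="gC/g">0.4</SimulaConstant>
    <SimulaConstant name="allocationRule" type="string">priority</SimulaConstant>
    <SimulaConstant name="recoveryRate" unit="-">0.1</SimulaConstant>
    <SimulaConstant name="initialLeafArea" unit="cm2">2.0</SimulaConstant>
    <SimulaTable name="potentialLeafArea" unit="cm2">0.0 2.0 10.0 120.0 30.0 900.0</SimulaTable>
    <SimulaTable name="specificLeafArea" unit="cm2/g">0.0 220.0 30.0 180.0</SimulaTable>
    <SimulaTable name="partitioningLeaf">0.0 0.45 30.0 0.4</SimulaTable>
    <SimulaTable name="partitioningStem">0.0 0.15 30.0 0.25</SimulaTable>
    <SimulaConstant name="radiationUseEfficiency" unit="gC/MJ">2.2</SimulaConstant>
    <SimulaConstant name="extinctionCoefficient" unit="-">0.65</SimulaConstant>
    <SimulaConstant name="plantDensity" unit="plants/m2">25.0</SimulaConstant>
    <SimulaConstant name="dailyLight" unit="MJ/m2/day">{light}</SimulaConstant>
    <SimulaConstant name="respirationRate" unit="gC/cm3/day">0.0008</SimulaConstant>
    <SimulaConstant name="exudationRate" unit="gC/cm/day">2e-06</SimulaConstant>""")
    if not monocot:
        parts.append("""    <SimulaBase name="whorls">
      <SimulaBase name="whorl0">
        <SimulaConstant name="startTime" unit="day">2.0</SimulaConstant>
        <SimulaConstant name="positionOnStem" unit="cm">0.5</SimulaConstant>
        <SimulaConstant name="nRoots" type="integer">3</SimulaConstant>
        <SimulaConstant name="rootClass" type="string">basal</SimulaConstant>
      </SimulaBase>
    </SimulaBase>""")
    if monocot:
        parts.append("""    <SimulaTable name="tillerDelay" unit="day">0.0 4.0 20.0 6.0</SimulaTable>
    <SimulaBase name="whorls">
      <SimulaBase name="whorl0">
        <SimulaConstant name="startTime" unit="day">4.0</SimulaConstant>
        <SimulaConstant name="positionOnStem" unit="cm">1.5</SimulaConstant>
        <SimulaConstant name="nRoots" type="integer">4</SimulaConstant>
        <SimulaConstant name="rootClass" type="string">nodal</SimulaConstant>
      </SimulaBase>
    </SimulaBase>""")
    parts.append("  </SimulaBase>")

    # root classes
    def root_class(name, elong, diam, spacing=None, branches=None,
                   grav=0.8, imp=0.25, vigor=0.2, npoles=4, delay=2.0,
                   secondary=None, seglen=0.5):
        s = [f'    <SimulaBase name="{name}">',
             f'      <SimulaTable name="elongationRate" unit="cm/day">{elong}</SimulaTable>',
             f'      <SimulaConstant name="initialDiameter" unit="cm">{diam}</SimulaConstant>',
             f'      <SimulaConstant name="segmentLength" unit="cm">{seglen}</SimulaConstant>',
             f'      <SimulaConstant name="gravitropism" unit="-">{grav}</SimulaConstant>',
             f'      <SimulaConstant name="impedance" unit="-">{imp}</SimulaConstant>',
             f'      <SimulaConstant name="vigorSigma" unit="-">{vigor}</SimulaConstant>',
             f'      <SimulaConstant name="nPoles" type="integer">{npoles}</SimulaConstant>',
             f'      <SimulaConstant name="axialBranchAngle" unit="degrees">80.0</SimulaConstant>']
        if spacing is not None:
            s.append(f'      <SimulaConstant name="branchSpacing" unit="cm">{spacing}</SimulaConstant>')
            s.append(f'      <SimulaConstant name="branchDelay" unit="day">{delay}</SimulaConstant>')
        if branches:
            s.append(f'      <SimulaConstant name="branchClasses" type="string">{branches}</SimulaConstant>')
        if secondary:
            s.append(f'      <SimulaTable name="secondaryGrowthRate" unit="cm/day">{secondary}</SimulaTable>')
        s.append("    </SimulaBase>")
        return "\n".join(s)

    parts.append('  <SimulaBase name="rootClasses">')
    if monocot:
        parts.append(root_class("primary", "0.0 2.5 10.0 2.0 30.0 1.2", 0.09,
                                spacing=0.8, branches="lateral"))
        parts.append(root_class("nodal", "0.0 2.2 30.0 1.5", 0.11,
                                spacing=1.0, branches="lateral", grav=0.35))
        parts.append(root_class("lateral", "0.0 1.0 8.0 0.3 20.0 0.05", 0.03,
                                grav=0.15, imp=0.35, vigor=0.35, seglen=0.4))
    else:
        parts.append(root_class("taproot", "0.0 2.5 10.0 2.0 30.0 1.2", 0.12,
                                spacing=0.8, branches="lateral",
                                secondary="0.0 0.0005 30.0 0.0005"))
        parts.append(root_class("basal", "0.0 1.8 30.0 1.0", 0.07,
                                spacing=1.2, branches="lateral", grav=0.25))
        if limited:
            parts.append(root_class("lateral", "0.0 2.5 10.0 1.0 20.0 0.2",
                                    0.045, grav=0.15, imp=0.35, vigor=0.35,
                                    seglen=0.4))
        else:
            parts.append(root_class("lateral", "0.0 1.0 8.0 0.3 20.0 0.05",
                                    0.03, grav=0.15, imp=0.35, vigor=0.35,
                                    seglen=0.4))
    parts.append("  </SimulaBase>")

    if kind == "plasticity_demo":
        parts.append("""  <SimulaBase name="plasticity">
    <SimulaConstant name="target" type="string">branch_spacing</SimulaConstant>
    <SimulaConstant name="environmentVariable" type="string">phosphorus</SimulaConstant>
    <SimulaTable name="responseCurve">0.0 0.4 1.0 1.0 3.0 2.2</SimulaTable>
    <SimulaTable name="phosphorusDepthProfile" unit="umol/cm3">0.0 3.0 12.0 3.0 18.0 0.3 60.0 0.3</SimulaTable>
  </SimulaBase>""")

    if kind == "hydro_demo":
        parts.append("""  <SimulaBase name="soil">
    <SimulaConstant name="nx" type="integer">8</SimulaConstant>
    <SimulaConstant name="ny" type="integer">8</SimulaConstant>
    <SimulaConstant name="nz" type="integer">10</SimulaConstant>
    <SimulaConstant name="dx" unit="cm">5.0</SimulaConstant>
    <SimulaConstant name="dy" unit="cm">5.0</SimulaConstant>
    <SimulaConstant name="dz" unit="cm">5.0</SimulaConstant>
    <SimulaConstant name="initialHydraulicHead" unit="cm">-300.0</SimulaConstant>
    <SimulaBase name="vanGenuchten">
      <SimulaConstant name="thetaR" unit="-">0.05</SimulaConstant>
      <SimulaConstant name="thetaS" unit="-">0.45</SimulaConstant>
      <SimulaConstant name="alpha" unit="1/cm">0.02</SimulaConstant>
      <SimulaConstant name="n" unit="-">1.8</SimulaConstant>
      <SimulaConstant name="Ks" unit="cm/day">50.0</SimulaConstant>
    </SimulaBase>
    <SimulaConstant name="radialConductivity" unit="cm/day/cm">5e-05</SimulaConstant>
    <SimulaConstant name="axialConductance" unit="cm4/day">0.05</SimulaConstant>
    <SimulaBase name="weather">
      <SimulaConstant name="netRadiation" unit="MJ/m2/day">14.0</SimulaConstant>
      <SimulaConstant name="temperature" unit="C">22.0</SimulaConstant>
      <SimulaConstant name="relativeHumidity" unit="%">55.0</SimulaConstant>
      <SimulaConstant name="windSpeed" unit="m/s">2.0</SimulaConstant>
      <SimulaConstant name="surfaceResistance" unit="s/m">70.0</SimulaConstant>
    </SimulaBase>
  </SimulaBase>""")
        parts.append("""  <SimulaBase name="nutrients">
    <SimulaBase name="nitrate">
      <SimulaConstant name="mobility" type="string">grid_solute</SimulaConstant>
      <SimulaConstant name="Imax" unit="umol/cm2/day">5.0</SimulaConstant>
      <SimulaConstant name="Km" unit="umol/cm3">0.05</SimulaConstant>
      <SimulaConstant name="Cmin" unit="umol/cm3">0.0</SimulaConstant>
      <SimulaConstant name="seedReserve" unit="umol">270.0</SimulaConstant>
      <SimulaConstant name="initialConcentration" unit="umol/cm3">1.2</SimulaConstant>
      <SimulaConstant name="diffusionCoefficient" unit="cm2/day">1.6</SimulaConstant>
      <SimulaConstant name="dispersivity" unit="cm">0.5</SimulaConstant>
      <SimulaTable name="optimalConcentration" unit="umol/g">0.0 1500.0 30.0 1000.0</SimulaTable>
      <SimulaTable name="minimalConcentration" unit="umol/g">0.0 700.0 30.0 500.0</SimulaTable>
    </SimulaBase>
  </SimulaBase>""")
    elif kind not in ("minimal", "plasticity_demo"):
        # plasticity_demo senses a static field; no nutrient model needed
        parts.append("""  <SimulaBase name="nutrients">
    <SimulaBase name="phosphorus">
      <SimulaConstant name="mobility" type="string">barber_cushman</SimulaConstant>
      <SimulaConstant name="Imax" unit="umol/cm2/day">0.26</SimulaConstant>
      <SimulaConstant name="Km" unit="umol/cm3">0.003</SimulaConstant>
      <SimulaConstant name="Cmin" unit="umol/cm3">0.0002</SimulaConstant>
      <SimulaConstant name="seedReserve" unit="umol">25.0</SimulaConstant>
      <SimulaConstant name="initialConcentration" unit="umol/cm3">0.01</SimulaConstant>
      <SimulaConstant name="bufferPower" unit="-">150.0</SimulaConstant>
      <SimulaConstant name="diffusionCoefficient" unit="cm2/day">0.8</SimulaConstant>
      <SimulaTable name="optimalConcentration" unit="umol/g">0.0 100.0 30.0 80.0</SimulaTable>
      <SimulaTable name="minimalConcentration" unit="umol/g">0.0 40.0 30.0 30.0</SimulaTable>
    </SimulaBase>
  </SimulaBase>""")

    parts.append("</SimulationModel>")
    return "\n".join(parts) + "\n"
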