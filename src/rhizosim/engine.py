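"""Hierarchical state-variable tree and time integration.

The simulator couples many small models ("minimodels"), each of which owns a
single named state variable with a unit.  Variables are arranged in a tree
that mirrors the structure of the input document: parameter lists for a root
class live under that class, plant-level pools under the plant, and so on.
The tree is also the coupling substrate — a variable can reference another
one by a path, and rate functions pull their inputs through such references.

Variable kinds
--------------
constant    a single value, evaluable at any time
table       a piecewise-linear interpolation table over time
stochastic  a value drawn once at instantiation from a seeded distribution
derived     computed on demand by a registered rate function
integrated  an ODE state advanced by a registered integration scheme
            (classic Runge-Kutta 4 by default) and recorded in a timetable

Integrated variables keep a timetable of (time, value) pairs so that any
historical value can be interpolated; all integrated variables in a tree are
advanced together, synchronised at every global maximum time step.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "EvaluationError",
    "StateVariable",
    "StateVariableTree",
    "Template",
    "ObjectGenerator",
    "SpacedGenerator",
    "resolve_reference",
    "evaluate_at",
    "advance",
    "spawn_children",
]

#: default global synchronisation step, days
DEFAULT_GLOBAL_MAX_DT = 0.1
#: hard floor for the adaptive sub-step, days
MIN_DT = 1e-4
#: relative predictor/corrector agreement required to accept a step
DEFAULT_STEP_TOLERANCE = 1e-3
#: consecutive step rejections tolerated before giving up
MAX_STEP_REJECTIONS = 40

KINDS = ("constant", "table", "stochastic", "derived", "integrated")


class ConfigurationError(ValueError):
    """A fatal problem in the declared model structure."""


class EvaluationError(RuntimeError):
    """A request that the declared model cannot answer."""


class StateVariable:
    """One named state variable with a unit, possibly with children.

    Parameters
    ----------
    name:
        Identifier, unique among siblings.
    kind:
        One of ``constant``, ``table``, ``stochastic``, ``derived``,
        ``integrated``.
    unit:
        Unit string; ``"-"`` marks a dimensionless quantity.
    value:
        The value of a constant, or the initial value of an integrated
        variable.
    table:
        Sequence of ``(time, value)`` pairs (strictly increasing times) for
        kind ``table``.
    rate_function:
        Registered function name for ``derived`` and ``integrated`` kinds.
    integration_method:
        Registered integration scheme name (``integrated`` only).
    distribution:
        ``(name, params)`` for ``stochastic``, e.g.
        ``("lognormal", {"mean": 1.0, "sigma": 0.3})``.
    """

    __slots__ = (
        "name", "kind", "unit", "value", "table", "rate_function",
        "integration_method", "distribution", "children", "parent",
        "creation_time", "timetable", "value_type", "generator",
    )

    def __init__(
        self,
        name: str,
        kind: str = "constant",
        unit: str = "-",
        value=None,
        table: Sequence[tuple[float, float]] | None = None,
        rate_function: str | None = None,
        integration_method: str = "RungeKutta4",
        distribution: tuple[str, dict] | None = None,
        value_type: str = "double",
    ):
        if kind not in KINDS:
            raise ConfigurationError(f"unknown variable kind {kind!r} for {name!r}")
        if kind == "constant" and value is None:
            raise ConfigurationError(f"constant {name!r} needs exactly one value")
        if kind == "integrated" and value is None:
            raise ConfigurationError(f"integrated {name!r} needs an initial value")
        if kind == "table":
            if not table:
                raise ConfigurationError(f"table {name!r} is empty")
            times = [t for t, _ in table]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ConfigurationError(
                    f"table {name!r}: times must be strictly increasing")
        self.name = name
        self.kind = kind
        self.unit = unit
        self.value = value
        self.value_type = value_type
        self.table = [(float(t), float(v)) for t, v in table] if table else None
        self.rate_function = rate_function
        self.integration_method = integration_method
        self.distribution = distribution
        self.children: dict[str, StateVariable] = {}
        self.parent: StateVariable | None = None
        self.creation_time = 0.0
        # recorded (t, value) history for integrated variables
        self.timetable: list[tuple[float, float]] = []
        self.generator: ObjectGenerator | None = None

    # -- tree plumbing ----------------------------------------------------

    def add(self, child: "StateVariable") -> "StateVariable":
        if child.name in self.children:
            raise ConfigurationError(
                f"duplicate sibling name {child.name!r} under {self.path()!r}")
        child.parent = self
        self.children[child.name] = child
        return child

    def child(self, name: str) -> "StateVariable":
        try:
            return self.children[name]
        except KeyError:
            raise ConfigurationError(
                f"{self.path()!r} has no child named {name!r}") from None

    def path(self) -> str:
        parts = []
        node: StateVariable | None = self
        while node is not None and node.parent is not None:
            parts.append(node.name)
            node = node.parent
        return "/" + "/".join(reversed(parts))

    def walk(self) -> Iterator["StateVariable"]:
        yield self
        for c in self.children.values():
            yield from c.walk()

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<StateVariable {self.path()} kind={self.kind} unit={self.unit}>"


@dataclass
class Template:
    """A prototype subtree instantiated on demand by a generator.

    Instantiation deep-copies the prototype so copies never alias prototype
    state.
    """

    prototype: StateVariable

    def instantiate(self, name: str, t: float) -> StateVariable:
        inst = copy.deepcopy(self.prototype)
        inst.name = name
        inst.parent = None
        for v in inst.walk():
            v.creation_time = t
        return inst


class ObjectGenerator:
    """Creates new children of a variable when its trigger fires.

    Subclasses implement :meth:`count_due`, returning how many instances
    should exist at time ``t``.  ``spawn_children`` instantiates the missing
    ones from the template, which makes repeated calls at the same time
    idempotent.
    """

    def __init__(self, template: Template, name_prefix: str = "item"):
        if template.prototype is None:
            raise ConfigurationError("generator template missing a prototype")
        self.template = template
        self.name_prefix = name_prefix
        self.n_created = 0

    def count_due(self, tree: "StateVariableTree", parent: StateVariable,
                  t: float) -> int:
        raise NotImplementedError

    def instance_time(self, tree, parent, index: int, t: float) -> float:
        return t


class SpacedGenerator(ObjectGenerator):
    """Trigger: one instance per ``spacing`` units of a referenced variable.

    The canonical use is branch roots appearing every *spacing* cm along a
    growing parent axis: ``count_due = floor(length / spacing)``.
    """

    def __init__(self, template: Template, length_path: str, spacing: float,
                 name_prefix: str = "branch"):
        super().__init__(template, name_prefix)
        if spacing <= 0:
            raise ConfigurationError("generator spacing must be > 0")
        self.length_path = length_path
        self.spacing = spacing

    def count_due(self, tree, parent, t):
        ref = resolve_reference(tree, parent, self.length_path)
        length = evaluate_at(ref, t, tree)
        return int(math.floor(length / self.spacing + 1e-12))


class StateVariableTree:
    """The whole model: a root variable, a function registry and a clock."""

    def __init__(
        self,
        root: StateVariable | None = None,
        global_max_dt: float = DEFAULT_GLOBAL_MAX_DT,
        step_tolerance: float = DEFAULT_STEP_TOLERANCE,
        seed: int = 0,
    ):
        if global_max_dt <= 0:
            raise ConfigurationError("global_max_dt must be > 0")
        self.root = root if root is not None else StateVariable("root", "constant", "-", 0.0)
        self.rate_registry: dict[str, Callable] = dict(_BUILTIN_RATES)
        self.integration_registry: dict[str, str] = {
            "RungeKutta4": "rk4", "ForwardEuler": "euler", "Heun": "heun"}
        self.global_max_dt = float(global_max_dt)
        self.step_tolerance = float(step_tolerance)
        self.global_clock = 0.0
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)
        # stage overrides used during RK sub-stage evaluation
        self._stage_values: dict[int, float] | None = None
        self._stage_time: float | None = None
        self._init_states()

    # -- registry ---------------------------------------------------------

    def register_rate(self, name: str, fn: Callable) -> None:
        """Extension point: add a named rate function.

        ``fn(tree, var, t) -> float`` may pull inputs from other variables
        through :func:`resolve_reference` / :func:`evaluate_at`.
        """
        self.rate_registry[name] = fn

    def rate(self, name: str) -> Callable:
        try:
            return self.rate_registry[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown function {name!r}; registry contains: "
                + ", ".join(sorted(self.rate_registry))) from None

    # -- lifecycle --------------------------------------------------------

    def _init_states(self) -> None:
        for v in self.root.walk():
            if v.kind == "integrated" and not v.timetable:
                v.timetable.append((v.creation_time, float(v.value)))
            if v.kind == "stochastic" and v.value is None:
                v.value = _draw(self.rng, v)
            if v.kind in ("derived", "integrated"):
                if v.rate_function is None:
                    raise ConfigurationError(
                        f"{v.path()!r} (kind={v.kind}) has no rate function")
            if v.kind == "integrated" and v.integration_method not in self.integration_registry:
                raise ConfigurationError(
                    f"{v.path()!r}: unknown integration method "
                    f"{v.integration_method!r}")

    def validate_registry(self) -> None:
        """Fail loudly when any declared function name is unregistered."""
        for v in self.root.walk():
            if v.kind in ("derived", "integrated"):
                self.rate(v.rate_function)

    def integrated_variables(self) -> list[StateVariable]:
        return [v for v in self.root.walk() if v.kind == "integrated"]


# ---------------------------------------------------------------------------
# reference resolution

def resolve_reference(tree: StateVariableTree, origin: StateVariable,
                      path: str) -> StateVariable:
    """Resolve a path to a variable.

    Absolute paths (leading ``/``) are walked from the tree root.  Relative
    paths are searched from ``origin`` upward through its ancestors; the
    nearest enclosing scope whose children contain the first path component
    wins.  Sibling names are unique by construction, so resolution is
    deterministic.
    """
    parts = [p for p in path.split("/") if p]
    if not parts:
        raise ConfigurationError(f"empty path requested from {origin.path()!r}")
    if path.startswith("/"):
        node = tree.root
        for p in parts:
            if p not in node.children:
                raise ConfigurationError(
                    f"unresolved absolute path {path!r} (from {origin.path()!r}): "
                    f"{node.path()!r} has no child {p!r}")
            node = node.children[p]
        return node
    scope: StateVariable | None = origin
    while scope is not None:
        if parts[0] in scope.children:
            node = scope.children[parts[0]]
            for p in parts[1:]:
                if p not in node.children:
                    raise ConfigurationError(
                        f"unresolved path {path!r} from {origin.path()!r}: "
                        f"{node.path()!r} has no child {p!r}")
                node = node.children[p]
            return node
        scope = scope.parent
    raise ConfigurationError(
        f"unresolved path {path!r} from origin {origin.path()!r}")


# ---------------------------------------------------------------------------
# evaluation

def _interp(table: Sequence[tuple[float, float]], t: float) -> float:
    """Piecewise-linear interpolation, clamped to the end values.

    Queries within 1e-9 d of a recorded point return the recorded value
    exactly, so historical values are stable against float drift in the
    accumulated step times.
    """
    if t <= table[0][0]:
        return table[0][1]
    if t >= table[-1][0] - 1e-9:
        return table[-1][1]
    times = [p[0] for p in table]
    i = int(np.searchsorted(times, t, side="right")) - 1
    t0, v0 = table[i]
    if abs(t - t0) <= 1e-9:
        return v0
    t1, v1 = table[i + 1]
    if abs(t - t1) <= 1e-9:
        return v1
    return v0 + (v1 - v0) * (t - t0) / (t1 - t0)


def evaluate_at(var: StateVariable, t: float,
                tree: StateVariableTree | None = None) -> float:
    """Value of ``var`` at time ``t`` (days).

    Constants, tables and stochastic draws are evaluable at any time.
    Derived variables call their rate function.  Integrated variables are
    linearly interpolated from the recorded timetable; during an integration
    sub-stage the stage value is used instead, and a request slightly past
    the last record returns a linear extrapolation (the predictor value).
    """
    if var.kind == "constant" or var.kind == "stochastic":
        return float(var.value)
    if var.kind == "table":
        return _interp(var.table, t)
    if var.kind == "derived":
        if tree is None:
            raise EvaluationError(
                f"derived variable {var.path()!r} needs a tree context")
        return float(tree.rate(var.rate_function)(tree, var, t))
    # integrated
    if t < var.creation_time - 1e-12:
        raise EvaluationError(
            f"{var.path()!r} requested at t={t} before its creation time "
            f"{var.creation_time}")
    if tree is not None and tree._stage_values is not None:
        ov = tree._stage_values.get(id(var))
        if ov is not None and t >= var.timetable[-1][0] - 1e-15:
            return ov
    tt = var.timetable
    if t <= tt[-1][0] + 1e-12:
        return _interp(tt, t)
    # beyond the recorded history: linear extrapolation (predictor)
    if len(tt) >= 2:
        (t0, v0), (t1, v1) = tt[-2], tt[-1]
        return v1 + (v1 - v0) * (t - t1) / (t1 - t0)
    return tt[-1][1]


# ---------------------------------------------------------------------------
# integration

def _rate_of(tree: StateVariableTree, var: StateVariable, t: float) -> float:
    return float(tree.rate(var.rate_function)(tree, var, t))


def _system_rates(tree: StateVariableTree, ivars: list[StateVariable],
                  t: float, y: np.ndarray) -> np.ndarray:
    """Evaluate all rate functions at a sub-stage with stage values in place."""
    tree._stage_values = {id(v): float(y[i]) for i, v in enumerate(ivars)}
    tree._stage_time = t
    try:
        return np.array([_rate_of(tree, v, t) for v in ivars], dtype=float)
    finally:
        tree._stage_values = None
        tree._stage_time = None


def advance(tree: StateVariableTree, t_target: float) -> StateVariableTree:
    """Advance every integrated variable to ``t_target``.

    The tree steps forward in global steps of at most ``global_max_dt``.
    Within a step all integrated variables form one coupled system advanced
    by their integration scheme (classic RK4 by default); rate functions see
    stage values of interdependent variables.  The corrected end-of-step
    values are compared against the timetable's linear extrapolation
    (the predictor); a step whose relative disagreement exceeds the tree
    tolerance is retried with a halved step, down to a floor, after which
    the step is accepted anyway (the floor marks the resolution limit).
    """
    if t_target < tree.global_clock - 1e-12:
        raise EvaluationError(
            f"cannot advance backwards: clock={tree.global_clock}, "
            f"target={t_target}")
    ivars = tree.integrated_variables()
    if not ivars:
        tree.global_clock = max(tree.global_clock, t_target)
        return tree
    rejections = 0
    while tree.global_clock < t_target - 1e-12:
        dt_global = min(tree.global_max_dt, t_target - tree.global_clock)
        t0 = tree.global_clock
        t_end = t0 + dt_global
        t = t0
        dt = dt_global
        while t < t_end - 1e-13:
            dt = min(dt, t_end - t)
            y0 = np.array([v.timetable[-1][1] for v in ivars])
            y1 = _step(tree, ivars, t, y0, dt)
            # predictor/corrector agreement
            accept = True
            if dt > MIN_DT:
                for i, v in enumerate(ivars):
                    if len(v.timetable) < 2:
                        continue
                    pred = evaluate_at(v, t + dt, tree)
                    scale = max(abs(y1[i]), abs(pred), 1e-12)
                    if abs(y1[i] - pred) / scale > tree.step_tolerance:
                        accept = False
                        break
            if not accept:
                rejections += 1
                if rejections > MAX_STEP_REJECTIONS:
                    raise EvaluationError(
                        "step rejection cascade: predictor disagrees with "
                        f"corrector near t={t:.6g} for one of "
                        f"{[v.path() for v in ivars]}")
                dt = max(dt / 2.0, MIN_DT)
                continue
            rejections = 0
            t += dt
            for i, v in enumerate(ivars):
                v.timetable.append((t, float(y1[i])))
            dt = min(dt * 2.0, dt_global)
        tree.global_clock = t_end
    return tree


def _step(tree, ivars, t, y0, dt) -> np.ndarray:
    method = tree.integration_registry[ivars[0].integration_method]
    f = lambda tt, yy: _system_rates(tree, ivars, tt, yy)
    if method == "euler":
        return y0 + dt * f(t, y0)
    if method == "heun":
        k1 = f(t, y0)
        k2 = f(t + dt, y0 + dt * k1)
        return y0 + dt * (k1 + k2) / 2.0
    # classic RK4
    k1 = f(t, y0)
    k2 = f(t + dt / 2.0, y0 + dt / 2.0 * k1)
    k3 = f(t + dt / 2.0, y0 + dt / 2.0 * k2)
    k4 = f(t + dt, y0 + dt * k3)
    return y0 + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


# ---------------------------------------------------------------------------
# dynamic object creation

def spawn_children(tree: StateVariableTree, parent: StateVariable,
                   t: float) -> list[StateVariable]:
    """Instantiate template copies whose trigger fired by time ``t``.

    Every due instance exists exactly once afterwards; repeated calls at the
    same time create nothing new.  Copies are deep, with their own creation
    times, and never alias the prototype.
    """
    gen = parent.generator
    if gen is None:
        raise ConfigurationError(
            f"{parent.path()!r} has no attached generator")
    due = gen.count_due(tree, parent, t)
    new: list[StateVariable] = []
    while gen.n_created < due:
        idx = gen.n_created
        name = f"{gen.name_prefix}{idx}"
        t_inst = gen.instance_time(tree, parent, idx, t)
        inst = gen.template.instantiate(name, t_inst)
        parent.add(inst)
        for v in inst.walk():
            if v.kind == "stochastic" and v.value is None:
                v.value = _draw(tree.rng, v)
            if v.kind == "integrated" and not v.timetable:
                v.timetable.append((v.creation_time, float(v.value)))
        gen.n_created += 1
        new.append(inst)
    return new


def _draw(rng: np.random.Generator, var: StateVariable) -> float:
    name, params = var.distribution
    if name == "lognormal":
        # parameterised by arithmetic mean and sigma of log; mean rescaled
        mean = params.get("mean", 1.0)
        sigma = params.get("sigma", 0.3)
        mu = math.log(mean) - sigma ** 2 / 2.0
        return float(rng.lognormal(mu, sigma))
    if name == "uniform":
        return float(rng.uniform(params.get("low", 0.0), params.get("high", 1.0)))
    if name == "normal":
        return float(rng.normal(params.get("mean", 0.0), params.get("sd", 1.0)))
    raise ConfigurationError(
        f"unknown distribution {name!r} for {var.path()!r}")


# ---------------------------------------------------------------------------
# built-in rate functions (the plugin registry's defaults)

def _use_path(tree: StateVariableTree, var: StateVariable, t: float) -> float:
    """Value of the variable named by child ``path``, times child ``multiplier``."""
    path_var = var.child("path")
    target = resolve_reference(tree, var, str(path_var.value))
    mult = 1.0
    if "multiplier" in var.children:
        mult = evaluate_at(var.children["multiplier"], t, tree)
    return evaluate_at(target, t, tree) * mult


def _use_name_rate(tree: StateVariableTree, var: StateVariable, t: float) -> float:
    """Rate pulled from the sibling named ``<name>Rate``."""
    rate_var = resolve_reference(tree, var, var.name + "Rate")
    return evaluate_at(rate_var, t, tree)


def _zero(tree, var, t) -> float:
    return 0.0


_BUILTIN_RATES: dict[str, Callable] = {
    "usePath": _use_path,
    "useName+Rate": _use_name_rate,
    "zero": _zero,
}


def check_unit(var: StateVariable, expected: str) -> None:
    """Fail loudly when a declared unit differs from the expected one.

    Units are carried as strings; there is no automatic conversion.
    """
    if var.unit != expected:
        raise ConfigurationError(
            f"{var.path()!r} declares unit {var.unit!r}, expected {expected!r}")
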