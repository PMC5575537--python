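"""State-variable tree: references, interpolation, integration, templates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhizosim.engine import (ConfigurationError, SpacedGenerator,
                             StateVariable, StateVariableTree, Template,
                             advance, evaluate_at, resolve_reference,
                             spawn_children)


def make_rgr_tree(dt=0.1, rate=0.1, start=1.0, tol=float("inf")):
    """The two-variable relative-growth model: rate = 0.1 x length."""
    root = StateVariable("model", "constant", "-", 0.0, value_type="group")
    deriv = StateVariable("rootGrowthRate", "derived", "cm/day",
                          rate_function="usePath")
    deriv.add(StateVariable("path", "constant", "-", "rootGrowth",
                            value_type="string"))
    deriv.add(StateVariable("multiplier", "constant", "1/day", rate))
    root.add(deriv)
    root.add(StateVariable("rootGrowth", "integrated", "cm", start,
                           rate_function="useName+Rate"))
    tree = StateVariableTree(root, global_max_dt=dt)
    tree.step_tolerance = tol
    return tree


class TestResolveReference:
    def test_relative_sibling_lookup(self):
        tree = make_rgr_tree()
        origin = tree.root.children["rootGrowthRate"]
        target = resolve_reference(tree, origin, "rootGrowth")
        assert target is tree.root.children["rootGrowth"]

    def test_absolute_path(self):
        root = StateVariable("r", "constant", "-", 0.0, value_type="group")
        plant = root.add(StateVariable("plant", "constant", "-", 0.0,
                                       value_type="group"))
        shoot = plant.add(StateVariable("shoot", "constant", "-", 0.0,
                                        value_type="group"))
        la = shoot.add(StateVariable("leafArea", "constant", "cm2", 5.0))
        tree = StateVariableTree(root)
        assert resolve_reference(tree, la, "/plant/shoot/leafArea") is la

    def test_nearest_scope_wins_over_outer_shadow(self):
        # the same name exists at two ancestor levels; the nearer one wins
        root = StateVariable("r", "constant", "-", 0.0, value_type="group")
        outer = root.add(StateVariable("x", "constant", "-", 1.0))
        mid = root.add(StateVariable("mid", "constant", "-", 0.0,
                                     value_type="group"))
        inner = mid.add(StateVariable("x", "constant", "-", 2.0))
        origin = mid.add(StateVariable("origin", "constant", "-", 0.0))
        tree = StateVariableTree(root)
        resolved = resolve_reference(tree, origin, "x")
        # brute-force oracle: walk ancestors from origin, first scope whose
        # children contain the name
        scope = origin
        oracle = None
        while scope is not None and oracle is None:
            oracle = scope.children.get("x")
            scope = scope.parent
        assert resolved is oracle is inner

    def test_unresolved_path_is_fatal_and_names_origin(self):
        tree = make_rgr_tree()
        origin = tree.root.children["rootGrowthRate"]
        with pytest.raises(ConfigurationError, match="rootGrowthRate"):
            resolve_reference(tree, origin, "noSuchThing")

    def test_duplicate_sibling_names_rejected_at_build(self):
        parent = StateVariable("p", "constant", "-", 0.0, value_type="group")
        parent.add(StateVariable("a", "constant", "-", 1.0))
        with pytest.raises(ConfigurationError, match="duplicate"):
            parent.add(StateVariable("a", "constant", "-", 2.0))


class TestEvaluateAt:
    def test_time_dependent_multiplier_table(self):
        var = StateVariable("m", "table", "1/day",
                            table=[(0.0, 0.1), (10.0, 0.05)])
        assert evaluate_at(var, 5.0) == pytest.approx(0.075)

    def test_constant_any_time(self):
        var = StateVariable("c", "constant", "-", 1.0)
        for t in (0.0, 3.7, 100.0):
            assert evaluate_at(var, t) == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=2.0))
    def test_matches_piecewise_linear_oracle(self, t):
        pts = [(0.0, 1.0), (1.0, 3.0), (2.0, 2.0)]
        var = StateVariable("v", "table", "-", table=pts)
        xs, ys = zip(*pts)
        assert evaluate_at(var, t) == pytest.approx(
            float(np.interp(t, xs, ys)), abs=1e-12)

    def test_request_before_creation_time_errors(self):
        var = StateVariable("v", "integrated", "cm", 1.0,
                            rate_function="zero")
        var.creation_time = 5.0
        var.timetable = [(5.0, 1.0)]
        with pytest.raises(Exception, match="before its creation"):
            evaluate_at(var, 2.0)


class TestAdvance:
    def test_relative_growth_matches_exponential(self):
        tree = make_rgr_tree(dt=0.1)
        advance(tree, 10.0)
        got = evaluate_at(tree.root.children["rootGrowth"], 10.0, tree)
        assert got == pytest.approx(math.exp(1.0), rel=1e-6)

    def test_zero_rate_stays_constant(self):
        root = StateVariable("r", "constant", "-", 0.0, value_type="group")
        root.add(StateVariable("v", "integrated", "cm", 3.5,
                               rate_function="zero"))
        tree = StateVariableTree(root)
        advance(tree, 5.0)
        for t in np.linspace(0, 5, 11):
            assert evaluate_at(root.children["v"], t, tree) == 3.5

    def test_harmonic_oscillator(self):
        # x' = y, y' = -x from (1, 0): at t = pi, (x, y) = (-1, 0)
        root = StateVariable("r", "constant", "-", 0.0, value_type="group")
        root.add(StateVariable("x", "integrated", "-", 1.0,
                               rate_function="rate_x"))
        root.add(StateVariable("y", "integrated", "-", 0.0,
                               rate_function="rate_y"))
        tree = StateVariableTree(root, global_max_dt=0.05)
        tree.step_tolerance = float("inf")
        tree.register_rate("rate_x", lambda tr, v, t: evaluate_at(
            resolve_reference(tr, v, "y"), t, tr))
        tree.register_rate("rate_y", lambda tr, v, t: -evaluate_at(
            resolve_reference(tr, v, "x"), t, tr))
        advance(tree, math.pi)
        x = evaluate_at(root.children["x"], math.pi, tree)
        y = evaluate_at(root.children["y"], math.pi, tree)
        assert x == pytest.approx(-1.0, abs=5e-6)
        assert y == pytest.approx(0.0, abs=5e-6)

    def test_fourth_order_convergence(self):
        errors = []
        for dt in (0.4, 0.2, 0.1):
            tree = make_rgr_tree(dt=dt)
            advance(tree, 10.0)
            got = evaluate_at(tree.root.children["rootGrowth"], 10.0, tree)
            errors.append(abs(got - math.exp(1.0)))
        r1 = errors[0] / errors[1]
        r2 = errors[1] / errors[2]
        assert 12.0 < r1 < 20.0
        assert 12.0 < r2 < 20.0

    def test_history_immutable_under_further_advance(self):
        tree = make_rgr_tree()
        advance(tree, 5.0)
        var = tree.root.children["rootGrowth"]
        probes = np.linspace(0, 5, 21)
        before = [evaluate_at(var, t, tree) for t in probes]
        advance(tree, 10.0)
        after = [evaluate_at(var, t, tree) for t in probes]
        assert before == after

    def test_determinism_with_stochastic_variables(self):
        def build(seed):
            root = StateVariable("r", "constant", "-", 0.0,
                                 value_type="group")
            root.add(StateVariable(
                "vigor", "stochastic", "-",
                distribution=("lognormal", {"mean": 1.0, "sigma": 0.3})))
            v = StateVariable("len", "integrated", "cm", 1.0,
                              rate_function="vig")
            root.add(v)
            tree = StateVariableTree(root, seed=seed)
            tree.register_rate("vig", lambda tr, vv, t: evaluate_at(
                resolve_reference(tr, vv, "vigor"), t, tr))
            advance(tree, 3.0)
            return v.timetable
        assert build(42) == build(42)
        assert build(42) != build(43)


class TestSpawnChildren:
    def _generator_parent(self, length_value):
        root = StateVariable("r", "constant", "-", 0.0, value_type="group")
        parent = root.add(StateVariable("axis", "constant", "-", 0.0,
                                        value_type="group"))
        parent.add(StateVariable("length", "constant", "cm", length_value))
        proto = StateVariable("branch", "constant", "-", 0.0,
                              value_type="group")
        proto.add(StateVariable("age", "integrated", "day", 0.0,
                                rate_function="zero"))
        parent.generator = SpacedGenerator(Template(proto), "length", 1.0,
                                           name_prefix="branch")
        return StateVariableTree(root), parent

    def test_branch_count_floor_oracle(self):
        tree, parent = self._generator_parent(10.0)
        new = spawn_children(tree, parent, t=5.0)
        assert len(new) == math.floor(10.0 / 1.0) == 10

    def test_trigger_never_fires(self):
        tree, parent = self._generator_parent(0.5)
        assert spawn_children(tree, parent, t=5.0) == []
        assert list(parent.children) == ["length"]

    def test_idempotent_at_same_time(self):
        tree, parent = self._generator_parent(4.0)
        spawn_children(tree, parent, t=2.0)
        again = spawn_children(tree, parent, t=2.0)
        assert again == []
        assert sum(1 for c in parent.children if c.startswith("branch")) == 4

    def test_copies_do_not_alias_prototype(self):
        tree, parent = self._generator_parent(2.0)
        new = spawn_children(tree, parent, t=1.0)
        proto = parent.generator.template.prototype
        new[0].children["age"].timetable.append((9.0, 9.0))
        assert proto.children["age"].timetable == []
        assert new[1].children["age"].timetable != \
            new[0].children["age"].timetable
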