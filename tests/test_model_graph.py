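"""Decision-tree rollback and Markov cohort engine, against brute-force oracles."""

import itertools

import numpy as np
import pytest

from skincost.model_graph import (
    COMPLEMENT,
    EXIT_STATE,
    Branch,
    Chance,
    MarkovState,
    ModelError,
    PathwayModel,
    Terminal,
    Transition,
    expected_cost,
    run_cohort,
    validate_model,
)
from skincost.parameters import Kind, ParameterSet, ParameterSpec


def _param_set(**values):
    specs = []
    for name, value in values.items():
        kind = Kind.PROBABILITY if name.startswith("p") else Kind.COST
        specs.append(ParameterSpec(name, kind, value))
    return ParameterSet.from_specs(specs)


def _single_state_model(cost_ref, transitions=(), horizon=5):
    return PathwayModel(
        name="single",
        root=Terminal("enter", state="alive"),
        states={
            "alive": MarkovState("alive", annual_costs=[cost_ref], transitions=list(transitions)),
            "gone": MarkovState("gone"),
        },
        horizon_years=horizon,
    )


class TestValidation:
    def test_well_formed_two_state_model_passes(self):
        model = _single_state_model("c", [Transition("gone", "p_exit")])
        report = validate_model(model, _param_set(c=100.0, p_exit=0.2))
        assert report.ok

    def test_probability_sum_violation_detected(self):
        model = PathwayModel(
            name="bad",
            root=Chance(
                "choice",
                branches=[
                    Branch(0.6, Terminal("a", costs=[10.0])),
                    Branch(0.5, Terminal("b", costs=[20.0])),
                ],
            ),
        )
        report = validate_model(model, _param_set())
        assert not report.ok
        assert any("sum to" in v for v in report.violations)

    def test_unresolved_reference_detected(self):
        model = _single_state_model("cost_missing")
        report = validate_model(model, _param_set())
        assert any("unresolved" in v for v in report.violations)

    def test_unreachable_absorbing_state_detected(self):
        model = PathwayModel(
            name="loop",
            root=Terminal("enter", state="a"),
            states={
                "a": MarkovState("a", transitions=[Transition("b", 1.0)]),
                "b": MarkovState("b", transitions=[Transition("a", 1.0)]),
            },
        )
        report = validate_model(model, _param_set())
        assert any("absorbing" in v for v in report.violations)


class TestExpectedCost:
    def test_single_state_accumulates_annual_cost(self):
        model = _single_state_model("c")
        result = expected_cost(model, _param_set(c=100.0))
        assert result.total == pytest.approx(500.0)
        assert result.year1 == pytest.approx(100.0)

    def test_chance_node_probability_weighted(self):
        model = PathwayModel(
            name="tree",
            root=Chance(
                "choice",
                branches=[
                    Branch("p", Terminal("a", costs=["c1"])),
                    Branch(COMPLEMENT, Terminal("b", costs=["c2"])),
                ],
            ),
            horizon_years=1,
        )
        result = expected_cost(model, _param_set(p=0.3, c1=100.0, c2=40.0))
        assert result.year1 == pytest.approx(0.3 * 100 + 0.7 * 40)

    def test_two_state_exit_closed_form(self):
        q = 0.23
        model = _single_state_model(0.0, [Transition("gone", q)], horizon=6)
        trace = run_cohort(model, _param_set())
        alive = trace.occupancy[:, trace.states.index("alive")]
        expected = [(1 - q) ** t for t in range(6)]
        assert alive == pytest.approx(expected, abs=1e-12)

    def test_horizon_below_one_rejected(self):
        with pytest.raises(ModelError):
            run_cohort(_single_state_model(1.0), _param_set(), horizon=0)

    def test_cost_linearity_and_monotonicity(self):
        model = _single_state_model("c", [Transition("gone", 0.1)])
        params = _param_set(c=100.0)
        base = expected_cost(model, params).total
        double = expected_cost(model, params.replace_value("c", 200.0)).total
        assert double == pytest.approx(2 * base)
        assert double >= base


# ---------------------------------------------------------------------------
# brute-force path-enumeration oracle


def _random_model(rng, max_states=4):
    n = rng.integers(2, max_states + 1)
    names = [f"s{i}" for i in range(n)]
    states = {}
    for i, name in enumerate(names):
        transitions = []
        if i < n - 1:  # last state absorbing
            budget = 1.0
            for j in rng.permutation(n):
                if rng.random() < 0.5 and budget > 0.05:
                    p = float(rng.uniform(0.05, budget * 0.8))
                    budget -= p
                    transitions.append(
                        Transition(names[j], p, counts_as_entry=bool(rng.random() < 0.5))
                    )
        states[name] = MarkovState(
            name,
            annual_costs=[float(rng.uniform(0, 100))],
            entry_costs=[float(rng.uniform(0, 50))],
            transitions=transitions,
        )
    # small chance tree over entry states
    leaves = [
        Terminal(f"leaf{i}", costs=[float(rng.uniform(0, 200))], state=names[i % n])
        for i in range(2)
    ]
    p = float(rng.uniform(0.1, 0.9))
    root = Chance("root", branches=[Branch(p, leaves[0]), Branch(COMPLEMENT, leaves[1])])
    return PathwayModel(name="random", root=root, states=states)


def _oracle_expected_cost(model, horizon):
    """Exhaustive enumeration of tree paths and Markov edge sequences."""

    def tree_paths(node):
        if isinstance(node, Terminal):
            cost = sum(node.costs)
            yield 1.0, cost, node.state or EXIT_STATE
            return
        probs = []
        residual = 1.0
        for br in node.branches:
            if br.probability is COMPLEMENT:
                probs.append(None)
            else:
                probs.append(float(br.probability))
                residual -= float(br.probability)
        for prob, br in zip(probs, node.branches):
            prob = residual if prob is None else prob
            for p, c, s in tree_paths(br.node):
                yield prob * p, sum(node.costs) + sum(br.costs) + c, s

    def edges_from(state_name):
        st = model.states.get(state_name)
        if st is None:
            return [(state_name, 1.0, False)]
        explicit = [(t.target, float(t.probability), t.counts_as_entry) for t in st.transitions]
        residual = 1.0 - sum(p for _, p, _ in explicit)
        return explicit + [(state_name, residual, False)]

    def annual(state_name):
        st = model.states.get(state_name)
        return sum(st.annual_costs) if st is not None else 0.0

    def entry(state_name):
        st = model.states.get(state_name)
        return sum(st.entry_costs) if st is not None else 0.0

    total = 0.0
    for tree_p, tree_c, entry_state in tree_paths(model.root):
        # enumerate edge sequences of length horizon-1
        stack = [(entry_state, tree_p, tree_c + entry(entry_state) + annual(entry_state), 1)]
        while stack:
            state, prob, cost, cycle = stack.pop()
            if cycle == horizon:
                total += prob * cost
                continue
            for target, p, is_entry in edges_from(state):
                if p <= 0.0:
                    continue
                step_cost = annual(target) + (entry(target) if is_entry else 0.0)
                stack.append((target, prob * p, cost + step_cost, cycle + 1))
    return total


@pytest.mark.parametrize("seed", range(20))
def test_expected_cost_matches_path_enumeration(seed):
    """Engine equals exhaustive path enumeration on small random models."""
    rng = np.random.default_rng(seed)
    model = _random_model(rng)
    horizon = int(rng.integers(1, 5))
    engine = expected_cost(model, {}, horizon=horizon)
    oracle = _oracle_expected_cost(model, horizon)
    assert engine.total == pytest.approx(oracle, rel=1e-10)


@pytest.mark.parametrize("seed", range(20))
def test_cohort_occupancy_conserved(seed):
    """Occupancy fractions sum to one at every cycle for valid models."""
    rng = np.random.default_rng(seed + 1000)
    model = _random_model(rng)
    trace = run_cohort(model, {}, horizon=int(rng.integers(1, 8)))
    assert trace.occupancy.sum(axis=1) == pytest.approx(
        np.ones(trace.occupancy.shape[0]), abs=1e-12
    )
    # cumulative cost never decreases
    assert np.all(np.diff(trace.cumulative_cost) >= -1e-12)
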