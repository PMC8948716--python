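"""Generic decision-tree plus Markov cohort costing engine.

A :class:`PathwayModel` is a decision tree (chance nodes with probability
references, terminal nodes carrying one-off costs) whose terminals place the
cohort into Markov states.  The Markov part is then run in annual cycles:
state costs accrue at cycle start for everyone occupying the state, and
transitions apply at cycle end, so year 1 equals the tree-rollback cost plus
the first cycle's state costs.  No discounting and no half-cycle correction
are applied over the 5-year horizon.

References to parameter values are symbolic: a ``str`` names an entry in a
:class:`~skincost.parameters.ParameterSet`; :class:`Scaled`, :class:`Product`
and :class:`OneMinus` build simple arithmetic on references; :class:`Subtree`
resolves to the rolled-back expected cost of a named tree node (used for
repeat-lesion episodes); :data:`COMPLEMENT` marks the residual branch of a
chance node so sibling probabilities always sum to one.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "COMPLEMENT",
    "EXIT_STATE",
    "Scaled",
    "Product",
    "OneMinus",
    "Subtree",
    "Branch",
    "Chance",
    "Terminal",
    "Transition",
    "MarkovState",
    "PathwayModel",
    "CohortTrace",
    "ExpectedCost",
    "ModelError",
    "ValidationReport",
    "validate_model",
    "run_cohort",
    "expected_cost",
    "referenced_parameters",
]


class _Complement:
    """Sentinel: the residual probability of a chance node's last branch."""

    def __repr__(self) -> str:  # pragma: no cover
        return "COMPLEMENT"


COMPLEMENT = _Complement()

#: Implicit zero-cost absorbing state receiving tree terminals with no state.
EXIT_STATE = "_exit"


@dataclass(frozen=True)
class Scaled:
    """A reference multiplied by a constant factor (e.g. two visits a year)."""

    ref: "Ref"
    factor: float


@dataclass(frozen=True)
class Product:
    """The product of two references (e.g. unit cost x calibration scale)."""

    a: "Ref"
    b: "Ref"


@dataclass(frozen=True)
class OneMinus:
    """One minus a reference (e.g. the year-2 share of therapy scripts)."""

    ref: "Ref"


@dataclass(frozen=True)
class Subtree:
    """Rolled-back expected cost of the named tree node, at current values."""

    node: str


Ref = Union[float, int, str, Scaled, Product, OneMinus, Subtree]


@dataclass
class Terminal:
    """Tree leaf: one-off costs, then entry into a Markov state (or exit)."""

    name: str
    costs: Sequence[Ref] = ()
    state: str | None = None


@dataclass
class Branch:
    probability: Ref | _Complement
    node: "Node"
    costs: Sequence[Ref] = ()


@dataclass
class Chance:
    """Chance node: costs accrued by everyone reaching it, then branching."""

    name: str
    branches: Sequence[Branch]
    costs: Sequence[Ref] = ()


Node = Union[Terminal, Chance]


@dataclass(frozen=True)
class Transition:
    """Annual outflow from a Markov state.

    ``counts_as_entry`` controls whether arrivals pay the target state's entry
    cost; explicit self-loops with ``counts_as_entry=True`` model repeat
    episodes (a new lesion each cycle).  Residual probability stays in the
    state without an entry charge.
    """

    target: str
    probability: Ref
    counts_as_entry: bool = True


@dataclass
class MarkovState:
    """Annual-cycle health state.

    ``annual_costs`` is either a flat sequence of cost references (accrued
    every cycle) or a mapping ``{cycle: refs}`` with the key ``"*"`` as the
    default for unlisted cycles; cycles are 1-based.  ``entry_costs`` are paid
    once per entering cohort fraction (including initial placement from the
    tree).  A state with no transitions is absorbing.
    """

    name: str
    annual_costs: Sequence[Ref] | Mapping = ()
    entry_costs: Sequence[Ref] = ()
    transitions: Sequence[Transition] = ()

    def cycle_costs(self, cycle: int) -> Sequence[Ref]:
        if isinstance(self.annual_costs, Mapping):
            if cycle in self.annual_costs:
                return self.annual_costs[cycle]
            return self.annual_costs.get("*", ())
        return self.annual_costs

    @property
    def absorbing(self) -> bool:
        return not self.transitions


@dataclass
class PathwayModel:
    """Decision tree plus Markov states over an annual-cycle horizon."""

    name: str
    root: Node
    states: dict[str, MarkovState] = field(default_factory=dict)
    aux: dict[str, Node] = field(default_factory=dict)
    horizon_years: int = 5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._node_index: dict[str, Node] | None = None

    def nodes(self) -> dict[str, Node]:
        """All tree nodes by name (main tree plus auxiliary subtrees)."""
        if self._node_index is None:
            index: dict[str, Node] = {}

            def walk(node: Node) -> None:
                if index.get(node.name) is node:
                    return
                if node.name in index:
                    raise ModelError(f"duplicate node name {node.name!r}")
                index[node.name] = node
                if isinstance(node, Chance):
                    for br in node.branches:
                        walk(br.node)

            walk(self.root)
            for node in self.aux.values():
                walk(node)
            self._node_index = index
        return self._node_index

    def state_order(self) -> list[str]:
        return list(self.states) + [EXIT_STATE]


class ModelError(ValueError):
    """Structural or reference error in a pathway model."""


# ---------------------------------------------------------------------------
# evaluation


def _resolve(ref: Ref, values: Mapping[str, float], model: PathwayModel) -> float:
    if isinstance(ref, (int, float)):
        return float(ref)
    if isinstance(ref, str):
        try:
            return values[ref]
        except KeyError:
            raise ModelError(f"unresolved parameter reference {ref!r}") from None
    if isinstance(ref, Scaled):
        return ref.factor * _resolve(ref.ref, values, model)
    if isinstance(ref, Product):
        return _resolve(ref.a, values, model) * _resolve(ref.b, values, model)
    if isinstance(ref, OneMinus):
        return 1.0 - _resolve(ref.ref, values, model)
    if isinstance(ref, Subtree):
        try:
            node = model.nodes()[ref.node]
        except KeyError:
            raise ModelError(f"unknown subtree node {ref.node!r}") from None
        return _rollback(node, values, model)[0]
    raise ModelError(f"unsupported reference {ref!r}")


def _cost_sum(refs: Sequence[Ref], values, model) -> float:
    return sum(_resolve(r, values, model) for r in refs)


def _branch_probabilities(
    node: Chance, values: Mapping[str, float], model: PathwayModel
) -> list[float]:
    explicit = [
        None if isinstance(br.probability, _Complement) else _resolve(br.probability, values, model)
        for br in node.branches
    ]
    n_compl = sum(p is None for p in explicit)
    if n_compl > 1:
        raise ModelError(f"node {node.name!r} has more than one complement branch")
    total = sum(p for p in explicit if p is not None)
    if n_compl:
        residual = 1.0 - total
        if residual < 0.0:
            # extreme tail draws of sibling shares can overshoot 1; the
            # complement scheme clamps to the simplex by renormalising
            explicit = [0.0 if p is None else p / total for p in explicit]
        else:
            explicit = [residual if p is None else p for p in explicit]
    return explicit


def _rollback(
    node: Node, values: Mapping[str, float], model: PathwayModel
) -> tuple[float, dict[str, float]]:
    """Expected one-off cost and Markov entry distribution below ``node``."""
    if isinstance(node, Terminal):
        cost = _cost_sum(node.costs, values, model)
        state = node.state if node.state is not None else EXIT_STATE
        return cost, {state: 1.0}
    cost = _cost_sum(node.costs, values, model)
    entry: dict[str, float] = {}
    probs = _branch_probabilities(node, values, model)
    for p, br in zip(probs, node.branches):
        if p == 0.0:
            continue
        child_cost, child_entry = _rollback(br.node, values, model)
        cost += p * (child_cost + _cost_sum(br.costs, values, model))
        for state, mass in child_entry.items():
            entry[state] = entry.get(state, 0.0) + p * mass
    return cost, entry


@dataclass
class CohortTrace:
    """Per-cycle occupancy and cost accumulation for a cohort of 1.0."""

    states: list[str]
    occupancy: np.ndarray  # (horizon, n_states), at cycle start
    cycle_costs: np.ndarray  # (horizon,), state + entry costs per cycle
    cumulative_cost: np.ndarray  # (horizon,), running total incl. tree cost
    tree_cost: float


@dataclass
class ExpectedCost:
    """Expected cost per year and cumulatively for one pathway model."""

    year_costs: np.ndarray  # year 1 includes the tree-rollback cost
    tree_cost: float
    trace: CohortTrace

    @property
    def year1(self) -> float:
        return float(self.year_costs[0])

    @property
    def total(self) -> float:
        return float(self.year_costs.sum())

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.year_costs)


def _values_of(params) -> Mapping[str, float]:
    if isinstance(params, ParameterSet):
        return params.point_values()
    return params


def run_cohort(
    model: PathwayModel, params, horizon: int | None = None
) -> CohortTrace:
    """Propagate the cohort through the Markov states, accruing costs.

    ``params`` is a :class:`ParameterSet` (evaluated at point estimates) or a
    plain ``{name: value}`` mapping (e.g. one Monte Carlo draw).
    """
    values = _values_of(params)
    horizon = model.horizon_years if horizon is None else horizon
    if horizon < 1:
        raise ModelError(f"horizon must be >= 1, got {horizon!r}")

    tree_cost, entry = _rollback(model.root, values, model)
    order = model.state_order()
    index = {name: i for i, name in enumerate(order)}
    for state in entry:
        if state not in index:
            raise ModelError(f"terminal refers to unknown state {state!r}")

    n = len(order)
    occ = np.zeros(n)
    for state, mass in entry.items():
        occ[index[state]] += mass

    def state_obj(name: str) -> MarkovState | None:
        return model.states.get(name)

    # values are fixed for the whole evaluation: resolve each state's entry
    # cost (which may roll back a whole episode subtree) and per-cycle costs
    # at most once
    _cycle_cache: dict[tuple[str, int], float] = {}
    _entry_cache: dict[str, float] = {}

    def cycle_state_cost(vec: np.ndarray, cycle: int) -> float:
        total = 0.0
        for name, i in index.items():
            if vec[i] == 0.0:
                continue
            st = state_obj(name)
            if st is None:
                continue
            key = (name, cycle)
            if key not in _cycle_cache:
                _cycle_cache[key] = _cost_sum(st.cycle_costs(cycle), values, model)
            total += vec[i] * _cycle_cache[key]
        return total

    def entry_cost_of(name: str) -> float:
        if name not in _entry_cache:
            st = state_obj(name)
            _entry_cache[name] = (
                _cost_sum(st.entry_costs, values, model) if st is not None else 0.0
            )
        return _entry_cache[name]

    occupancy = np.zeros((horizon, n))
    cycle_costs = np.zeros(horizon)

    occupancy[0] = occ
    cycle_costs[0] = cycle_state_cost(occ, 1) + sum(
        mass * entry_cost_of(state) for state, mass in entry.items()
    )

    for t in range(2, horizon + 1):
        new = np.zeros(n)
        entry_charge = 0.0
        for name, i in index.items():
            mass = occ[i]
            if mass == 0.0:
                continue
            st = state_obj(name)
            if st is None or not st.transitions:
                new[i] += mass
                continue
            outflow = 0.0
            for tr in st.transitions:
                p = _resolve(tr.probability, values, model)
                if p < -1e-12 or p > 1.0 + 1e-9:
                    raise ModelError(
                        f"state {name!r}: transition probability {p:.6g} outside [0, 1]"
                    )
                j = index.get(tr.target)
                if j is None:
                    raise ModelError(
                        f"state {name!r}: unknown transition target {tr.target!r}"
                    )
                flow = mass * p
                new[j] += flow
                outflow += p
                if tr.counts_as_entry:
                    entry_charge += flow * entry_cost_of(tr.target)
            if outflow > 1.0 + 1e-9:
                raise ModelError(
                    f"state {name!r}: outgoing probabilities sum to {outflow:.6g} > 1"
                )
            new[i] += mass * max(1.0 - outflow, 0.0)
        occ = new
        occupancy[t - 1] = occ
        cycle_costs[t - 1] = cycle_state_cost(occ, t) + entry_charge

    cumulative = tree_cost + np.cumsum(cycle_costs)
    return CohortTrace(
        states=order,
        occupancy=occupancy,
        cycle_costs=cycle_costs,
        cumulative_cost=cumulative,
        tree_cost=tree_cost,
    )


def expected_cost(
    model: PathwayModel, params, horizon: int | None = None
) -> ExpectedCost:
    """Per-year and cumulative expected cost: tree rollback plus cohort trace."""
    trace = run_cohort(model, params, horizon)
    year_costs = trace.cycle_costs.copy()
    year_costs[0] += trace.tree_cost
    return ExpectedCost(year_costs=year_costs, tree_cost=trace.tree_cost, trace=trace)


# ---------------------------------------------------------------------------
# validation


def _iter_refs(model: PathwayModel):
    """Yield every Ref in the model (tree, aux, states)."""

    def from_node(node: Node):
        yield from node.costs
        if isinstance(node, Chance):
            for br in node.branches:
                if not isinstance(br.probability, _Complement):
                    yield br.probability
                yield from br.costs
                yield from from_node(br.node)

    yield from from_node(model.root)
    for node in model.aux.values():
        yield from from_node(node)
    for st in model.states.values():
        if isinstance(st.annual_costs, Mapping):
            for refs in st.annual_costs.values():
                yield from refs
        else:
            yield from st.annual_costs
        yield from st.entry_costs
        for tr in st.transitions:
            yield tr.probability


def _ref_names(ref: Ref) -> set[str]:
    if isinstance(ref, str):
        return {ref}
    if isinstance(ref, Scaled):
        return _ref_names(ref.ref)
    if isinstance(ref, OneMinus):
        return _ref_names(ref.ref)
    if isinstance(ref, Product):
        return _ref_names(ref.a) | _ref_names(ref.b)
    return set()


def referenced_parameters(model: PathwayModel) -> set[str]:
    """Names of every parameter the model's references resolve through."""
    names: set[str] = set()
    for ref in _iter_refs(model):
        names |= _ref_names(ref)
    return names


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def raise_if_invalid(self) -> None:
        if self.violations:
            raise ModelError("; ".join(self.violations))


def validate_model(model: PathwayModel, params: ParameterSet) -> ValidationReport:
    """Check references, probability sums, targets and absorbing reachability."""
    report = ValidationReport()
    values = params.point_values()

    try:
        nodes = model.nodes()
    except ModelError as exc:
        report.violations.append(str(exc))
        return report

    missing = sorted(referenced_parameters(model) - params.names)
    for name in missing:
        report.violations.append(f"unresolved parameter reference {name!r}")
    if missing:
        return report

    # subtree targets
    for ref in _iter_refs(model):
        if isinstance(ref, Subtree) and ref.node not in nodes:
            report.violations.append(f"unknown subtree node {ref.node!r}")

    # chance-node probability sums at point estimates
    for node in nodes.values():
        if not isinstance(node, Chance):
            continue
        explicit = []
        n_compl = 0
        for br in node.branches:
            if isinstance(br.probability, _Complement):
                n_compl += 1
            else:
                try:
                    explicit.append(_resolve(br.probability, values, model))
                except ModelError as exc:
                    report.violations.append(str(exc))
        if n_compl > 1:
            report.violations.append(
                f"node {node.name!r}: more than one complement branch"
            )
            continue
        if any(p < -1e-9 or p > 1.0 + 1e-9 for p in explicit):
            report.violations.append(
                f"node {node.name!r}: branch probability outside [0, 1]"
            )
        total = sum(explicit)
        if n_compl == 0 and abs(total - 1.0) > 1e-9:
            report.violations.append(
                f"node {node.name!r}: branch probabilities sum to {total:.9g}, not 1"
            )
        if n_compl == 1 and total > 1.0 + 1e-9:
            report.violations.append(
                f"node {node.name!r}: explicit branch probabilities sum to "
                f"{total:.9g} > 1"
            )

    # terminal states exist
    for node in nodes.values():
        if isinstance(node, Terminal) and node.state is not None:
            if node.state not in model.states:
                report.violations.append(
                    f"terminal {node.name!r} enters unknown state {node.state!r}"
                )

    # state rows: targets known, outflow within [0, 1]
    for st in model.states.values():
        outflow = 0.0
        for tr in st.transitions:
            if tr.target != EXIT_STATE and tr.target not in model.states:
                report.violations.append(
                    f"state {st.name!r}: unknown transition target {tr.target!r}"
                )
                continue
            try:
                p = _resolve(tr.probability, values, model)
            except ModelError as exc:
                report.violations.append(str(exc))
                continue
            if p < -1e-9 or p > 1.0 + 1e-9:
                report.violations.append(
                    f"state {st.name!r}: transition probability {p:.6g} outside [0, 1]"
                )
            outflow += p
        if outflow > 1.0 + 1e-9:
            report.violations.append(
                f"state {st.name!r}: outgoing probabilities sum to {outflow:.9g} > 1"
            )

    # every state reaches an absorbing state (structurally)
    absorbing = {EXIT_STATE} | {n for n, st in model.states.items() if st.absorbing}
    for start in model.states:
        seen = {start}
        frontier = [start]
        reached = start in absorbing
        while frontier and not reached:
            current = frontier.pop()
            st = model.states.get(current)
            if st is None:
                continue
            for tr in st.transitions:
                if tr.target in absorbing:
                    reached = True
                    break
                if tr.target not in seen and tr.target in model.states:
                    seen.add(tr.target)
                    frontier.append(tr.target)
        if not reached:
            report.violations.append(
                f"state {start!r} cannot reach any absorbing state"
            )

    return report


def export_graph(model: PathwayModel) -> "pd.DataFrame":
    """Node/edge listing of the model (for inspection), as a tidy frame."""
    import pandas as pd

    rows = []
    for name, node in model.nodes().items():
        kind = "chance" if isinstance(node, Chance) else "terminal"
        rows.append({"element": "node", "name": name, "kind": kind, "target": ""})
        if isinstance(node, Chance):
            for br in node.branches:
                rows.append(
                    {
                        "element": "branch",
                        "name": name,
                        "kind": repr(br.probability),
                        "target": br.node.name,
                    }
                )
        elif node.state is not None:
            rows.append(
                {"element": "entry", "name": name, "kind": "state", "target": node.state}
            )
    for sname, st in model.states.items():
        rows.append({"element": "state", "name": sname, "kind": "markov", "target": ""})
        for tr in st.transitions:
            rows.append(
                {
                    "element": "transition",
                    "name": sname,
                    "kind": repr(tr.probability),
                    "target": tr.target,
                }
            )
    return pd.DataFrame(rows, columns=["element", "name", "kind", "target"])
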