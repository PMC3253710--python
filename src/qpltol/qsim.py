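"""Qualitative simulation of PL models.

Within one regulatory domain every variable converges monotonically toward
its focal point, so the only qualitative events are threshold crossings.  The
engine abstracts these as asynchronous unit steps: a successor state moves
exactly one variable one interval toward its focal interval.  Breadth-first
closure from an initial state yields the state transition graph (STG); a
qualitative steady state is a node with no outgoing edge.

Labels ``s1, s2, ...`` are assigned in breadth-first discovery order purely
for display — they carry no temporal meaning, and positions along a path are
ordinal only.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .model import (
    PLModel,
    QualitativeState,
    focal_position,
)

__all__ = [
    "StateTransitionGraph",
    "enumerate_states",
    "successors",
    "build_stg",
    "steady_states",
    "shortest_path",
    "temporal_profiles",
    "write_dot",
    "write_graphml",
]


def enumerate_states(model: PLModel) -> set[QualitativeState]:
    """Every qualitative state of the model: the Cartesian product of the
    state variables' intervals, inputs pinned at their clamps."""
    names = model.variable_names
    axes = []
    for v in model.variables:
        if v.role == "input":
            axes.append((model.clamps.get(v.name, 0),))
        else:
            axes.append(tuple(range(v.n_intervals)))
    return {QualitativeState(names, combo) for combo in itertools.product(*axes)}


def successors(model: PLModel, state: QualitativeState) -> list[QualitativeState]:
    """Asynchronous unit-step successors, sorted for determinism.

    For each state variable whose focal interval differs from its current
    interval, emit one successor with that variable moved one interval toward
    the focal point.  A state equal to its own focal domain has none — it is
    a qualitative steady state.
    """
    out = []
    for v in model.state_variables:
        eq = model.equation(v.name)
        target = focal_position(eq, state, model)
        cur = state.level(v.name)
        if target != cur:
            step = 1 if target > cur else -1
            out.append(state.with_level(v.name, cur + step))
    return sorted(out)


@dataclass
class StateTransitionGraph:
    """Directed graph over the qualitative states reachable from ``initial``."""

    graph: nx.DiGraph
    initial: QualitativeState
    labels: dict[QualitativeState, str] = field(default_factory=dict)

    @property
    def states(self) -> list[QualitativeState]:
        """Nodes in discovery order."""
        return sorted(self.graph.nodes, key=lambda s: int(self.labels[s][1:]))

    @property
    def steady(self) -> frozenset[QualitativeState]:
        return frozenset(n for n in self.graph.nodes if self.graph.out_degree(n) == 0)

    @property
    def n_states(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_transitions(self) -> int:
        return self.graph.number_of_edges()

    def label(self, state: QualitativeState) -> str:
        return self.labels[state]


def build_stg(model: PLModel, initial: QualitativeState | None = None) -> StateTransitionGraph:
    """Breadth-first closure of :func:`successors` from ``initial`` (default:
    all state variables at interval 0, inputs at their clamps).  Node labels
    s1, s2, ... follow discovery order, so serialization is reproducible."""
    if initial is None:
        initial = model.make_state()
    g = nx.DiGraph()
    g.add_node(initial)
    labels = {initial: "s1"}
    queue = deque([initial])
    while queue:
        state = queue.popleft()
        for nxt in successors(model, state):
            if nxt not in labels:
                labels[nxt] = f"s{len(labels) + 1}"
                queue.append(nxt)
            g.add_edge(state, nxt)
    return StateTransitionGraph(graph=g, initial=initial, labels=labels)


def steady_states(stg: StateTransitionGraph) -> frozenset[QualitativeState]:
    """The out-degree-0 nodes: states lacking a successive stage."""
    return stg.steady


def shortest_path(
    stg: StateTransitionGraph,
    source: QualitativeState | None = None,
    target: QualitativeState | None = None,
) -> list[QualitativeState] | None:
    """A minimum-length directed path from source to target, or ``None`` if
    the target is unreachable.

    Defaults: source = the STG's initial state; target = its unique steady
    state (an error if the steady set is not a singleton).  Among equally
    short paths the lexicographically smallest successor (levels compared in
    declared variable order) is taken at every step, so the choice is
    deterministic.
    """
    if source is None:
        source = stg.initial
    if target is None:
        steadies = stg.steady
        if len(steadies) != 1:
            raise ValueError(
                f"no default target: STG has {len(steadies)} steady states"
            )
        (target,) = steadies
    if source not in stg.graph or target not in stg.graph:
        raise ValueError("source/target not in the state transition graph")
    if source == target:
        return [source]
    # distance-to-target on the reversed graph, then greedy descent
    dist = {target: 0}
    queue = deque([target])
    rev = stg.graph.reverse(copy=False)
    while queue:
        node = queue.popleft()
        for pred in rev.successors(node):
            if pred not in dist:
                dist[pred] = dist[node] + 1
                queue.append(pred)
    if source not in dist:
        return None
    path = [source]
    node = source
    while node != target:
        nxt = min(
            s for s in stg.graph.successors(node)
            if dist.get(s, float("inf")) == dist[node] - 1
        )
        path.append(nxt)
        node = nxt
    return path


def temporal_profiles(path: Sequence[QualitativeState]) -> pd.DataFrame:
    """Per-variable sequence of qualitative levels along a path.

    Returns a DataFrame with a ``path_position`` column (0-based ordinal
    position — positions are consecutive conditions, not points on a clock)
    and one column per variable.
    """
    if not path:
        return pd.DataFrame({"path_position": []})
    names = path[0].names
    data = {"path_position": list(range(len(path)))}
    for name in names:
        data[name] = [s.level(name) for s in path]
    return pd.DataFrame(data)


def first_rise_position(path: Sequence[QualitativeState], variable: str) -> int | None:
    """Ordinal position of the first state where ``variable`` is nonzero, or
    None if it stays at 0 along the whole path."""
    for i, s in enumerate(path):
        if s.level(variable) > 0:
            return i
    return None


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def _dot_quote(text: str) -> str:
    return '"' + text.replace('"', r"\"") + '"'


def write_dot(
    stg: StateTransitionGraph,
    path: str | Path,
    highlight: Sequence[QualitativeState] | None = None,
) -> None:
    """Serialize the STG in DOT format; steady states are doubly circled and
    an optional highlighted path is colored."""
    hl = list(highlight or [])
    hl_edges = set(zip(hl, hl[1:]))
    hl_nodes = set(hl)
    steady = stg.steady
    lines = ["digraph stg {", "  rankdir=LR;"]
    for state in stg.states:
        attrs = [f"label={_dot_quote(stg.label(state))}",
                 f"tooltip={_dot_quote(str(state))}"]
        if state in steady:
            attrs.append("shape=doublecircle")
            attrs.append('steady="true"')
        if state in hl_nodes:
            attrs.append("color=red")
        lines.append(f"  {_dot_quote(stg.label(state))} [{', '.join(attrs)}];")
    for u, v in sorted(stg.graph.edges, key=lambda e: (e[0], e[1])):
        attrs = "color=red" if (u, v) in hl_edges else ""
        suffix = f" [{attrs}]" if attrs else ""
        lines.append(f"  {_dot_quote(stg.label(u))} -> {_dot_quote(stg.label(v))}{suffix};")
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(
    stg: StateTransitionGraph,
    path: str | Path,
    highlight: Sequence[QualitativeState] | None = None,
) -> None:
    """Serialize the STG as GraphML with per-variable level attributes."""
    hl = list(highlight or [])
    hl_edges = set(zip(hl, hl[1:]))
    steady = stg.steady
    g = nx.DiGraph()
    for state in stg.states:
        attrs = {name: int(level) for name, level in state.as_dict().items()}
        g.add_node(
            stg.label(state),
            steady=state in steady,
            on_shortest_path=state in set(hl),
            **attrs,
        )
    for u, v in sorted(stg.graph.edges, key=lambda e: (e[0], e[1])):
        g.add_edge(stg.label(u), stg.label(v), on_shortest_path=(u, v) in hl_edges)
    nx.write_graphml(g, str(path))
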