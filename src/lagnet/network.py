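"""Temporal DAG assembly from stage-wise selection results, plus graph I/O.

Edges connect ``(variable, time)`` nodes and always point forward in time
(earlier measures point towards later measures), so every constructible graph
is acyclic.  Edge weights are the *absolute* refit coefficients — the signed
coefficient is kept as edge metadata, since the sign is needed to sanity-check
the directionality of conditional probabilities downstream.  Variables not
linked to the network are pruned by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .exceptions import TemporalOrderError, UnknownFormatError
from .panel import Node, TemporalOrdering


@dataclass
class TemporalDAG:
    """Weighted DAG over ``(variable, time)`` nodes with a designated outcome."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    outcome: Node | None = None

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Node, Node, float, float]],
        outcome: Node | None = None,
        extra_nodes: Iterable[Node] = (),
        prune_isolated: bool = True,
    ) -> "TemporalDAG":
        """Build a DAG from ``(src, dst, weight, sign)`` tuples.

        Weights must be nonnegative (absolute coefficients); ``sign`` carries
        the direction of the underlying effect.  Edges violating the temporal
        order raise; duplicate edges with conflicting attributes raise.
        """
        g = nx.DiGraph()
        for src, dst, weight, sign in edges:
            src, dst = Node(*src), Node(*dst)
            if src.time >= dst.time:
                raise TemporalOrderError(
                    f"edge {src.label()} -> {dst.label()} does not point forward in time"
                )
            if weight < 0:
                raise ValueError("edge weights are absolute values, got < 0")
            if g.has_edge(src, dst):
                prev = g.edges[src, dst]
                if prev["weight"] != weight or prev["sign"] != sign:
                    raise ValueError(
                        f"conflicting duplicate edge {src.label()} -> {dst.label()}"
                    )
                continue
            g.add_edge(src, dst, weight=float(weight), sign=float(sign))
        for node in extra_nodes:
            g.add_node(Node(*node))
        if outcome is not None:
            outcome = Node(*outcome)
            g.add_node(outcome)
        if prune_isolated:
            keep = outcome
            for node in [n for n in g.nodes if g.degree(n) == 0]:
                if node != keep:
                    g.remove_node(node)
        return cls(graph=g, outcome=outcome)

    # -- views -------------------------------------------------------------
    def nodes(self) -> list[Node]:
        return sorted(self.graph.nodes, key=lambda n: (n.time, n.variable))

    def edges(self) -> list[tuple[Node, Node, float, float]]:
        return sorted(
            (
                (u, v, d["weight"], d["sign"])
                for u, v, d in self.graph.edges(data=True)
            ),
            key=lambda e: (e[0].time, e[0].variable, e[1].time, e[1].variable),
        )

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def parents(self, node: Node) -> list[Node]:
        return sorted(self.graph.predecessors(Node(*node)), key=lambda n: (n.time, n.variable))

    def times(self) -> list[int]:
        return sorted({n.time for n in self.graph.nodes})

    def variables(self) -> list[str]:
        return sorted({n.variable for n in self.graph.nodes})

    def earliest_node_of(self, variable: str) -> Node | None:
        cands = [n for n in self.graph.nodes if n.variable == variable]
        return min(cands, key=lambda n: n.time) if cands else None

    def has_path(self, src: Node, dst: Node) -> bool:
        g = self.graph
        return g.has_node(src) and g.has_node(dst) and nx.has_path(g, src, dst)

    def edge_set(self) -> set[tuple[Node, Node]]:
        return set(self.graph.edges)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TemporalDAG):
            return NotImplemented
        return (
            set(self.graph.nodes) == set(other.graph.nodes)
            and self.edges() == other.edges()
            and self.outcome == other.outcome
        )


def build_dag(
    results: Sequence,
    ordering: TemporalOrdering | None = None,
    outcome: Node | None = None,
    prune_isolated: bool = True,
) -> TemporalDAG:
    """Assemble the network from stage results: one edge per selected pair.

    Each selected predictor contributes an edge predictor -> response with
    weight ``|refit coefficient|``.  If an explicit ``ordering`` is supplied,
    predictors must rank strictly below their response; otherwise the node
    years themselves enforce the temporal direction.
    """
    edges: list[tuple[Node, Node, float, float]] = []
    for res in results:
        response = Node(*res.response)
        for pred, coef, sel in zip(res.predictors, res.coefficient, res.selected):
            if not sel:
                continue
            pred = Node(*pred)
            if ordering is not None and ordering.rank(pred) >= ordering.rank(response):
                raise TemporalOrderError(
                    f"selected predictor {pred.label()} not earlier than "
                    f"response {response.label()}"
                )
            sign = 1.0 if coef > 0 else (-1.0 if coef < 0 else 0.0)
            edges.append((pred, response, abs(float(coef)), sign))
    return TemporalDAG.from_edges(edges, outcome=outcome, prune_isolated=prune_isolated)


def classify_predictors(
    dag: TemporalDAG, outcome: Node | None = None
) -> tuple[set[str], set[str]]:
    """Split base variables into direct vs indirect predictors of the outcome.

    *Direct*: variables whose measurement at the slice immediately before the
    outcome is a parent of the outcome node.  *Indirect*: variables not in the
    direct set that still have a node with a directed path to the outcome —
    their influence is entirely mediated.
    """
    outcome = Node(*(outcome or dag.outcome))
    if not dag.graph.has_node(outcome):
        raise KeyError(f"outcome {outcome!r} not in DAG")
    earlier = [t for t in dag.times() if t < outcome.time]
    prev_time = max(earlier) if earlier else None
    direct = {
        p.variable
        for p in dag.parents(outcome)
        if prev_time is not None and p.time == prev_time
    }
    ancestors = nx.ancestors(dag.graph, outcome)
    indirect = {n.variable for n in ancestors} - direct - {outcome.variable} | (
        {outcome.variable}
        if any(n.variable == outcome.variable for n in ancestors)
        else set()
    )
    indirect -= direct
    return direct, indirect


# ---------------------------------------------------------------------------
# export / import


def _dag_to_json_obj(dag: TemporalDAG) -> dict:
    return {
        "nodes": [{"variable": n.variable, "time": n.time} for n in dag.nodes()],
        "edges": [
            {
                "src": {"variable": u.variable, "time": u.time},
                "dst": {"variable": v.variable, "time": v.time},
                "weight": w,
                "sign": s,
            }
            for u, v, w, s in dag.edges()
        ],
        "outcome": (
            {"variable": dag.outcome.variable, "time": dag.outcome.time}
            if dag.outcome
            else None
        ),
    }


def _dag_from_json_obj(obj: dict) -> TemporalDAG:
    edges = [
        (
            Node(e["src"]["variable"], int(e["src"]["time"])),
            Node(e["dst"]["variable"], int(e["dst"]["time"])),
            float(e["weight"]),
            float(e["sign"]),
        )
        for e in obj["edges"]
    ]
    nodes = [Node(n["variable"], int(n["time"])) for n in obj["nodes"]]
    outcome = (
        Node(obj["outcome"]["variable"], int(obj["outcome"]["time"]))
        if obj.get("outcome")
        else None
    )
    return TemporalDAG.from_edges(
        edges, outcome=outcome, extra_nodes=nodes, prune_isolated=False
    )


def _dag_to_dot(dag: TemporalDAG) -> str:
    lines = ["digraph temporal_network {", "  rankdir=LR;"]
    for t in dag.times():
        members = " ".join(
            f'"{n.label()}";' for n in dag.nodes() if n.time == t
        )
        lines.append(f"  {{ rank=same; {members} }}")
    for n in dag.nodes():
        shape = "doublecircle" if n == dag.outcome else "ellipse"
        lines.append(f'  "{n.label()}" [shape={shape}];')
    for u, v, w, s in dag.edges():
        style = "solid" if s >= 0 else "dashed"
        lines.append(f'  "{u.label()}" -> "{v.label()}" [label="{w:g}", style={style}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_graph(dag: TemporalDAG, path, format: str = "json") -> None:
    """Write the DAG as ``json`` (edge-list dialect), ``graphml`` or ``dot``.

    JSON and GraphML are lossless and round-trip through
    :func:`import_graph`; DOT is a rendering export that groups nodes of each
    time slice at the same rank.
    """
    fmt = format.lower()
    path = str(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_dag_to_json_obj(dag), fh, indent=1)
    elif fmt == "graphml":
        g = nx.DiGraph()
        for n in dag.nodes():
            g.add_node(
                n.label(),
                variable=n.variable,
                time=int(n.time),
                is_outcome=int(n == dag.outcome),
            )
        for u, v, w, s in dag.edges():
            g.add_edge(u.label(), v.label(), weight=float(w), sign=float(s))
        nx.write_graphml(g, path)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write(_dag_to_dot(dag))
    else:
        raise UnknownFormatError(f"unknown graph format {format!r}")


def import_graph(path, format: str = "json") -> TemporalDAG:
    fmt = format.lower()
    if fmt == "json":
        with open(str(path)) as fh:
            return _dag_from_json_obj(json.load(fh))
    if fmt == "graphml":
        g = nx.read_graphml(str(path))
        nodes = {
            nid: Node(d["variable"], int(d["time"])) for nid, d in g.nodes(data=True)
        }
        outcome = None
        for nid, d in g.nodes(data=True):
            if int(d.get("is_outcome", 0)):
                outcome = nodes[nid]
        edges = [
            (nodes[u], nodes[v], float(d["weight"]), float(d["sign"]))
            for u, v, d in g.edges(data=True)
        ]
        return TemporalDAG.from_edges(
            edges, outcome=outcome, extra_nodes=nodes.values(), prune_isolated=False
        )
    raise UnknownFormatError(f"unknown graph format {format!r}")
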