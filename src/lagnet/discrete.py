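"""Discrete (binary) network parameterization and exact inference.

The continuous panel is broken into binary variables at per-column means
(strictly above average -> 1, ties and below -> 0), the temporal DAG is
parameterized by conditional probability tables estimated by counting with
Laplace smoothing, and observational / interventional queries are answered
exactly by variable elimination.  ``brute_force_query`` enumerates the full
joint table and is the in-package reference oracle for the elimination code.

CPT layout: a node's parents are sorted by ``(time, variable)``; the table
has ``2**k`` entries giving ``P(node = 1 | parent configuration)``, where the
configuration index uses the first (sorted) parent as the most significant
bit.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import NullEvidenceError, UndefinedCPTError
from .network import TemporalDAG
from .panel import Node, PanelDataset


@dataclass
class BinaryPanel:
    """Panel with all cells in {0, 1} plus the per-column cut points used."""

    frame: pd.DataFrame  # (variable, time) MultiIndex columns, int 0/1 cells
    cut_points: dict[Node, float]

    def series(self, node: Node) -> np.ndarray:
        return self.frame[(node.variable, int(node.time))].to_numpy(dtype=int)

    def has_node(self, node: Node) -> bool:
        return (node.variable, int(node.time)) in set(self.frame.columns)

    @property
    def n_units(self) -> int:
        return len(self.frame)


def binarize(panel: PanelDataset) -> BinaryPanel:
    """Split every column at its mean: strictly greater -> 1, else 0.

    Constant columns become all-zero (no value is strictly above the mean)
    and trigger a warning.
    """
    out = {}
    cuts = {}
    for col in panel.frame.columns:
        node = Node(col[0], int(col[1]))
        x = panel.frame[col].to_numpy(dtype=float)
        mu = float(x.mean())
        b = (x > mu).astype(int)
        if b.min() == b.max():
            warnings.warn(
                f"column {node.label()} is constant after binarization", stacklevel=2
            )
        out[col] = b
        cuts[node] = mu
    frame = pd.DataFrame(out, index=panel.frame.index)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["variable", "time"])
    return BinaryPanel(frame=frame, cut_points=cuts)


@dataclass
class CPT:
    """P(node = 1 | each parent configuration); parents sorted by (time, variable)."""

    node: Node
    parents: tuple[Node, ...]
    table: np.ndarray  # shape (2**len(parents),)

    def row(self, config: tuple[int, ...]) -> float:
        idx = 0
        for bit in config:
            idx = (idx << 1) | int(bit)
        return float(self.table[idx])


@dataclass
class BinaryNetwork:
    """A temporal DAG with one binary CPT per node."""

    dag: TemporalDAG
    cpts: dict[Node, CPT]
    alpha: float

    def nodes(self) -> list[Node]:
        return self.dag.nodes()


def _config_index(bits: np.ndarray) -> np.ndarray:
    """Row-wise big-endian index of a (n, k) 0/1 matrix (k may be 0)."""
    n, k = bits.shape
    idx = np.zeros(n, dtype=int)
    for j in range(k):
        idx = (idx << 1) | bits[:, j]
    return idx


def estimate_cpts(bpanel: BinaryPanel, dag: TemporalDAG, alpha: float = 1.0) -> BinaryNetwork:
    """Counting estimate with pseudo-count ``alpha`` per cell.

    ``P(node=1 | parents=c) = (count(node=1, c) + alpha) / (count(c) + 2*alpha)``;
    root nodes get (smoothed) marginal frequencies.  With ``alpha = 0`` an
    unobserved parent configuration raises :class:`UndefinedCPTError`.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    cpts: dict[Node, CPT] = {}
    for node in dag.nodes():
        if not bpanel.has_node(node):
            raise KeyError(f"node {node.label()} not present in the binary panel")
        parents = tuple(dag.parents(node))
        y = bpanel.series(node)
        if parents:
            bits = np.column_stack([bpanel.series(p) for p in parents])
        else:
            bits = np.zeros((len(y), 0), dtype=int)
        idx = _config_index(bits)
        size = 2 ** len(parents)
        total = np.bincount(idx, minlength=size).astype(float)
        ones = np.bincount(idx, weights=y, minlength=size)
        if alpha == 0.0 and (total == 0).any():
            missing = int(np.flatnonzero(total == 0)[0])
            config = format(missing, f"0{len(parents)}b") if parents else ""
            raise UndefinedCPTError(
                f"node {node.label()}: parent configuration {config!r} never "
                "observed and alpha=0"
            )
        table = (ones + alpha) / (total + 2 * alpha)
        cpts[node] = CPT(node=node, parents=parents, table=table)
    return BinaryNetwork(dag=dag, cpts=cpts, alpha=float(alpha))


# ---------------------------------------------------------------------------
# factors and variable elimination


@dataclass
class _Factor:
    vars: tuple[Node, ...]
    table: np.ndarray  # shape (2,) * len(vars)

    @classmethod
    def from_cpt(cls, cpt: CPT) -> "_Factor":
        k = len(cpt.parents)
        p1 = cpt.table.reshape((2,) * k) if k else cpt.table.reshape(())
        tab = np.stack([1.0 - p1, p1], axis=-1)  # last axis = the node itself
        return cls(vars=tuple(cpt.parents) + (cpt.node,), table=tab)

    def reduce(self, node: Node, value: int) -> "_Factor":
        if node not in self.vars:
            return self
        ax = self.vars.index(node)
        tab = np.take(self.table, value, axis=ax)
        return _Factor(
            vars=self.vars[:ax] + self.vars[ax + 1 :], table=tab
        )

    def multiply(self, other: "_Factor") -> "_Factor":
        union = list(self.vars) + [v for v in other.vars if v not in self.vars]
        t1 = _expand(self, union)
        t2 = _expand(other, union)
        return _Factor(vars=tuple(union), table=t1 * t2)

    def marginalize(self, node: Node) -> "_Factor":
        ax = self.vars.index(node)
        return _Factor(
            vars=self.vars[:ax] + self.vars[ax + 1 :],
            table=self.table.sum(axis=ax),
        )


def _expand(f: _Factor, union: list[Node]) -> np.ndarray:
    src = [f.vars.index(v) for v in union if v in f.vars]
    tab = np.transpose(f.table, axes=src) if f.vars else f.table
    shape = tuple(2 if v in f.vars else 1 for v in union)
    return tab.reshape(shape)


def _eliminate(factors: list[_Factor], keep: set[Node]) -> _Factor:
    """Sum out every variable not in ``keep``; returns the product factor."""
    factors = list(factors)
    to_eliminate = {v for f in factors for v in f.vars} - keep
    while to_eliminate:
        # greedy: eliminate the variable whose product factor is smallest
        best, best_size = None, None
        for v in to_eliminate:
            involved = {u for f in factors if v in f.vars for u in f.vars}
            size = len(involved)
            if best_size is None or size < best_size:
                best, best_size = v, size
        involved = [f for f in factors if best in f.vars]
        rest = [f for f in factors if best not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(best)]
        to_eliminate.discard(best)
    prod = _Factor(vars=(), table=np.array(1.0))
    for f in factors:
        prod = prod.multiply(f)
    return prod


def _drop_barren(net: BinaryNetwork, relevant: set[Node]) -> list[Node]:
    """Nodes that matter for a query: the relevant set and its ancestors."""
    g = net.dag.graph
    keep = set()
    for node in relevant:
        keep.add(node)
        keep |= set(nx.ancestors(g, node))
    return [n for n in net.nodes() if n in keep]


def _check_nodes(net: BinaryNetwork, nodes) -> None:
    have = set(net.nodes())
    for n in nodes:
        if Node(*n) not in have:
            raise KeyError(f"node {Node(*n).label()} not in network")


def query(net: BinaryNetwork, target, evidence: dict | None = None) -> float:
    """Exact ``P(target = 1 | evidence)`` by variable elimination."""
    target = Node(*target)
    evidence = {Node(*k): int(v) for k, v in (evidence or {}).items()}
    _check_nodes(net, [target, *evidence])
    if target in evidence:
        raise ValueError("target must not be part of the evidence")
    nodes = _drop_barren(net, {target, *evidence})
    factors = [_Factor.from_cpt(net.cpts[n]) for n in nodes]
    for e, val in evidence.items():
        factors = [f.reduce(e, val) for f in factors]
    result = _eliminate(factors, keep={target})
    if result.vars != (target,):
        raise RuntimeError(f"elimination left unexpected factor over {result.vars}")
    tab = result.table
    z = float(tab.sum())
    if z <= 0.0:
        raise NullEvidenceError("evidence has probability zero under the network")
    return float(tab[1] / z)


def joint_probability(net: BinaryNetwork, assignment: dict) -> float:
    """Exact joint probability of a (partial) assignment."""
    assignment = {Node(*k): int(v) for k, v in assignment.items()}
    _check_nodes(net, assignment)
    nodes = _drop_barren(net, set(assignment))
    factors = [_Factor.from_cpt(net.cpts[n]) for n in nodes]
    for e, val in assignment.items():
        factors = [f.reduce(e, val) for f in factors]
    return float(_eliminate(factors, keep=set()).table)


def mutilate(net: BinaryNetwork, do: dict) -> BinaryNetwork:
    """Graph surgery for an intervention: cut incoming edges, fix states."""
    do = {Node(*k): int(v) for k, v in do.items()}
    _check_nodes(net, do)
    edges = [
        (u, v, w, s) for u, v, w, s in net.dag.edges() if v not in do
    ]
    dag = TemporalDAG.from_edges(
        edges,
        outcome=net.dag.outcome,
        extra_nodes=net.dag.nodes(),
        prune_isolated=False,
    )
    cpts = {}
    for node, cpt in net.cpts.items():
        if node in do:
            cpts[node] = CPT(
                node=node, parents=(), table=np.array([float(do[node])])
            )
        else:
            cpts[node] = cpt
    return BinaryNetwork(dag=dag, cpts=cpts, alpha=net.alpha)


def intervene(net: BinaryNetwork, do: dict, target) -> float:
    """Exact ``P(target = 1 | do(assignment))`` on the mutilated network."""
    target = Node(*target)
    do = {Node(*k): int(v) for k, v in do.items()}
    if target in do:
        raise ValueError("target must not be intervened on")
    return query(mutilate(net, do), target)


def brute_force_query(net: BinaryNetwork, target, evidence: dict | None = None) -> float:
    """Reference oracle: enumerate the full joint table (exponential)."""
    target = Node(*target)
    evidence = {Node(*k): int(v) for k, v in (evidence or {}).items()}
    _check_nodes(net, [target, *evidence])
    nodes = net.nodes()
    num = 0.0
    den = 0.0
    for states in itertools.product((0, 1), repeat=len(nodes)):
        s = dict(zip(nodes, states))
        if any(s[e] != v for e, v in evidence.items()):
            continue
        p = 1.0
        for n in nodes:
            cpt = net.cpts[n]
            p1 = cpt.row(tuple(s[par] for par in cpt.parents))
            p *= p1 if s[n] == 1 else (1.0 - p1)
        den += p
        if s[target] == 1:
            num += p
    if den <= 0.0:
        raise NullEvidenceError("evidence has probability zero under the network")
    return num / den


# ---------------------------------------------------------------------------
# serialization


def network_to_json(net: BinaryNetwork, path) -> None:
    obj = {
        "alpha": net.alpha,
        "outcome": (
            {"variable": net.dag.outcome.variable, "time": net.dag.outcome.time}
            if net.dag.outcome
            else None
        ),
        "edges": [
            {
                "src": {"variable": u.variable, "time": u.time},
                "dst": {"variable": v.variable, "time": v.time},
                "weight": w,
                "sign": s,
            }
            for u, v, w, s in net.dag.edges()
        ],
        "nodes": [
            {
                "variable": n.variable,
                "time": n.time,
                "parents": [
                    {"variable": p.variable, "time": p.time}
                    for p in net.cpts[n].parents
                ],
                "cpt": net.cpts[n].table.tolist(),
            }
            for n in net.nodes()
        ],
    }
    with open(str(path), "w") as fh:
        json.dump(obj, fh, indent=1)


def network_from_json(path) -> BinaryNetwork:
    with open(str(path)) as fh:
        obj = json.load(fh)
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
    dag = TemporalDAG.from_edges(
        edges, outcome=outcome, extra_nodes=nodes, prune_isolated=False
    )
    cpts = {}
    for n in obj["nodes"]:
        node = Node(n["variable"], int(n["time"]))
        parents = tuple(Node(p["variable"], int(p["time"])) for p in n["parents"])
        cpts[node] = CPT(node=node, parents=parents, table=np.array(n["cpt"], dtype=float))
    return BinaryNetwork(dag=dag, cpts=cpts, alpha=float(obj["alpha"]))
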