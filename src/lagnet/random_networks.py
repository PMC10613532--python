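"""Seeded random binary networks for oracle checks and property tests."""

from __future__ import annotations

import numpy as np

from .discrete import CPT, BinaryNetwork
from .network import TemporalDAG
from .panel import Node


def random_binary_network(
    n_nodes: int, seed: int, edge_prob: float = 0.45
) -> BinaryNetwork:
    """Random temporal DAG over ``n_nodes`` nodes with random CPTs in (0, 1).

    Nodes are spread over three annual slices; each forward-in-time pair is an
    edge with probability ``edge_prob``; every CPT entry is uniform on
    (0.05, 0.95), so all evidence has positive probability.  The outcome is a
    node of the last slice.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    nodes = [Node(f"v{i}", 2015 + i % 3) for i in range(n_nodes)]
    edges = []
    for u in nodes:
        for v in nodes:
            if u.time < v.time and rng.random() < edge_prob:
                edges.append((u, v, float(rng.uniform(0.05, 1.0)), 1.0))
    last = max(n.time for n in nodes)
    outcome = next(n for n in nodes if n.time == last)
    dag = TemporalDAG.from_edges(
        edges, outcome=outcome, extra_nodes=nodes, prune_isolated=False
    )
    cpts = {}
    for node in dag.nodes():
        parents = tuple(dag.parents(node))
        table = rng.uniform(0.05, 0.95, size=2 ** len(parents))
        cpts[node] = CPT(node=node, parents=parents, table=table)
    return BinaryNetwork(dag=dag, cpts=cpts, alpha=1.0)
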