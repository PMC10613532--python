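"""Structure-recovery evaluation: planted edges vs two-stage selection output.

The two-stage procedure can only discover edges into the outcome and into the
outcome's true direct predictors, so recovery is scored against that
reachable slice of the planted DAG.  The true-positive rate is computed over
reachable planted edges with |weight| at or above a floor (weak edges below
the clinically meaningful threshold are not demanded); the false-discovery
rate counts selected edges absent from the full planted DAG.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .network import TemporalDAG
from .panel import Node
from .selection import SelectionConfig, StabilityResult, run_two_stage
from .synthetic import generate_panel, study_like_spec


@dataclass
class RecoveryMetrics:
    tpr: float
    fdr: float
    n_relevant_true: int
    n_discovered: int
    n_true_positive: int
    n_false_positive: int


def _discovered_edges(results: list[StabilityResult]) -> set[tuple[Node, Node]]:
    out = set()
    for res in results:
        resp = Node(*res.response)
        for p in res.selected_predictors():
            out.add((Node(*p), resp))
    return out


def evaluate_two_stage_recovery(
    truth: TemporalDAG,
    results: list[StabilityResult],
    weight_floor: float = 0.1,
) -> RecoveryMetrics:
    """Score a two-stage run against the planted DAG."""
    outcome = Node(*truth.outcome)
    true_direct = truth.parents(outcome)
    relevant_responses = {outcome} | set(true_direct)
    relevant = {
        (u, v): w for u, v, w, _ in truth.edges() if v in relevant_responses
    }
    strong = {e for e, w in relevant.items() if w >= weight_floor}
    discovered = _discovered_edges(results)
    all_truth = truth.edge_set()
    tp_strong = len(strong & discovered)
    fp = len(discovered - all_truth)
    return RecoveryMetrics(
        tpr=tp_strong / len(strong) if strong else float("nan"),
        fdr=fp / len(discovered) if discovered else 0.0,
        n_relevant_true=len(relevant),
        n_discovered=len(discovered),
        n_true_positive=len(discovered & all_truth),
        n_false_positive=fp,
    )


def structure_recovery_experiment(
    n_units: int,
    seeds,
    config: SelectionConfig | None = None,
    weight_floor: float = 0.1,
) -> pd.DataFrame:
    """Run the full pipeline on study-like panels across seeds; one row per seed."""
    rows = []
    for seed in seeds:
        spec = study_like_spec(n_units=n_units, seed=int(seed))
        panel, truth = generate_panel(spec)
        cfg = replace(config or SelectionConfig(), seed=int(seed) + 104729)
        results = run_two_stage(panel, truth.outcome, cfg)
        m = evaluate_two_stage_recovery(truth, results, weight_floor=weight_floor)
        rows.append(
            {
                "seed": int(seed),
                "tpr": m.tpr,
                "fdr": m.fdr,
                "n_relevant_true": m.n_relevant_true,
                "n_discovered": m.n_discovered,
                "n_true_positive": m.n_true_positive,
                "n_false_positive": m.n_false_positive,
                "outcome_stage_r2": results[0].r2,
            }
        )
    return pd.DataFrame(rows)
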