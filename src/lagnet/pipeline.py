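"""End-to-end orchestration: panel -> selection -> network -> CPTs -> effects.

``run_pipeline`` executes the whole analysis behind a single configuration
object (YAML-serializable) and writes its artifacts — tidy stability CSVs, a
wide coefficient matrix, graph exports, the parameterized binary network and
the effect table — deterministically for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .discrete import binarize, estimate_cpts, network_to_json
from .exceptions import PipelineError
from .mediation import effect_table, effects_frame
from .network import build_dag, classify_predictors, export_graph
from .panel import Node, PanelDataset, read_panel, write_panel
from .selection import SelectionConfig, StabilityResult, run_two_stage
from .synthetic import SyntheticSpec, generate_panel, study_like_spec

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Exactly one of ``input_path`` / ``synthetic`` drives the run."""

    outcome_variable: str
    outcome_time: int
    input_path: str | None = None
    synthetic: SyntheticSpec | None = None
    synthetic_study_like: bool = False
    n_units: int = 1000
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    alpha: float = 1.0
    out_dir: str = "pipeline_out"
    seed: int = 0
    graph_formats: tuple[str, ...] = ("json", "dot")

    def __post_init__(self):
        sources = sum(
            [self.input_path is not None, self.synthetic is not None,
             self.synthetic_study_like]
        )
        if sources != 1:
            raise ValueError(
                "exactly one of input_path / synthetic / synthetic_study_like"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(str(path)) as fh:
            obj = yaml.safe_load(fh)
        sel = SelectionConfig(**obj.pop("selection", {}))
        syn = obj.pop("synthetic", None)
        if syn is not None:
            syn["weights"] = {tuple(k.split("->")): v for k, v in syn["weights"].items()}
            if syn.get("final_weights"):
                syn["final_weights"] = {
                    tuple(k.split("->")): v for k, v in syn["final_weights"].items()
                }
            syn = SyntheticSpec(**syn)
        return cls(selection=sel, synthetic=syn, **obj)


def report_table1(results: list[StabilityResult]) -> pd.DataFrame:
    """Wide coefficient matrix: rows = prior-year predictor variables, columns
    = responses; cells hold the refit coefficient of selected pairs and ``"."``
    elsewhere.  Predictor rows selected nowhere are omitted."""
    if not results:
        raise ValueError("results must be non-empty")
    cols = {}
    row_vars: list[str] = []
    for res in results:
        resp = Node(*res.response)
        cells = {}
        for p, c, s in zip(res.predictors, res.coefficient, res.selected):
            if s:
                pv = Node(*p).variable
                cells[pv] = c
                if pv not in row_vars:
                    row_vars.append(pv)
        cols[resp.label()] = cells
    data = {
        label: [f"{cells[v]:.2f}" if v in cells else "." for v in row_vars]
        for label, cells in cols.items()
    }
    return pd.DataFrame(data, index=pd.Index(row_vars, name="predictor"))


def _load_panel(config: PipelineConfig):
    if config.input_path is not None:
        return read_panel(config.input_path), None
    spec = config.synthetic
    if config.synthetic_study_like:
        spec = study_like_spec(config.n_units, seed=config.seed)
    return generate_panel(spec)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages and write artifacts; returns artifact paths by name.

    Stages: load/generate -> two-stage stability selection -> DAG assembly and
    predictor classification -> binarization -> CPT estimation -> effect
    table.  Any stage failure aborts with the stage name and an error code.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    outcome = Node(config.outcome_variable, int(config.outcome_time))

    def stage(name, code, fn):
        try:
            logger.info("pipeline stage=%s starting", name)
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, code, str(exc)) from exc

    panel, truth = stage("load", "load-failed", lambda: _load_panel(config))
    if config.outcome_time != panel.times[-1]:
        raise PipelineError(
            "load", "outcome-not-last", "outcome year must be the panel's last slice"
        )
    logger.info(
        "pipeline stage=load n_units=%d n_vars=%d times=%s",
        panel.n_units, len(panel.variables), panel.times,
    )
    p_panel = out / "panel.csv"
    write_panel(panel, p_panel)
    artifacts["panel"] = p_panel
    if truth is not None:
        export_graph(truth, out / "truth_dag.json", "json")
        artifacts["truth_dag"] = out / "truth_dag.json"

    sel_cfg = replace(config.selection, seed=config.seed)
    results = stage(
        "select", "selection-failed", lambda: run_two_stage(panel, outcome, sel_cfg)
    )
    for res in results:
        p = out / f"stability_{Node(*res.response).label().replace('@', '_')}.csv"
        res.to_frame().to_csv(p, index=False)
        artifacts[f"stability:{Node(*res.response).label()}"] = p
    p_tab = out / "coefficient_matrix.csv"
    report_table1(results).to_csv(p_tab)
    artifacts["coefficient_matrix"] = p_tab

    dag = stage("build-net", "dag-failed", lambda: build_dag(results, outcome=outcome))
    direct, indirect = classify_predictors(dag) if dag.graph.has_node(outcome) else (set(), set())
    logger.info(
        "pipeline stage=build-net edges=%d direct=%d indirect=%d",
        dag.n_edges, len(direct), len(indirect),
    )
    for fmt in config.graph_formats:
        p = out / f"dag.{fmt}"
        export_graph(dag, p, fmt)
        artifacts[f"dag:{fmt}"] = p
    pd.DataFrame(
        sorted(
            [(v, "direct") for v in direct] + [(v, "indirect") for v in indirect]
        ),
        columns=["variable", "classification"],
    ).to_csv(out / "classification.csv", index=False)
    artifacts["classification"] = out / "classification.csv"

    bpanel = stage("fit-cpt", "binarize-failed", lambda: binarize(panel))
    net = stage(
        "fit-cpt", "cpt-failed", lambda: estimate_cpts(bpanel, dag, alpha=config.alpha)
    )
    p_net = out / "network.json"
    network_to_json(net, p_net)
    artifacts["network"] = p_net

    def effects():
        if dag.n_edges == 0:
            return pd.DataFrame(
                columns=["variable", "time", "classification", "total_effect",
                         "natural_direct", "natural_indirect"]
            )
        return effects_frame(effect_table(net, outcome, per_mediator=True))

    eff = stage("effects", "effects-failed", effects)
    p_eff = out / "effects.csv"
    eff.to_csv(p_eff, index=False)
    artifacts["effects"] = p_eff
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return artifacts
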