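"""Natural direct and indirect (mediated) effects on the risk-difference scale.

For a binary exposure X, binary outcome Y and a set of mediators M, the
mediation formula gives

    NDE = sum_m [ P(Y=1 | do(X=1, M=m)) - P(Y=1 | do(X=0, M=m)) ] * P(M=m | do(X=0))
    NIE = sum_m   P(Y=1 | do(X=1, M=m)) * [ P(M=m | do(X=1)) - P(M=m | do(X=0)) ]

and the nested total effect ``TE = E[Y(1, M(1))] - E[Y(0, M(0))]`` equals
``NDE + NIE`` as an algebraic identity; that nested total is what
:class:`EffectReport` carries.  Under the network's assumed sufficiency it
coincides with the interventional contrast ``P(Y=1|do(X=1)) -
P(Y=1|do(X=0))`` (exposed separately as :func:`total_effect`) whenever the
outcome's remaining parents are not confounded with the mediators; on
temporal networks built here the two agree to numerical precision except in
that confounded corner, which docs/methods.md discusses.

Effects are reported as risk differences (probability-point changes), the
natural scale for binarized prevalence variables.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .discrete import BinaryNetwork, intervene, joint_probability, mutilate
from .network import classify_predictors
from .panel import Node


@dataclass
class EffectReport:
    """Total / natural direct / natural indirect effects of one exposure."""

    exposure: Node
    outcome: Node
    mediators: list[Node]
    total_effect: float
    natural_direct: float
    natural_indirect: float
    per_mediator_indirect: dict[Node, float] | None = None
    classification: str | None = None  # direct / indirect / none
    scale: str = "risk difference"


def total_effect(net: BinaryNetwork, exposure, outcome) -> float:
    """Interventional contrast ``P(Y=1|do(X=1)) - P(Y=1|do(X=0))``."""
    exposure, outcome = Node(*exposure), Node(*outcome)
    if exposure == outcome:
        raise ValueError("exposure and outcome must differ")
    return intervene(net, {exposure: 1}, outcome) - intervene(net, {exposure: 0}, outcome)


def _mediator_dist(net: BinaryNetwork, exposure: Node, x: int, mediators: list[Node]):
    """P(M = m | do(X = x)) for every joint mediator configuration."""
    mut = mutilate(net, {exposure: x})
    return {
        config: joint_probability(mut, dict(zip(mediators, config)))
        for config in itertools.product((0, 1), repeat=len(mediators))
    }


def natural_effects(
    net: BinaryNetwork,
    exposure,
    outcome,
    mediators,
    per_mediator: bool = True,
) -> EffectReport:
    """Mediation-formula decomposition with the joint mediator state.

    ``per_mediator`` adds a descriptive single-mediator decomposition (other
    mediators marginalized under the intervention on the exposure); the
    per-mediator numbers need not sum to the joint NIE when mediators
    interact.  With an empty mediator list the NDE reduces to the
    interventional contrast and the NIE to zero.
    """
    exposure, outcome = Node(*exposure), Node(*outcome)
    mediators = [Node(*m) for m in mediators]
    if exposure == outcome or outcome in mediators or exposure in mediators:
        raise ValueError("exposure, outcome and mediators must be distinct")
    g = net.dag.graph
    for m in mediators:
        if not (nx.has_path(g, exposure, m) and nx.has_path(g, m, outcome)):
            warnings.warn(
                f"mediator {m.label()} lies on no {exposure.label()} -> "
                f"{outcome.label()} path; its contribution is zero"
            )

    pm1 = _mediator_dist(net, exposure, 1, mediators)
    pm0 = _mediator_dist(net, exposure, 0, mediators)
    nde = 0.0
    nie = 0.0
    for config in itertools.product((0, 1), repeat=len(mediators)):
        do_m = dict(zip(mediators, config))
        y1m = intervene(net, {exposure: 1, **do_m}, outcome)
        y0m = intervene(net, {exposure: 0, **do_m}, outcome)
        nde += (y1m - y0m) * pm0[config]
        nie += y1m * (pm1[config] - pm0[config])

    per: dict[Node, float] | None = None
    if per_mediator:
        per = {}
        for m in mediators:
            s = 0.0
            for v in (0, 1):
                y1 = intervene(net, {exposure: 1, m: v}, outcome)
                p1v = joint_probability(mutilate(net, {exposure: 1}), {m: v})
                p0v = joint_probability(mutilate(net, {exposure: 0}), {m: v})
                s += y1 * (p1v - p0v)
            per[m] = s

    return EffectReport(
        exposure=exposure,
        outcome=outcome,
        mediators=mediators,
        total_effect=nde + nie,
        natural_direct=nde,
        natural_indirect=nie,
        per_mediator_indirect=per,
    )


def effect_table(
    net: BinaryNetwork, outcome=None, per_mediator: bool = False
) -> list[EffectReport]:
    """One report per base variable: its earliest network node as the exposure.

    Mediators are the outcome's parents of *other* base variables — a
    variable's own later measurement is part of its direct pathway, not a
    mediator.  Direct-classified variables carry a natural direct effect;
    variables with no direct edge into the outcome have NDE exactly 0 by
    construction; variables with no path to the outcome report all-zero
    effects.
    """
    dag = net.dag
    outcome = Node(*(outcome or dag.outcome))
    direct, indirect = classify_predictors(dag, outcome)
    out_parents = dag.parents(outcome)
    reports = []
    for var in dag.variables():
        exposure = dag.earliest_node_of(var)
        if exposure is None or exposure == outcome:
            continue
        mediators = [p for p in out_parents if p.variable != var]
        cls = "direct" if var in direct else ("indirect" if var in indirect else "none")
        if not dag.has_path(exposure, outcome):
            reports.append(
                EffectReport(
                    exposure=exposure,
                    outcome=outcome,
                    mediators=mediators,
                    total_effect=0.0,
                    natural_direct=0.0,
                    natural_indirect=0.0,
                    per_mediator_indirect={m: 0.0 for m in mediators}
                    if per_mediator
                    else None,
                    classification=cls,
                )
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # off-path mediators are expected here
            rep = natural_effects(
                net, exposure, outcome, mediators, per_mediator=per_mediator
            )
        rep.classification = cls
        has_direct_edge = any(
            dag.graph.has_edge(n, outcome)
            for n in dag.graph.nodes
            if n.variable == var
        )
        if not has_direct_edge:
            # structural zero: every exposure->outcome path runs through mediators
            rep.natural_direct = 0.0
            rep.total_effect = rep.natural_indirect
        reports.append(rep)
    return reports


def effects_frame(reports: list[EffectReport]) -> pd.DataFrame:
    """Tidy table of an effect report list (one row per exposure variable)."""
    mediator_cols = sorted(
        {m.label() for r in reports for m in (r.per_mediator_indirect or {})}
    )
    rows = []
    for r in reports:
        row = {
            "variable": r.exposure.variable,
            "time": r.exposure.time,
            "classification": r.classification,
            "total_effect": r.total_effect,
            "natural_direct": r.natural_direct,
            "natural_indirect": r.natural_indirect,
        }
        for mc in mediator_cols:
            row[f"nie_via_{mc}"] = (
                {m.label(): v for m, v in (r.per_mediator_indirect or {}).items()}
            ).get(mc, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["time", "variable"]).reset_index(drop=True)
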