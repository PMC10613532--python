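"""Worked example: a county-level diabetes mediation network (2015-2017).

This module carries the coefficient matrix of six lagged LASSO regressions
from a published county-level analysis of US diabetes prevalence: the 2017
diabetes rate regressed on 30 county characteristics measured in 2016
(linear), and each of the five direct 2016 predictors binarized and regressed
on the same 30 characteristics measured in 2015 (logistic).  Eleven predictor
variables carry at least one retained coefficient; the other 19 county
characteristics were significant in none of the regressions.

The matrix serves three roles in the package: a desk-scale input for network
construction (five direct predictor variables, six indirect ones, 18 edges),
the weight pattern for the study-like synthetic panel generator, and the
structure used in the mediation worked example.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import Node
from .selection import StabilityResult

OUTCOME_VARIABLE = "diabetic"
OUTCOME = Node("diabetic", 2017)

#: the six response nodes, outcome first, mediators in the published column order
RESPONSES: list[Node] = [
    Node("diabetic", 2017),
    Node("african_american", 2016),
    Node("physically_inactive", 2016),
    Node("obese", 2016),
    Node("diabetic", 2016),
    Node("poor_fair_health", 2016),
]

#: retained coefficients: response node -> {prior-year predictor variable: coefficient}
COEFFICIENTS: dict[Node, dict[str, float]] = {
    Node("diabetic", 2017): {
        "african_american": 0.08,
        "diabetic": 0.63,
        "obese": 0.12,
        "physically_inactive": 0.06,
        "poor_fair_health": 0.11,
    },
    Node("african_american", 2016): {"african_american": 0.97},
    Node("physically_inactive", 2016): {
        "physically_inactive": 0.77,
        "median_income": -0.07,
    },
    Node("obese", 2016): {"obese": 0.74, "limited_healthy_food_access": -0.05},
    Node("diabetic", 2016): {"diabetic": 0.55, "median_income": -0.06},
    Node("poor_fair_health", 2016): {
        "hispanic": 0.11,
        "physically_inactive": 0.09,
        "physically_distressed": 0.17,
        "poor_fair_health": 0.56,
        "smokers": 0.07,
        "children_in_poverty": 0.13,
    },
}

#: the 11 predictor variables with at least one retained coefficient
LINKED_VARIABLES: list[str] = [
    "african_american",
    "hispanic",
    "diabetic",
    "obese",
    "physically_inactive",
    "physically_distressed",
    "poor_fair_health",
    "smokers",
    "children_in_poverty",
    "limited_healthy_food_access",
    "median_income",
]

#: 19 county characteristics significant in none of the six regressions
DISTRACTOR_VARIABLES: list[str] = [
    "unemployed",
    "near_park",
    "forested_area",
    "water_area",
    "open_space",
    "fine_particulate_matter",
    "natural_amenities",
    "population",
    "metro_size",
    "small_town",
    "food_insecure",
    "uninsured_adults",
    "uninsured_children",
    "poor_mental_health_days",
    "poor_physical_health_days",
    "mentally_distressed",
    "white",
    "age_65_plus",
    "female",
]

STUDY_VARIABLES: list[str] = LINKED_VARIABLES + DISTRACTOR_VARIABLES

#: plausible county-level means (mostly proportions) for the synthetic panel
STUDY_MEANS: dict[str, float] = {
    "african_american": 0.10,
    "hispanic": 0.09,
    "diabetic": 0.11,
    "obese": 0.31,
    "physically_inactive": 0.26,
    "physically_distressed": 0.12,
    "poor_fair_health": 0.17,
    "smokers": 0.18,
    "children_in_poverty": 0.21,
    "limited_healthy_food_access": 0.07,
    "median_income": 0.50,
    "unemployed": 0.05,
    "near_park": 0.30,
    "forested_area": 0.35,
    "water_area": 0.05,
    "open_space": 0.40,
    "fine_particulate_matter": 0.40,
    "natural_amenities": 0.35,
    "population": 0.30,
    "metro_size": 0.30,
    "small_town": 0.40,
    "food_insecure": 0.14,
    "uninsured_adults": 0.12,
    "uninsured_children": 0.06,
    "poor_mental_health_days": 0.13,
    "poor_physical_health_days": 0.13,
    "mentally_distressed": 0.12,
    "white": 0.77,
    "age_65_plus": 0.18,
    "female": 0.50,
}

#: variable-pair cross-lag weights applied between consecutive slices
STATIONARY_WEIGHTS: dict[tuple[str, str], float] = {
    (pred, resp.variable): coef
    for resp, cells in COEFFICIENTS.items()
    if resp.time == 2016
    for pred, coef in cells.items()
}

#: outcome-year override: the 2017 diabetes rate loads on its five direct predictors
FINAL_WEIGHTS: dict[tuple[str, str], float] = {
    (pred, "diabetic"): coef
    for pred, coef in COEFFICIENTS[Node("diabetic", 2017)].items()
}


def coefficient_table() -> pd.DataFrame:
    """Wide matrix: rows = prior-year predictors, columns = the six responses.

    Cells hold the retained coefficient, NaN where the predictor was dropped.
    """
    rows = LINKED_VARIABLES
    data = {
        resp.label(): [COEFFICIENTS[resp].get(v, np.nan) for v in rows]
        for resp in RESPONSES
    }
    return pd.DataFrame(data, index=pd.Index(rows, name="predictor"))


def stage_results(
    frequency_threshold: float = 0.95, coef_threshold: float = 0.05
) -> list[StabilityResult]:
    """The coefficient matrix recast as stage results for network construction.

    Retained predictors are given selection frequency 1.0 (they were robust in
    the source analysis); the full 30-variable predictor list is preserved so
    selection thresholds apply as in a live run.
    """
    out = []
    for resp in RESPONSES:
        ptime = resp.time - 1
        preds = [Node(v, ptime) for v in STUDY_VARIABLES]
        coef = np.array(
            [COEFFICIENTS[resp].get(v, 0.0) for v in STUDY_VARIABLES], dtype=float
        )
        freq = (coef != 0.0).astype(float)
        selected = (freq >= frequency_threshold) & (np.abs(coef) >= coef_threshold)
        out.append(
            StabilityResult(
                response=resp,
                predictors=preds,
                selection_frequency=freq,
                coefficient=coef,
                selected=selected,
                penalty=float("nan"),
                family="linear" if resp.time == 2017 else "logistic",
                frequency_threshold=frequency_threshold,
                coef_threshold=coef_threshold,
                n_subsamples=100,
            )
        )
    return out


def network():
    """The published network: 18 edges over 12 nodes, outcome diabetic@2017."""
    from .network import build_dag

    return build_dag(stage_results(), outcome=OUTCOME)
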