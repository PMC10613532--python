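"""Stability-selected LASSO: the variable-selection engine of the pipeline.

A predictor of a response is *statistically significant* when its LASSO
coefficient is non-zero, and *robust* when it stays non-zero in at least a
threshold fraction (default 95%) of LASSO regressions fitted on random
subsamples (default 90% of the units, drawn without replacement).  The
penalty is chosen on each subsample by K-fold cross-validated deviance
minimization over a log-spaced path; the reported coefficient is a full-data
refit at a full-data cross-validated penalty, and a predictor is *selected*
when it is robust and its refit coefficient has magnitude at or above a
minimum clinically meaningful effect size (default 0.05, on the standardized
scale).

Linear paths are delegated to :func:`sklearn.linear_model.lasso_path`;
logistic paths use the package's warm-started coordinate-descent solver
(:mod:`lagnet._logistic`).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from ._logistic import logistic_deviance, logistic_lasso_path
from .exceptions import DegenerateResponseError, TemporalOrderError
from .panel import Node, PanelDataset, slice_design

logger = logging.getLogger(__name__)

N_PENALTIES = 100
PENALTY_RATIO = 1e-3  # smallest penalty = lambda_max / 1000


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the robustness rule and the penalized fits.

    ``frequency_threshold``/``n_subsamples`` default to the 95%-of-100
    subsample rule; an alternative 9-out-of-10 reading of robustness is
    available by setting (0.9, 10).
    """

    subsample_fraction: float = 0.9
    n_subsamples: int = 100
    frequency_threshold: float = 0.95
    coef_threshold: float = 0.05
    cv_folds: int = 10
    family: str = "linear"
    standardize: bool = True
    seed: int = 0
    #: penalty rule for the subsample fits that yield selection frequencies:
    #: "1se" (largest penalty within one standard error of the CV minimum,
    #: the parsimonious choice) or "min" (CV minimum)
    subsample_penalty_rule: str = "1se"
    #: penalty rule for the full-data refit that yields reported coefficients
    refit_penalty_rule: str = "min"
    #: "shared": the subsample penalty is cross-validated once on the full
    #: data and reused across subsamples (the classic stability-selection
    #: formulation); "per_subsample": re-cross-validated on every subsample
    penalty_scope: str = "shared"

    def __post_init__(self):
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be positive")
        if not 0.0 < self.frequency_threshold <= 1.0:
            raise ValueError("frequency_threshold must be in (0, 1]")
        if self.coef_threshold < 0:
            raise ValueError("coef_threshold must be nonnegative")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.family not in ("linear", "logistic"):
            raise ValueError("family must be 'linear' or 'logistic'")
        if self.frequency_threshold * self.n_subsamples < 1:
            raise ValueError("frequency_threshold * n_subsamples must be >= 1")
        for rule in (self.subsample_penalty_rule, self.refit_penalty_rule):
            if rule not in ("min", "1se"):
                raise ValueError("penalty rules must be 'min' or '1se'")
        if self.penalty_scope not in ("shared", "per_subsample"):
            raise ValueError("penalty_scope must be 'shared' or 'per_subsample'")


@dataclass
class StabilityResult:
    """Per-predictor selection frequencies, refit coefficients and decisions."""

    response: Node
    predictors: list
    selection_frequency: np.ndarray
    coefficient: np.ndarray
    selected: np.ndarray
    penalty: float
    family: str
    frequency_threshold: float
    coef_threshold: float
    n_subsamples: int
    r2: float | None = None

    def selected_predictors(self) -> list:
        return [p for p, s in zip(self.predictors, self.selected) if s]

    def reselect(self, frequency_threshold: float, coef_threshold: float) -> np.ndarray:
        """Selection mask under alternative thresholds (same fits)."""
        return (self.selection_frequency >= frequency_threshold) & (
            np.abs(self.coefficient) >= coef_threshold
        )

    def to_frame(self) -> pd.DataFrame:
        resp = Node(*self.response).label() if isinstance(self.response, tuple) else str(self.response)
        return pd.DataFrame(
            {
                "response": resp,
                "predictor": [
                    Node(*p).label() if isinstance(p, tuple) else str(p)
                    for p in self.predictors
                ],
                "frequency": self.selection_frequency,
                "coefficient": self.coefficient,
                "selected": self.selected,
            }
        )


# ---------------------------------------------------------------------------
# internals


def _as_matrix(X, predictors=None):
    if isinstance(X, pd.DataFrame):
        preds = list(X.columns) if predictors is None else list(predictors)
        return np.ascontiguousarray(X.to_numpy(dtype=float)), preds
    X = np.asarray(X, dtype=float)
    if predictors is None:
        predictors = [f"x{j}" for j in range(X.shape[1])]
    return np.ascontiguousarray(X), list(predictors)


def _standardize(X: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    Xc = X - mean
    if not scale:
        return Xc, np.ones(X.shape[1])
    sd = Xc.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return Xc / sd, sd


def _scale_response(y: np.ndarray, family: str, scale: bool) -> np.ndarray:
    """Fully standardized coefficients for linear fits: y on unit-variance scale."""
    if family != "linear" or not scale:
        return y
    sd = y.std()
    return y / sd if sd > 0 else y


def _lambda_path(Xs: np.ndarray, y: np.ndarray, family: str) -> np.ndarray:
    n = len(y)
    lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n
    lam_max = max(lam_max, 1e-10)
    return lam_max * np.logspace(0, np.log10(PENALTY_RATIO), N_PENALTIES)


def _fit_path(Xs, y, lambdas, family):
    """Coefficients along the path; returns (intercepts (L,), betas (L, p))."""
    if family == "linear":
        yc = y - y.mean()
        _, coefs, _ = lasso_path(Xs, yc, alphas=lambdas)
        # lasso_path returns coefficients ordered by decreasing alpha
        return np.full(len(lambdas), y.mean()), coefs.T
    b0, beta = logistic_lasso_path(Xs, np.asarray(y, dtype=float), lambdas)
    return b0, beta


def _path_losses(b0, beta, X_val, y_val, family):
    if family == "linear":
        pred = b0[:, None] + beta @ X_val.T
        return ((pred - y_val[None, :]) ** 2).mean(axis=1)
    return logistic_deviance(b0, beta, X_val, y_val)


def _cv_losses(Xs, y, lambdas, folds, rng, family) -> np.ndarray:
    """Per-fold validation loss along the path; shape (folds, len(lambdas))."""
    n = len(y)
    perm = rng.permutation(n)
    bounds = np.linspace(0, n, folds + 1).astype(int)
    losses = np.zeros((folds, len(lambdas)))
    for k in range(folds):
        val = perm[bounds[k] : bounds[k + 1]]
        train = np.concatenate([perm[: bounds[k]], perm[bounds[k + 1] :]])
        b0, beta = _fit_path(Xs[train], y[train], lambdas, family)
        losses[k] = _path_losses(b0, beta, Xs[val], y[val], family)
    return losses


def _choose_index(losses: np.ndarray, rule: str) -> int:
    """Penalty index under ``"min"`` (first minimizer of the mean loss on the
    descending path) or ``"1se"`` (largest penalty within one standard error
    of that minimum)."""
    mean_loss = losses.mean(axis=0)
    i_min = int(np.argmin(mean_loss))
    if rule == "min":
        return i_min
    folds = losses.shape[0]
    se = losses.std(axis=0, ddof=1)[i_min] / np.sqrt(folds)
    within = np.flatnonzero(mean_loss <= mean_loss[i_min] + se)
    return int(within[0])


def _cv_choose(Xs, y, lambdas, folds, rng, family, rule="min"):
    losses = _cv_losses(Xs, y, lambdas, folds, rng, family)
    return _choose_index(losses, rule), losses.mean(axis=0)


def _check_classes(y: np.ndarray, family: str, context: str):
    if family == "logistic":
        u = np.unique(y)
        if not np.isin(u, (0.0, 1.0)).all():
            raise DegenerateResponseError(f"{context}: logistic response must be 0/1")
        if len(u) < 2:
            raise DegenerateResponseError(f"{context}: single-class response")


# ---------------------------------------------------------------------------
# public operations


def select_penalty(
    X, y, folds: int, family: str, seed: int, standardize: bool = True,
    rule: str = "min",
) -> float:
    """Cross-validated penalty choice over the log-spaced path.

    By default returns the penalty minimizing the mean cross-validated
    deviance; deterministic given the seed (fold assignment is seeded); the
    returned value is always a member of the computed path.
    """
    X, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if len(y) < folds:
        raise ValueError("need at least `folds` rows")
    _check_classes(y, family, "select_penalty")
    Xs, _ = _standardize(X, standardize)
    ys = _scale_response(y, family, standardize)
    lambdas = _lambda_path(Xs, ys, family)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 11)))
    idx, _ = _cv_choose(Xs, ys, lambdas, folds, rng, family, rule=rule)
    return float(lambdas[idx])


def stability_select(X, y, config: SelectionConfig, predictors=None, response=None) -> StabilityResult:
    """Subsampled LASSO selection with a full-data refit.

    For each subsample (without replacement, size ``ceil(fraction * n)``) a
    LASSO is fitted at the subsample penalty — by default the one-standard-
    error penalty cross-validated once on the full data and shared across
    subsamples; optionally re-cross-validated per subsample — and the fit's
    non-zero pattern recorded; a predictor's selection frequency is the share
    of subsample fits in which its coefficient is non-zero.  Reported
    coefficients come from a full-data refit at the full-data cross-validated
    penalty; logistic coefficients are reported as average marginal effects
    (probability-point change per standard deviation of the predictor) so the
    common clinically-meaningful threshold applies across families.
    ``selected`` requires both frequency and coefficient thresholds.
    """
    X, preds = _as_matrix(X, predictors)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    m = math.ceil(config.subsample_fraction * n)
    if m < config.cv_folds:
        raise ValueError("subsample size smaller than cv_folds")
    _check_classes(y, config.family, "stability_select")

    # full-data cross-validation: yields the refit penalty and, in the shared
    # scope, the subsample penalty
    Xs_full, _ = _standardize(X, config.standardize)
    yf = _scale_response(y, config.family, config.standardize)
    lambdas = _lambda_path(Xs_full, yf, config.family)
    rng_full = np.random.default_rng(np.random.SeedSequence((int(config.seed), 29)))
    losses = _cv_losses(Xs_full, yf, lambdas, config.cv_folds, rng_full, config.family)
    li_refit = _choose_index(losses, config.refit_penalty_rule)
    li_shared = _choose_index(losses, config.subsample_penalty_rule)

    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 23)))
    nonzero_counts = np.zeros(p)
    attempts = 0
    max_attempts = 10 * config.n_subsamples
    done = 0
    while done < config.n_subsamples:
        if attempts >= max_attempts:
            raise DegenerateResponseError(
                "could not draw a two-class subsample within the attempt budget"
            )
        idx = rng.choice(n, size=m, replace=False)
        attempts += 1
        ysub = y[idx]
        if config.family == "logistic" and len(np.unique(ysub)) < 2:
            logger.info("stability_select: redrew single-class subsample")
            continue
        Xsub = X[idx]
        Xs, _ = _standardize(Xsub, config.standardize)
        ys = _scale_response(ysub, config.family, config.standardize)
        if config.penalty_scope == "per_subsample":
            sub_lams = _lambda_path(Xs, ys, config.family)
            sub_losses = _cv_losses(
                Xs, ys, sub_lams, config.cv_folds, rng, config.family
            )
            li = _choose_index(sub_losses, config.subsample_penalty_rule)
            _, beta_path = _fit_path(Xs, ys, sub_lams, config.family)
            beta_sub = beta_path[li]
        else:
            # short warm-started path down to the shared penalty
            lam = lambdas[li_shared]
            mini = np.geomspace(lambdas[0], lam, num=5)
            _, beta_path = _fit_path(Xs, ys, mini, config.family)
            beta_sub = beta_path[-1]
        nonzero_counts += beta_sub != 0.0
        done += 1
    frequency = nonzero_counts / config.n_subsamples

    # full-data refit
    b0_path, beta_path = _fit_path(Xs_full, yf, lambdas, config.family)
    coef = beta_path[li_refit].copy()
    penalty = float(lambdas[li_refit])

    if config.family == "linear":
        pred = b0_path[li_refit] + Xs_full @ coef
        sst = float(((yf - yf.mean()) ** 2).sum())
        r2 = 1.0 - float(((yf - pred) ** 2).sum()) / sst if sst > 0 else None
    else:
        eta = b0_path[li_refit] + Xs_full @ coef
        prob = 1.0 / (1.0 + np.exp(-eta))
        # risk scale: average marginal effect of one SD of each predictor
        coef = coef * float(np.mean(prob * (1.0 - prob)))
        dev = logistic_deviance(
            b0_path[[li_refit]], beta_path[[li_refit]], Xs_full, yf
        )[0]
        ybar = min(max(yf.mean(), 1e-12), 1 - 1e-12)
        null_dev = -2.0 * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
        r2 = 1.0 - dev / null_dev if null_dev > 0 else None  # McFadden

    selected = (frequency >= config.frequency_threshold) & (
        np.abs(coef) >= config.coef_threshold
    )
    return StabilityResult(
        response=response,
        predictors=preds,
        selection_frequency=frequency,
        coefficient=coef,
        selected=selected,
        penalty=penalty,
        family=config.family,
        frequency_threshold=config.frequency_threshold,
        coef_threshold=config.coef_threshold,
        n_subsamples=config.n_subsamples,
        r2=r2,
    )


def run_stage(
    panel: PanelDataset,
    response,
    config: SelectionConfig,
    binarize_response: bool = False,
) -> StabilityResult:
    """One selection stage: response at time t, all predictors at the preceding slice.

    With ``binarize_response`` the response is mapped to 1 when strictly above
    its mean and the family is forced to logistic (regardless of the config).
    """
    response = Node(*response)
    times = panel.times
    if response.time not in times or times.index(response.time) < 1:
        raise TemporalOrderError(
            f"response {response.label()} has no preceding slice in the panel"
        )
    predictor_time = times[times.index(response.time) - 1]
    X, y = slice_design(panel, response, predictor_time)
    yv = y.to_numpy(dtype=float)
    family = config.family
    if binarize_response:
        yv = (yv > yv.mean()).astype(float)
        if len(np.unique(yv)) < 2:
            raise DegenerateResponseError(
                f"binarized response {response.label()} has a single class"
            )
        family = "logistic"
    cfg = replace(config, family=family)
    logger.info(
        "run_stage: response=%s predictors@%s n=%d p=%d family=%s",
        response.label(), predictor_time, len(yv), X.shape[1], family,
    )
    return stability_select(X, yv, cfg, response=response)


def _stage_seed(seed: int, k: int) -> int:
    ss = np.random.SeedSequence((int(seed), 1000 + k))
    return int(ss.generate_state(1)[0] % (2**31))


def run_two_stage(panel: PanelDataset, outcome, config: SelectionConfig) -> list[StabilityResult]:
    """Outcome stage plus one binarized logistic stage per selected direct predictor.

    The outcome (continuous) is regressed on the slice before it; each
    selected direct predictor then becomes a binarized response regressed on
    the slice before *that* (its own earlier measurement included).  Mediator
    stages follow the outcome stage's predictor order.
    """
    outcome = Node(*outcome)
    times = panel.times
    if len(times) < 3 or outcome.time != times[-1]:
        raise TemporalOrderError(
            "run_two_stage needs >= 3 slices ending at the outcome's time"
        )
    cfg0 = replace(config, seed=_stage_seed(config.seed, 0))
    results = [run_stage(panel, outcome, cfg0, binarize_response=False)]
    mediators = results[0].selected_predictors()
    if not mediators:
        warnings.warn("outcome stage selected no predictors; no mediator stages run")
        return results
    for k, pred in enumerate(mediators, start=1):
        cfg_k = replace(config, seed=_stage_seed(config.seed, k))
        results.append(
            run_stage(panel, Node(*pred), cfg_k, binarize_response=True)
        )
    return results
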