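"""Stability-LASSO engine: solver correctness, penalty choice, selection rules."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagnet._logistic import logistic_lasso_path
from lagnet.exceptions import DegenerateResponseError, TemporalOrderError
from lagnet.panel import Node
from lagnet.selection import (
    SelectionConfig,
    StabilityResult,
    _fit_path,
    _lambda_path,
    _scale_response,
    _standardize,
    run_stage,
    run_two_stage,
    select_penalty,
    stability_select,
)
from lagnet.synthetic import SyntheticSpec, generate_panel

from conftest import make_panel


import functools


@functools.lru_cache(maxsize=1)
def _monotonicity_result():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(200, 8))
    y = 0.4 * X[:, 0] - 0.2 * X[:, 3] + rng.normal(size=200)
    cfg = SelectionConfig(seed=3, n_subsamples=20, cv_folds=5)
    return stability_select(X, y, cfg)


def _single_edge_panel(n, seed, weight=0.8, noise=0.1, n_distractors=4):
    names = ["x", "y"] + [f"d{i}" for i in range(n_distractors)]
    spec = SyntheticSpec(
        n_units=n,
        variables=names,
        times=[2015, 2016, 2017],
        weights={("x", "y"): weight},
        intercepts={v: 0.0 for v in names},
        noise_sd={v: noise for v in names},
        init_mean={v: 0.0 for v in names},
        init_sd={v: 1.0 for v in names},
        seed=seed,
    )
    return generate_panel(spec)


class TestSolverAgainstSklearn:
    """The in-house logistic path solver must match an independent solver."""

    def test_logistic_path_matches_saga(self):
        rng = np.random.default_rng(1)
        n, p = 300, 8
        X = rng.normal(size=(n, p))
        eta = X[:, 0] - 0.8 * X[:, 1] - 0.2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        Xs, _ = _standardize(X, True)
        lams = _lambda_path(Xs, y, "logistic")
        b0, B = logistic_lasso_path(Xs, y, lams)
        from sklearn.linear_model import LogisticRegression

        for li in (25, 70):
            C = 1.0 / (n * lams[li])
            sk = LogisticRegression(
                C=C, solver="saga", penalty="l1", l1_ratio=1.0,
                tol=1e-10, max_iter=100000,
            )
            sk.fit(Xs, y)
            assert np.allclose(sk.coef_[0], B[li], atol=5e-6)
            assert sk.intercept_[0] == pytest.approx(b0[li], abs=5e-6)

    def test_linear_path_matches_direct_lasso(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 6))
        y = 0.5 * X[:, 0] + rng.normal(size=200) * 0.3
        Xs, _ = _standardize(X, True)
        ys = _scale_response(y, "linear", True)
        lams = _lambda_path(Xs, ys, "linear")
        _, B = _fit_path(Xs, ys, lams, "linear")
        from sklearn.linear_model import Lasso

        for li in (10, 60):
            sk = Lasso(alpha=lams[li], fit_intercept=True, tol=1e-12)
            sk.fit(Xs, ys)
            assert np.allclose(sk.coef_, B[li], atol=1e-5)


class TestSelectPenalty:
    def test_perfect_signal_keeps_the_column(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 5))
        y = X[:, 2] + rng.normal(size=120) * 1e-6
        lam = select_penalty(X, y, folds=5, family="linear", seed=0)
        Xs, _ = _standardize(X, True)
        ys = _scale_response(y, "linear", True)
        lams = _lambda_path(Xs, ys, "linear")
        _, B = _fit_path(Xs, ys, lams, "linear")
        li = int(np.argmin(np.abs(lams - lam)))
        assert B[li][2] != 0.0

    def test_penalty_is_a_path_member(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 4))
        y = rng.normal(size=100)
        lam = select_penalty(X, y, folds=5, family="linear", seed=1)
        Xs, _ = _standardize(X, True)
        ys = _scale_response(y, "linear", True)
        lams = _lambda_path(Xs, ys, "linear")
        assert np.min(np.abs(lams - lam)) < 1e-15 * max(1.0, lam)

    def test_null_model_chosen_on_pure_noise_with_1se_rule(self):
        # parsimonious penalty rule keeps the null model on noise-only data
        hits = 0
        reps = 25
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            X = rng.normal(size=(200, 5))
            y = rng.normal(size=200)
            lam = select_penalty(
                X, y, folds=5, family="linear", seed=rep, rule="1se"
            )
            Xs, _ = _standardize(X, True)
            ys = _scale_response(y, "linear", True)
            lams = _lambda_path(Xs, ys, "linear")
            _, B = _fit_path(Xs, ys, lams, "linear")
            li = int(np.argmin(np.abs(lams - lam)))
            hits += (B[li] == 0.0).all()
        assert hits >= 0.8 * reps

    def test_single_class_logistic_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        with pytest.raises(DegenerateResponseError):
            select_penalty(X, np.ones(50), folds=5, family="logistic", seed=0)


class TestStabilitySelect:
    def test_true_parent_has_frequency_one(self):
        for seed in (0, 1):
            panel, _ = _single_edge_panel(1200, seed)
            res = run_stage(panel, Node("y", 2016), SelectionConfig(seed=seed))
            byvar = {Node(*p).variable: i for i, p in enumerate(res.predictors)}
            assert res.selection_frequency[byvar["x"]] == 1.0
            assert res.selected[byvar["x"]]
            for v, i in byvar.items():
                if v != "x":
                    assert not res.selected[i]

    def test_pure_noise_selects_nothing(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(400, 10))
        y = rng.normal(size=400)
        res = stability_select(X, y, SelectionConfig(seed=9))
        assert not res.selected.any()

    def test_frequencies_are_multiples_of_inverse_subsamples(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(150, 4))
        y = X[:, 0] * 0.3 + rng.normal(size=150)
        cfg = SelectionConfig(seed=0, n_subsamples=20, cv_folds=5)
        res = stability_select(X, y, cfg)
        assert np.allclose(res.selection_frequency * 20, np.round(res.selection_frequency * 20))

    def test_selected_flag_matches_threshold_rule(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(300, 6))
        y = 0.5 * X[:, 1] + rng.normal(size=300)
        res = stability_select(X, y, SelectionConfig(seed=2, n_subsamples=25, cv_folds=5))
        assert np.array_equal(res.selected, res.reselect(0.95, 0.05))

    def test_robust_but_small_coefficient_is_rejected(self):
        # frequency 1.0 with |refit| = 0.03 fails the effect-size threshold
        res = StabilityResult(
            response=Node("y", 2016),
            predictors=[Node("x", 2015)],
            selection_frequency=np.array([1.0]),
            coefficient=np.array([0.03]),
            selected=np.array([False]),
            penalty=0.01,
            family="linear",
            frequency_threshold=0.95,
            coef_threshold=0.05,
            n_subsamples=100,
        )
        assert not res.reselect(0.95, 0.05)[0]
        assert res.reselect(0.95, 0.02)[0]

    @settings(deadline=None, max_examples=60)
    @given(
        f1=st.floats(0.01, 1.0), f2=st.floats(0.01, 1.0),
        c1=st.floats(0.0, 0.5), c2=st.floats(0.0, 0.5),
    )
    def test_threshold_monotonicity(self, f1, f2, c1, c2):
        """Raising either threshold never enlarges the selected set."""
        res = _monotonicity_result()
        lo = res.reselect(min(f1, f2), min(c1, c2))
        hi = res.reselect(max(f1, f2), max(c1, c2))
        assert not np.any(hi & ~lo)

    def test_identical_seed_gives_identical_result(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(150, 5))
        y = 0.4 * X[:, 0] + rng.normal(size=150)
        cfg = SelectionConfig(seed=5, n_subsamples=15, cv_folds=5)
        r1 = stability_select(X, y, cfg)
        r2 = stability_select(X, y, cfg)
        assert np.array_equal(r1.selection_frequency, r2.selection_frequency)
        assert np.array_equal(r1.coefficient, r2.coefficient)
        assert r1.penalty == r2.penalty

    def test_logistic_subsamples_redrawn_on_single_class(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(60, 3))
        y = np.zeros(60)
        y[:4] = 1.0  # rare class: some subsamples will miss it
        cfg = SelectionConfig(
            seed=6, n_subsamples=10, cv_folds=3, family="logistic",
            subsample_fraction=0.5,
        )
        res = stability_select(X, y, cfg)
        assert res.selection_frequency.shape == (3,)

    def test_best_subset_bic_oracle_agrees_on_single_edge_data(self):
        """Exhaustive size-<=2 best-subset search with BIC finds the same support."""
        agree = 0
        seeds = range(6)
        for seed in seeds:
            panel, _ = _single_edge_panel(600, seed, n_distractors=3)
            res = run_stage(panel, Node("y", 2016), SelectionConfig(seed=seed))
            stab = {Node(*p).variable for p in res.selected_predictors()}
            X = np.column_stack(
                [panel.series(Node(v, 2015)) for v in panel.variables]
            )
            y = panel.series(Node("y", 2016))
            n = len(y)
            best, best_bic = (), np.inf
            for k in (0, 1, 2):
                for subset in itertools.combinations(range(X.shape[1]), k):
                    A = np.column_stack([np.ones(n)] + [X[:, j] for j in subset])
                    resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
                    bic = n * np.log(resid @ resid / n) + (k + 1) * np.log(n)
                    if bic < best_bic:
                        best, best_bic = subset, bic
            oracle = {panel.variables[j] for j in best}
            agree += stab == oracle
        assert agree >= len(seeds) - 1


class TestRunStage:
    def test_binarize_forces_logistic(self, study_panel_small):
        panel, _ = study_panel_small
        cfg = SelectionConfig(seed=1, n_subsamples=10, cv_folds=3, family="linear")
        res = run_stage(panel, Node("obese", 2016), cfg, binarize_response=True)
        assert res.family == "logistic"

    def test_constant_response_binarization_fails(self):
        panel = make_panel(
            {
                ("x", 2015): [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
                ("y", 2015): [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                ("x", 2016): [5.0] * 6,
                ("y", 2016): [0.5, 0.1, 0.9, 0.3, 0.2, 0.8],
            }
        )
        with pytest.raises(DegenerateResponseError):
            run_stage(
                panel, Node("x", 2016),
                SelectionConfig(seed=0, n_subsamples=5, cv_folds=2),
                binarize_response=True,
            )

    def test_response_needs_a_preceding_slice(self, tiny_panel):
        with pytest.raises(TemporalOrderError):
            run_stage(tiny_panel, Node("a", 2015), SelectionConfig(seed=0))


class TestRunTwoStage:
    def test_study_layout_yields_six_stages(self, study_panel_small):
        panel, truth = study_panel_small
        results = run_two_stage(panel, truth.outcome, SelectionConfig(seed=4))
        assert len(results) == 6
        # mediator stages regress on the T-2 slice, own lag included
        for res in results[1:]:
            assert {Node(*p).time for p in res.predictors} == {2015}
            assert Node(Node(*res.response).variable, 2015) in [
                Node(*p) for p in res.predictors
            ]
            assert res.family == "logistic"

    def test_zero_structure_returns_single_stage_with_warning(self):
        names = ["a", "b", "c"]
        spec = SyntheticSpec(
            n_units=300,
            variables=names,
            times=[2015, 2016, 2017],
            weights={},
            intercepts={v: 0.0 for v in names},
            noise_sd={v: 0.1 for v in names},
            init_mean={v: 0.0 for v in names},
            init_sd={v: 1.0 for v in names},
            seed=0,
        )
        panel, _ = generate_panel(spec)
        cfg = SelectionConfig(seed=0, n_subsamples=20, cv_folds=5)
        with pytest.warns(UserWarning, match="no predictors"):
            results = run_two_stage(panel, Node("a", 2017), cfg)
        assert len(results) == 1
        assert not results[0].selected.any()
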