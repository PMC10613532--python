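# Methods

## The model and its assumptions

The analysis treats a panel of areal units as draws from a structural
equation system over variable–year nodes in which causes strictly precede
effects: a variable measured in year `t` may be influenced only by variables
measured in year `t−1`.  Under that ordering, penalized regression of each
node on the full preceding slice identifies the node's parent set (the
selected predictors lie on the response's Markov blanket, and temporal order
removes the usual ambiguity between parents and children), so a directed
acyclic network can be assembled stage by stage from regressions alone.

Three assumptions do real work and are taken at face value rather than
tested:

- **Causal sufficiency.** No unmeasured common causes of the panel variables;
  mediation quantities are identified only under this assumption.
- **One-year lag.** Effects operate between consecutive slices; there are no
  contemporaneous edges.  Slower processes are only visible as chains.
- **Linearity for selection, discreteness for inference.** Selection stages
  are (generalized) linear; the fitted network is then re-parameterized over
  mean-split binary variables, which coarsens but never contradicts the
  selected structure.

## Selection engine

Stage one regresses the continuous outcome on all variables of the preceding
slice.  Stage two takes each selected direct predictor, binarizes it at its
mean (strictly above → 1; ties and below → 0) and fits logistic LASSO on the
slice before that.  Decisions combine two criteria:

- **Robustness**: non-zero coefficient in at least `frequency_threshold`
  (default 0.95) of `n_subsamples` (default 100) fits on random
  `subsample_fraction` (default 0.9) subsamples drawn without replacement.
- **Effect size**: full-data refit coefficient with magnitude at least
  `coef_threshold` (default 0.05).  The threshold is closed at 0.05 — a
  coefficient of exactly ±0.05 is retained.

Penalties live on a 100-point log-spaced path from the smallest penalty that
zeroes every coefficient down to 1/1000 of it, and are chosen by seeded
K-fold (default 10) cross-validated deviance.  Two rules are exposed:

- `refit_penalty_rule = "min"` (default): the reported coefficients come from
  a full-data refit at the deviance-minimizing penalty, i.e. nearly unshrunk.
- `subsample_penalty_rule = "1se"` (default): the subsample fits that yield
  selection frequencies use the largest penalty within one standard error of
  the CV minimum.  The parsimonious rule is essential here: in strong-signal
  binarized-logistic stages the CV-minimizing penalty is so small that every
  predictor is non-zero in every subsample and frequencies stop
  discriminating.  With the 1-SE rule, noise predictors drop out of most
  subsample fits while true effects persist.

By default the subsample penalty is cross-validated **once on the full
data** and shared across subsamples (`penalty_scope = "shared"`, the classic
stability-selection formulation); re-cross-validating on every subsample is
available (`"per_subsample"`) but costs two orders of magnitude more compute
for no measurable gain in recovery on the synthetic benchmark.

**Coefficient scale.** Linear fits standardize predictors *and* response, so
coefficients are correlations-per-SD and the 0.05 effect-size floor has one
meaning across variables.  Logistic refit coefficients are reported as
average marginal effects — `mean(p̂(1−p̂)) · β` per SD of the predictor, a
probability-point change — which puts them on the same scale as the linear
coefficients; raw logit-scale coefficients would make a common 0.05 floor
vacuous.  Selection frequencies are computed on the non-zero pattern and are
scale-invariant.

Degenerate cases: a binarized response with a single class raises
immediately; a logistic subsample containing one class is redrawn (logged)
up to `10 · n_subsamples` attempts.

## Synthetic panel generator

`study_like_spec(n_units, seed)` builds the benchmark system: 30 variables
over 2015–2017.  Eleven variables carry the worked example's cross-lag
pattern — autoregressive self-lags 0.55–0.97, cross-lags of magnitude
0.05–0.17, and a final-transition override so the outcome loads on its five
direct predictors (its own self-lag is 0.55 between 2015→2016 but 0.63 into
the 2017 outcome) — and 19 variables are pure-noise distractors.  Choices
made once and why:

- initial slice `Normal(mean_v, 0.1)` with plausible county proportions as
  means; intercepts solve mean-stationarity so slices stay comparable;
- additive Gaussian noise with `sd = 0.035` for every variable, calibrated so
  the outcome-stage regression explains ≈ 62–63% of variance, matching the
  explanatory power reported for the real county extract.  Clamping to
  [0, 1] is available but off by default (the selection stages are
  scale-free, and unclamped noise keeps the system exactly linear-Gaussian);
- one master seed with per-(slice, variable-name) substreams, so adding a
  variable never perturbs existing columns and output is bit-reproducible.

What the generator deliberately does **not** emulate: spatial autocorrelation
between counties, bounded/skewed marginals of real proportions, measurement
error, policy shocks, or time-varying dynamics.  Passing recovery tests
therefore show that the machinery finds sparse cross-lag structure under the
stated model — not that the real extract satisfies that model.

## Discrete network and inference

CPTs are counting estimates with Laplace pseudo-count `α` (default 1):
`P(node=1 | config) = (n₁ + α)/(n + 2α)`; with `α > 0` no probability is
exactly 0 or 1, with `α = 0` an unobserved parent configuration is an error.
Parents are ordered by `(time, variable)` and configuration indices use the
first parent as the most significant bit.

Queries run by variable elimination with barren-node removal (only ancestors
of the target/evidence are kept) and a greedy smallest-factor elimination
order; networks here are Figure-scale (≤ ~20 nodes), so exact inference is
cheap.  Interventions mutilate the network (incoming edges of do-nodes cut,
states fixed) and reuse the same query machinery.  A brute-force full-joint
enumeration oracle ships in the package and the test suite holds elimination
to within 1e-12 of it.

## Mediation conventions

For exposure variable `v` the exposure node is `v`'s earliest network node;
the mediators are the outcome's parents **of other base variables** — a
variable's own later measurement is part of its direct pathway, not a
mediator.  This is what makes "direct predictors" carry natural direct
effects (e.g. the path diabetic@2015 → diabetic@2016 → outcome) while
indirect predictors, whose every path runs through the mediator set, have
NDE exactly zero (enforced structurally, reported as exact 0.0).

`EffectReport.total_effect` is the nested-decomposition total
`E[Y(1, M(1))] − E[Y(0, M(0))]` computed by the mediation formula, so
`TE = NDE + NIE` holds to machine precision by construction.  The
interventional contrast `P(Y|do(1)) − P(Y|do(0))` is exposed separately as
`total_effect()`; the two coincide whenever the outcome's parents are covered
by the mediators plus the exposure pathway and agree to 1e-10 in that regime
(tested); they can differ when the non-mediator parent is confounded with
the mediators, which is why the nested total is the one reported.
Per-mediator indirect effects (single-mediator formula, other mediators
marginalized under the intervention) are descriptive and need not sum to the
joint NIE when mediators interact.

Effects are risk differences in [−1, 1]; an odds-ratio readout can be formed
from the same interventional probabilities if needed.

## Numerical choices

- Binarization ties at the mean go to 0 everywhere (one shared rule).
- Penalty ties in CV resolve to the largest penalty (first on the descending
  path).
- The logistic path solver is IRLS + weighted coordinate descent with a
  working active set and full KKT checks, warm-started along the path;
  IRLS weights are floored at 1e-5 and convergence is `max|Δβ| < 1e-7`.
  It matches scikit-learn's saga solver to ~1e-9 on shared objectives.
- Zero-variance predictors get unit scale (coefficient 0) rather than NaN.
- Graph JSON/GraphML exports round-trip exactly (shortest-repr floats);
  wide-CSV panel I/O round-trips bit-for-bit
  (`float_precision="round_trip"`).

## Problem sizes used by tests and the acceptance script

Structure recovery runs at the study's scale: 3,000 units, 30 variables,
3 slices, 100 subsamples, 20 seeds (≈ 3 minutes; observed mean TPR ≈ 0.99
for planted edges with |weight| ≥ 0.1, mean FDR 0.0).  Unit tests use
smaller panels (150–1,200 units) chosen for determinism and speed; the
shared study-like fixture (1,200 units, fixed seed) is one draw where all
five mediator stages run, which is not guaranteed at that size — power for
the weakest planted effect (0.06) is only reached near full scale.

## Known limitations

- Complete-case loading: units with any missing cell are dropped (logged);
  no imputation.
- No confounding adjustment beyond the DAG's own assumptions (no inverse
  propensity weighting) and no uncertainty quantification on effects
  (bootstrap CIs are future work).
- The robustness rule exposes both published readings (95-of-100 subsample
  rule by default; a 9-of-10 reading via
  `frequency_threshold=0.9, n_subsamples=10`).
- Exact inference only; networks much beyond ~25 nodes would need a junction
  tree or sampling.
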