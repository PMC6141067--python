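# Methods

## The risk model

The classifier is a deliberately small multilayer perceptron: *p* inputs
(natural-log adduct concentrations), one hidden layer of *m* logistic
nodes, one logistic output. With the default four-adduct panel and
*m* = 10 the parameter vector
*w* = (*dᵀ*, *c₀*, *a₁ᵀ*, …, *a₁₀ᵀ*, *c₁*, …, *c₁₀*)ᵀ has
*m*(*p* + 2) + 1 = 61 entries. The output

f(x, w) = σ(c₀ + Σⱼ dⱼ σ(aⱼᵀx + cⱼ))

is read as a risk score in (0, 1). Training minimises

V(w) = (1/n) Σₖ (yₖ − f(xₖ, w))² + (α/2)‖w‖²

by plain full-batch gradient descent with a fixed step, for a fixed
number of updates. The objective is a single deterministic function of
the whole training set, so the update is the exact analytic gradient of
V (backpropagation through both logistic layers plus the α·w decay
term); there is no stochasticity beyond the initialisation, and no
momentum, line search, restarts or early stopping. Squared-error loss on
a logistic output (rather than cross-entropy) is a modelling choice with
consequences: gradients vanish as scores saturate, so the weight-decay
term, not the loss, ultimately limits ‖w‖.

Defaults, with units and rationale:

| parameter | default | meaning |
| --- | --- | --- |
| α | 0.0004 | weight-decay coefficient (per-unit ‖w‖² penalty) |
| μ | 0.02 | gradient-descent step size |
| n_updates | 50 000 | exact number of full-batch updates performed |
| m | 10 | hidden-layer width |
| init_scale | 0.5 | half-width of the uniform initialisation |

α, μ, n_updates and m are the analysis's operating constants. The
initialisation is this package's own choice — independent uniform draws
on [−0.5, 0.5] from one seeded generator — picked as a standard small
symmetric start for logistic networks; it is part of the model
configuration and fully reproducible from the seed. Inputs are the raw
natural-log concentrations; no centering or standardisation is applied
(none is part of the analysis; for log-concentrations of magnitude a few
units the network trains without it).

The mean-squared-error prefactor is 1/n for whatever training set is
supplied (the full 223-subject cohort or an 80% training split), since
validation retrains on subsets.

## Decision threshold

Scores are binarised by `score ≥ t`. Instead of the conventional
t = 0.5, the operating threshold is selected by evaluating the training
error rate at every t on the fixed grid 0.00, 0.01, …, 1.00 and taking
t_opt = (t_min + t_max)/2, the midpoint of the smallest and largest grid
thresholds attaining the minimum error. The grid step is deliberately
not configurable: the 101-point scan is the analysis's operating
characteristic. When the set of minimising thresholds is not contiguous
(possible, e.g., for anti-correlated scores with balanced classes) the
extremes are still reported per the literal rule, but a warning is
logged because the midpoint then need not attain the minimum.

## ROC and AUC

Two AUC estimates are computed. The *sweep* AUC traces the ROC polygon
over the same 101-threshold grid and integrates by trapezoids; it is
reported because it is the quantity the threshold-scan procedure
naturally produces, but it inherits the 0.01 grid resolution (scores
clustered between two grid points move in a block, so a separable score
set can read slightly below 1). The *rank* AUC is the exact Mann–Whitney
statistic — the probability that a random case outscores a random
control, ties counted ½, computed from midranks — and is the quantity
used wherever exactness matters. On tie-free scores the two agree to
within the grid resolution (≤ 0.02 band asserted in tests).

## Validation

Repeated stratified holdout: per repeat, each class is independently
permuted and floor(0.8·n_class) subjects enter the training set (152/71
→ 121 cases + 56 controls, the only rounding consistent with those
counts); the network is trained on the training split only; t_opt is
selected on training scores only and frozen; error at t_opt and rank AUC
are evaluated on both splits. Twenty repeats by default; means and
sample (n−1) standard deviations are reported, with SD defined as 0 for
a single repeat. All partitions and per-repeat training seeds derive
from one master generator, so the whole experiment reproduces from a
single integer.

The full-cohort reports (`run_case_full`, `full_data_report`) are
*apparent* operating characteristics: threshold scan and ROC evaluated
on the same samples the model was fitted to. That is the intended
protocol for the panel-screening table, but apparent AUC is optimistic
by construction; the holdout report is the honest generalisation
estimate.

Five panel cases are evaluated: the full four-adduct panel (Case 1) and
the four three-adduct panels that drop, respectively, Hb 3,4-Q
(Case 2), Hb 2,3-Q (Case 3), Alb 3,4-Q (Case 4) and Alb 2,3-Q (Case 5),
so each adduct is omitted exactly once.

## Synthetic cohorts

The generator draws each group from a multivariate lognormal (normal on
the log scale), the simplest family matching the model's log-scale
inputs and roughly elliptical group clusters. The default configuration
is calibrated to four qualitative facts about real adduct panels:

1. median Alb 3,4-Q : 2,3-Q ratio ≈ 2 in cases, ≈ 0.5 in controls
   (log-mean differences ± ln 2);
2. median Hb 3,4-Q : 2,3-Q ratio ≈ 2 in both groups;
3. cases and controls overlap in each per-protein (3,4-Q vs 2,3-Q)
   scatter projection;
4. the groups are separable in the full four-marker log space.

Facts 3 and 4 coexist through the covariance structure: a shared
per-subject factor (loading λ = 1.0 on all four log-markers,
representing between-subject variation in cumulative estrogen exposure)
dominates each two-marker projection, while the idiosyncratic noise is
small (σ = 0.18 for Hb, 0.33 for Alb). Within a projection the case
shift lies mostly along the shared-factor direction, so the clusters
overlap (two-marker Mahalanobis separations ≈ 2.2 and 3.0, Bayes errors
≈ 14% and 7%); in four dimensions the exposure factor cancels out of
cross-protein and within-protein-difference contrasts, leaving a
Mahalanobis separation ≈ 7.6 (Bayes error < 1e−4). Sampled 223-subject
cohorts are therefore practically always linearly separable in 4-D
while neither 2-D projection is — verified by LP feasibility in the
tests. Case log-means are elevated by 2.2 (Hb) and 0.4 (Alb) over
controls, and baselines put concentrations at a few units; the data
carry no units (the assay's absolute scale is irrelevant to the
log-space analysis and is left unspecified).

What the generator does **not** emulate: assay measurement error as a
separate variance component, covariates (age, BMI, menopausal status),
and whatever fine structure makes real three-adduct subpanels imperfectly
separable. Consequently, passing tests show the pipeline is correct and
that the stated geometry implies the stated operating points; they do
not show that real cohorts are separable — on measured data the
three-adduct cases are expected to show small nonzero errors, as the
synthetic Case 5 already does.

## Numerical choices

* Logistic functions evaluate via `scipy.special.expit` (no overflow at
  saturated arguments).
* Gradient correctness is anchored to a central finite-difference oracle
  (step 1e−6, max-norm tolerance 1e−6 at random small-weight points);
  the analytic and trained paths share one implementation, so the oracle
  covers the trainer.
* Threshold-grid ties: error rates at different thresholds are exact
  multiples of 1/n computed identically, so float equality against the
  minimum is exact, not approximate.
* Degenerate inputs: single-class training sets, empty cohorts,
  non-positive concentrations and non-positive-definite covariances are
  rejected with explicit errors; all-equal score vectors still produce a
  well-defined threshold scan.
* Cohort CSVs render floats with `repr` and are parsed with
  `float_precision="round_trip"`, so write→read is bit-exact. XLSX
  stores ~15 significant digits and round-trips only to that precision.
* Fixed-step descent is not guaranteed monotone; the final objective
  being below the initial one is asserted for the packaged fixtures as a
  monitored sanity property, not claimed as a theorem.

## Problem sizes

Study-scale computations use the 223-subject cohort (152/71) with the
full 50 000-update schedule — a few seconds per training on one core.
Structural tests (I/O, determinism, report shapes) use abbreviated
schedules (500–2000 updates) and a 45-subject cohort, since they assert
plumbing rather than convergence. The acceptance script runs 105
full-schedule trainings (5 panel cases full-cohort + 5 × 20 holdout
repeats).

## Known limitations

* Fixed-step full-batch descent with a fixed iteration count is the
  analysis's procedure, not a recommendation; it can oscillate or stop
  short on other data. No convergence criterion is applied.
* Apparent (training-set) AUC for the full-cohort table is optimistic;
  use the holdout report for generalisation claims.
* The sweep AUC is grid-coarsened; compare models on the rank AUC.
* No missing-value handling: the analysis is complete-case only.
* The synthetic default cannot reproduce any particular real cohort's
  table values, only the qualitative overlap/separability structure.
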