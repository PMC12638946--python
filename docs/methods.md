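# Methods

## Model

`riskaudit` fits a main-effects additive logistic model: for a patient with
features `x = (x₁, …, x_R)` and binary outcome `Y`,

    logit P(Y = 1 | x) = β₀ + Σᵣ fᵣ(xᵣ).

Each component `fᵣ` is piecewise constant over a fixed bin grid: quantile
bins for continuous features (at most `max_bins`, empty bins merged left,
deduplicated; a feature with ≤ `max_bins` distinct values gets midpoint cuts
between distinct values), the `{0,1}` split for booleans, one bin per
category for nominals, plus a dedicated missing bin whenever a feature has
missing values. Bins are half-open `[lo, hi)` with the last bin closed
above; a value exactly on a threshold belongs to the right-hand bin. The
outer bins are unbounded; the observed data range ("support") is stored so
each bin has a finite representative point (its midpoint, outer bins
anchored at the data extremes).

Components are identified by centering: after fitting, each component's
training-count-weighted mean is subtracted (shifting the intercept), so
`fᵣ` reads as a log-odds contrast against the cohort average and the
intercept carries the base rate. Centering never changes predictions.

### Fitting

Round-robin gradient boosting of depth-1 learners: every round visits the
features in schema order; a visit computes the gradient `g = y − p` and
hessian `h = p(1−p)` of the Bernoulli log-loss at the current scores,
aggregates both over the feature's bins, picks the single split on the
ordered bin grid maximizing the second-order gain `G_L²/H_L + G_R²/H_R`
(ties to the smaller bin index, for determinism), and adds the shrunken
Newton leaf values `lr·G/H` to the component. The missing bin, when present,
is its own leaf at every visit. Second-order (Newton) leaf values are used
rather than plain gradient means because their per-visit contraction is
~`lr` regardless of the outcome rate; gradient-mean leaves contract as
`lr·p(1−p)` and fail to converge within a practical round budget when
outcomes are rare.

Two regularizers control overfitting:

* **Early stopping** (default): 15% of the training samples are held out;
  fitting stops after `early_stop_patience = 50` rounds without validation
  log-loss improvement and the best-round component values are kept.
* **Activation gate** (`split_alpha`, default 0.05): a feature's component
  stays at exactly zero until the first visit in which its best split
  improves the gain over the no-split update by more than the χ²(1)
  critical value at level `split_alpha / n_candidate_splits` — a Bonferroni
  bound on the best of the feature's candidate splits under the null. Once
  activated, a feature boosts without further gating. The gate keeps null
  features exactly flat (no accumulated noise wiggles for the artifact scan
  to trip over) while leaving real effects unbiased — an always-on gain
  floor was rejected because its stopping bias `≈ √(floor/H)` is shared
  across bootstrap bags and therefore invisible to the confidence bands.

Defaults: `max_bins = 64`, `learning_rate = 0.1`, `n_rounds = 500` with
early stopping, `n_bags = 100`, `bag_fraction = 1.0` (resampling with
replacement). All randomness derives from a single integer seed through
`numpy.random.SeedSequence`; identical seed and data give bit-identical
models.

### Bagging and confidence bands

`n_bags` bootstrap resamples are fitted on one shared bin grid (computed
once on the full data), so bag curves are comparable bin by bin. Reported
component values are bag means; the per-bin confidence band is the empirical
`(α/2, 1−α/2)` quantile across bags (default 95%). The bands capture
resampling variance, not model bias; with the activation gate that bias is
negligible for activated features and exactly zero for inactive ones.

## Artifact detection

### Discontinuities

For a component with thresholds `t_{r,0} < … < t_{r,K−1}`, a threshold
`t_{r,j}` is testable when both neighbours exist (`1 ≤ j ≤ K−2`; a
component therefore needs ≥ 4 bins). The locally-linear surrogate `f̃ᵣ`
replaces the component on the window `[t_{r,j−1}, t_{r,j+1})` by the
straight line joining `f(t_{r,j−1})` and `f(t_{r,j+1})` (the bins to the
right of each window edge, by the half-open convention) and leaves it
untouched elsewhere. The test statistic is the exact log-likelihood
difference

    T_d(r, j) = ℓ(fᵣ | X, Y) − ℓ(f̃ᵣ | X, Y),

with all other components and the intercept fixed; only samples inside the
window contribute, which makes the scan cheap. `T_d = 0` identically when
the component is flat across the window, and `T_d` is invariant to constant
component shifts with compensating intercept changes. An alternative
signed-sum reduction (outcomes coded ±1, summing component differences
directly) is available behind `method="signed_sum"` but is not the default:
its scale mixes conventions and it is retained only for comparison.

Per threshold, `T_d` is computed within every bag (each bag's own component
linearized inside its own model); the *bag support* is the fraction of bags
with `T_d > 0`. A discontinuity is flagged when support ≥ `support_level`
(default 0.95) and the bag-median `T_d` is positive. Windows holding fewer
than `min_window_count = 20` training samples are marked low-confidence
rather than dropped — apparent jumps in sparse regions are noted, not
trusted. Rankings order by support, then |median `T_d`|.

Known limitation: `T_d` tests the fitted step pattern against a *linear*
null. Strong genuine curvature inside a window (e.g. the steep flank of a
U-shaped risk curve) can yield positive `T_d` without any treatment
threshold; the statistic localizes candidate thresholds and is read together
with the non-monotonicity scan and clinical context, not as a causal
certificate.

### Non-monotonicities

Per-threshold slopes `s_{r,j} = (y_{r,j+1} − y_{r,j}) / (rep_{j+1} − rep_j)`
(value change across threshold `j` over the span between bin
representatives) are reduced to signs with a dead zone
`slope_zero_tol = 1e−8`; zeros are removed and the remaining sign sequence
is scanned for persistent regime flips by run-length detection — a flip
counts only when both the old and the new sign persist for `min_run = 2`
consecutive non-zero slopes. A `+ → −` flip is a **concave** changepoint (a
risk peak), `− → +` is **convex** (a valley). Only concave changepoints can
be flagged, and only when a concave changepoint appears within a one-bin
window in ≥ `support_level` of bags; convex valleys are reported but never
flagged, since a U shape over a biomarker usually marks its healthy range.
Only the slope *signs* enter detection, so the denominator normalization is
immaterial; with short ternary sequences, run-length detection is equivalent
to binary segmentation with a 0/1 sign-agreement cost.

Multiple testing across thresholds and features is handled by the bag
support requirement, not by p-value correction; support is an empirical
stability measure, not a calibrated error rate — a documented limitation.

## Treatment-threshold simulator

The generative model: biomarker `x` drawn from a truncated normal (mean 5,
s.d. 2) on `[0, 10]` (grid step 0.05); untreated risk
`p0(x) = expit(a + b·x)` with defaults `a = −4`, `b = 1` (monotone by
assumption — intrinsic risk increases smoothly in the biomarker); treated
risk `p1` from one of four benefit shapes:

| kind               | contract                                  | default |
|--------------------|-------------------------------------------|---------|
| `flattens_risk`    | `p1 ≡ level`                              | 0.15    |
| `limits_risk`      | `p1 = min(p0, cap)`                       | 0.30    |
| `reduces_biomarker`| `p1(x) = p0(x − shift)`                   | 2.0     |
| `constant_benefit` | `logit p1 = logit p0 − offset`            | 1.5     |

and an adherence policy `π(x)`: strict `1[x ≥ τ]` or loose
`expit((x − τ)/w)` with ramp width `w = 0.5`. The default protocol
threshold `τ = 4.0` is a deliberate "round number" above the optimal
threshold of the default benefit curves, so misalignment artifacts are
present by construction. Observed population risk is the mixture
`p = π·p1 + (1−π)·p0`; cohorts sample `treated ~ Bernoulli(π(x))` and
`outcome ~ Bernoulli(p_treated-or-not(x))`, plus independent standard-normal
nuisance features. The treatment flag is generated but excluded from
exported features by default — treatment as an unobserved confounder is the
premise being audited.

The optimal threshold `x*` is the smallest grid point where `p0` rises
above `p1`; when the curves never change order the domain boundary is
returned with a "treat everyone" / "never treat" note, and more than one
order change is an error demanding a refined scenario. Excess risk of a
policy is `∫ [p_policy(x) − p_opt(x)] φ(x) dx` with `p_opt` strict
adherence at `x*`, integrated by the midpoint rule per grid cell — exact
for policy steps sitting on grid points, where a trapezoid would smear the
jump — and zero iff the policy matches the optimal strict policy almost
everywhere under the density.

What the generator does **not** emulate: correlated comorbidities,
time-varying or dose-dependent treatment, measurement error in the
biomarker, informative missingness, multi-biomarker decision rules. Passing
recovery tests on these cohorts shows the pipeline finds the artifacts its
causal model produces; it does not certify behaviour on real EHR data,
where thresholds interact and documentation is incomplete.

## Experiment definitions and problem sizes

The test suite and `scripts/acceptance.py` run the following experiments
(sizes chosen as the package's standard audit profile: cohorts of
n = 20,000; fits with `n_bags = 20`, `n_rounds = 150`, `max_bins = 16` for
scan experiments; `n_rounds = 200`, `learning_rate = 0.1`, default bins for
the recovery experiment):

* **Exactness** — `T_d` is 0 (≤ 1e−12) on flat windows and matches an
  independent per-row Bernoulli log-likelihood sum to 1e−9.
* **Parameter recovery** — cohorts simulated from a known additive logistic
  model (a 4-level step component and a linear component, plus 3 nuisance
  features); fitted bin values are compared to the within-bin mean of the
  generating component (its L2-optimal piecewise-constant projection):
  per-bin RMSE ≤ 0.15 log-odds, nuisance components < 0.1.
* **Discontinuity recovery** — strict `flattens_risk` scenario; the
  top-ranked flagged discontinuity must fall within one bin of the protocol
  threshold in ≥ 90% of replicates (50 in the test suite, 20 in the
  acceptance script).
* **Non-monotonicity recovery and specificity** — loose scenario: a flagged
  concave changepoint within one bin of the population-risk peak in ≥ 90%
  of replicates; U-shaped intrinsic-risk control: concave flags in ≤ 5% of
  replicates; null data (20 independent features): flagged features ≤ 5%.
* **Scenario suite** — exactly 8 bundles; every strict population curve
  jumps > 0.02 absolute risk at `τ`; every loose curve's largest adjacent
  grid jump < 0.02; mixture bounds `min(p0,p1) ≤ p ≤ max(p0,p1)` pointwise.
* **Excess risk** — zero at `x*` (≤ 1e−6); positive and non-decreasing in
  the undertreatment gap, matching adaptive quadrature on the closed forms.
* **Reproducibility** — identical seeds give byte-identical cohort CSVs and
  bit-identical models.

## Numerical choices

* Probabilities are clipped to `[1e−12, 1 − 1e−12]` inside likelihoods
  (with a warning), so `T_d` stays finite on degenerate fits.
* Split-gain ties break toward the smaller bin index; bag seeds are spawned
  deterministically from the master seed.
* Model JSON serializes floats by shortest round-trip repr; curve CSVs use
  `%.17g` and are parsed with round-trip float precision, so export →
  import preserves `T_d` to better than 1e−12. Unbounded outer bin edges
  serialize as `-inf` / `+inf`; each feature's finite support travels in
  `#`-comment headers.
* Constant features produce single-bin components, flagged untestable;
  boolean and nominal components are excluded from the artifact scan
  (no ordered interior thresholds).
* Unbagged models can be scanned, but nothing is ever flagged without bag
  evidence (point estimates only, with a warning).
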