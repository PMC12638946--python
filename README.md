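# riskaudit

Glass-box additive risk models and automatic detection of the statistical
artifacts that threshold-guided clinical practice leaves in observational
risk curves.

## The problem

Risk models trained on observational clinical data learn *effective* risk —
risk after clinicians have already intervened — not intrinsic biological
risk. When treatment is triggered by a biomarker threshold (treat when
creatinine exceeds some round number, say), the observed population risk
curve inherits characteristic distortions: a **jump discontinuity** at the
protocol threshold when adherence is strict, or a **counter-causal concave
peak** (risk *falling* as the biomarker worsens) when guidance is loose.
Rather than treating this confounding as noise to remove, `riskaudit` treats
it as signal: the artifacts localize where practice thresholds sit and where
they are misaligned with the optimal treatment point.

The package provides:

1. **`gam` — a glass-box risk model.** A main-effects generalized additive
   model on the log-odds scale,

   `logit P(Y=1 | x) = β₀ + Σᵣ fᵣ(xᵣ)`,

   with each component `fᵣ` piecewise constant over quantile bins, fitted by
   round-robin boosting of single-split tree learners (so components can
   place jumps at any bin edge) and bagged over bootstrap resamples for
   per-bin confidence bands.

2. **`detect` — the artifact scan.** For every interior threshold `t_{r,j}`
   of a component, the discontinuity statistic

   `T_d = ℓ(fᵣ | X, Y) − ℓ(f̃ᵣ | X, Y)`

   compares the Bernoulli log-likelihood of the fitted component against a
   locally-linearized version `f̃ᵣ` (linear interpolation across
   `[t_{r,j−1}, t_{r,j+1})`, everything else unchanged). Non-monotonicities
   are found by changepoint detection on the signs of the non-zero
   per-threshold slopes; only **concave** changepoints (peaks) are flagged —
   convex valleys are usually genuine healthy ranges. Findings are ranked by
   bootstrap bag support: an artifact counts only if it recurs in ≥95% of
   bagged models.

3. **`simulate` — the causal sandbox.** Eight scenarios (four treatment
   benefit shapes × strict/loose adherence) compose untreated risk `p0`,
   treated risk `p1` and an adherence policy `π` into observed population
   risk `p = π·p1 + (1−π)·p0`, sample patient-level cohorts from it, and
   quantify the excess risk of a misaligned protocol threshold relative to
   the optimal threshold `x*` where `p0` crosses above `p1`.

## Worked example

```python
import riskaudit as ra

# a cohort where clinicians treat strictly above biomarker 4.0,
# although treatment already pays off above ~2.3
scenario = ra.make_scenario("flattens_risk", "strict", threshold=4.0)
print(ra.optimal_threshold(scenario).x)        # 2.3
cohort = ra.sample_cohort(scenario, n=20_000, seed=11)
table = cohort.to_table()                      # treatment flag hidden

model = ra.AdditiveRiskModel(table)
res = model.fit(n_bags=20, n_rounds=150, max_bins=16, seed=13)
report = ra.scan_artifacts(res, table)
top = report.ranked_discontinuities()[0]
print(top.feature, round(top.threshold, 2), round(top.statistic_median, 1),
      top.bag_support, top.flagged)
```

Output:

```
2.3
biomarker 3.65 212.8 1.0 True
```

The scan top-ranks a flagged discontinuity at biomarker ≈ 3.7 — the
quantile-bin edge just below the hidden protocol threshold 4.0 — with `T_d`
median ≈ 213 log-likelihood units and support in 20/20 bags. The gap between
the recovered threshold (≈4) and the optimal one (2.3) is the audit's
clinical message: patients in between carry excess risk, here

```python
print(round(ra.excess_risk(scenario), 4))      # 0.0404 absolute risk
```

Re-running with `"loose"` adherence produces no jump; instead the top
finding is a flagged *concave* non-monotonicity at the population-risk peak
(≈3.8), the signature of soft threshold guidance.

The same workflow runs from the shell:

```bash
riskaudit simulate --out sims --n 20000 --seed 1
riskaudit fit --data sims/flattens_risk-strict/cohort.csv \
              --out model.json --curves curves.csv --n-bags 20 --max-bins 16
riskaudit detect --model model.json \
                 --data sims/flattens_risk-strict/cohort.csv --out report.json
riskaudit report --report report.json
```

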