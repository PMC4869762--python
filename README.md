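# panelcf

Panel-data counterfactual estimators for policy evaluation, and a Monte
Carlo harness for comparing them.

When a policy (a pay-for-performance scheme, a tariff, a regulation) is
adopted by some units of a balanced panel — hospitals observed by quarter,
say — the effect of interest is the **average treatment effect on the
treated (ATT)**: for post-adoption periods `t > T0`,

    τ_t = E[Y¹_it − Y⁰_it | D_it = 1],

where the untreated outcome follows `Y⁰_it = X_it β + λ_t μ_i + δ_t + ε_it`
with a time-invariant unobserved confounder `μ_i` whose loading `λ_t` may
drift over time. `panelcf` implements four estimators that resolve the
missing counterfactual under two non-nested assumptions:

| estimator | identifying assumption |
|---|---|
| `DifferenceInDifferences` | parallel trends (`λ_t` constant): two-way fixed-effects WLS |
| `LaggedDependentVariable` | independence conditional on past outcomes: post-period OLS on covariates, all `T0` pre-period outcomes, and the treatment indicator |
| `SyntheticControl` | same, semiparametric: simplex-constrained reweighting of controls minimizing `(X1 − X0 W)' V (X1 − X0 W)`, for multiple treated units via a weighted treated aggregate |
| `GeneticMatchingDiD` | same: evolutionary balance-optimized Mahalanobis matching on pre-period outcomes/covariates, then DiD on the matched sample |

All estimators honour frequency weights (e.g. admissions per
hospital-quarter) and cluster-robust inference; the synthetic control is
accompanied by placebo permutation inference. The package also provides
parallel-trends and conditional-independence pre-tests, balance tables
with standardized differences, a fully parameterized data-generating
process with scenario presets (parallel trends holding/failing, serial
correlation, high outcome variance), and a harness that reports each
estimator's percentage bias and RMSE over replicated panels.

## Worked example

Generate one panel from scenario B (a trending `λ_t` breaks parallel
trends; the true ATT is 10) and compare the estimators:

```python
import numpy as np
from panelcf import (generate_panel, scenario_presets, fit_did, fit_ldv,
                     fit_match_did, MatchSpec, placebo_test, pretrend_test)
from panelcf.synth import SyntheticControl

cfg = scenario_presets("B", 10)                 # 150 units, 75 treated, T=10
panel, _ = generate_panel(cfg, rng=np.random.default_rng(1))

print(f"parallel pre-trends test: p = {pretrend_test(panel):.2g}")
did = fit_did(panel)
ldv = fit_ldv(panel)
synth = SyntheticControl(panel, v_mode="outcome-priority").fit()
match, _ = fit_match_did(panel, MatchSpec(population=20, generations=10, seed=1))
for r in (did, ldv, synth, match):
    se = f"  (SE {r.se:.2f})" if r.se is not None else ""
    print(f"  {r.method:>5}: ATT = {r.att:5.2f}{se}")

placebo = placebo_test(
    panel, R=200, rng=np.random.default_rng(11),
    estimator=lambda p: SyntheticControl(p, v_mode="outcome-priority").fit(),
)
print(f"  synth placebo p = {placebo.p_value:.3f}")
```

This prints:

```
parallel pre-trends test: p = 8.2e-05
    did: ATT =  3.98  (SE 1.84)
    ldv: ATT = 11.23  (SE 2.54)
  synth: ATT =  7.64
  match: ATT =  5.36  (SE 2.21)
  synth placebo p = 0.040
```

The pre-test correctly rejects parallel pre-trends, and the DiD estimate
(3.98) is badly biased for the true ATT of 10, while the
lagged-dependent-variable estimate (11.23) — which uses the pre-period
outcomes to proxy the drifting confounder — lands close to the truth.
That single draw reflects the systematic comparison: over 300 replications
of this scenario the DiD bias is about −46% against roughly +2% for LDV.

The same analysis runs from the shell on any long-format CSV panel
(columns `unit,time,treated,outcome,...`):

```
panelcf estimate --method ldv --data panel.csv --t0 9 --covariates x1,x2
panelcf diagnose --data panel.csv --t0 9 --covariates x1,x2
panelcf table3 --reps 300 --seed 0 --out grid.csv     # full scenario grid
```

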