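"""Placebo permutation inference and identification pre-tests.

* :func:`placebo_test` -- permutation-style inference for estimators
  without an analytic standard error (primarily the synthetic control):
  control units are iteratively re-labelled "placebo treated" with
  probability equal to the original treated share, the estimator is re-run
  on the control pool, and the p-value is the share of replicates whose
  absolute placebo ATT exceeds the observed |ATT|.  This is a
  falsification test, not a sampling-uncertainty p-value.

* :func:`pretrend_test` -- parallel-trends pre-test: on the pre-treatment
  periods, a two-way FE regression with a treated-group x linear-time
  interaction; the cluster-robust test of the interaction is a test of
  equal pre-period slopes.

* :func:`conditional_independence_test` -- holds out the final
  pre-treatment period and asks whether the treated-group label still
  predicts it given earlier outcomes and covariates; under independence
  conditional on past outcomes it should not.

The two pre-tests are this package's operationalizations of the
identification checks; the assumptions themselves are untestable and
these remain necessary-condition diagnostics only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import PanelDataset
from .synth import fit_synth
from .wls import wls_fit

__all__ = [
    "PlaceboResult",
    "placebo_test",
    "pretrend_test",
    "conditional_independence_test",
]


@dataclass
class PlaceboResult:
    """Observed ATT against its placebo distribution."""

    observed_att: float
    placebo_atts: np.ndarray
    p_value: float
    n_replicates: int
    n_failures: int = 0

    def __post_init__(self):
        expected = float(
            np.mean(np.abs(self.placebo_atts) > abs(self.observed_att))
        )
        assert abs(self.p_value - expected) < 1e-12
        assert 0.0 <= self.p_value <= 1.0

    def summary(self) -> str:
        return (
            f"Placebo test: observed ATT {self.observed_att:.6g}, "
            f"p = {self.p_value:.4g} over {self.n_replicates} replicates "
            f"(share of |placebo ATT| strictly exceeding |observed|)"
        )


def placebo_test(
    panel: PanelDataset,
    estimator=fit_synth,
    R: int = 200,
    rng=None,
    max_failure_share: float = 0.2,
) -> PlaceboResult:
    """Placebo permutation test over the control pool.

    In each of ``R`` replicates every control unit independently becomes
    placebo-treated with probability ``n_treated / n_units``; draws that
    leave no placebo-treated or no remaining control units are redrawn, as
    are replicates in which the estimator fails (a failure share above
    ``max_failure_share`` is a hard error).  "Exceeds" is strict, so an
    observed ATT of exactly zero has p close to 1.
    """
    if panel.n_control < 2:
        raise ValueError("placebo test needs at least 2 control units")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    observed = float(estimator(panel).att)
    co = ~panel.treated
    n_c = int(co.sum())
    q = panel.n_treated / panel.n_units
    atts = np.empty(R)
    failures = 0
    r = 0
    while r < R:
        assign = rng.random(n_c) < q
        k = int(assign.sum())
        if k == 0 or k == n_c:
            continue
        placebo_panel = PanelDataset(
            units=panel.units[co], y=panel.y[co], treated=assign,
            T0=panel.T0, X=panel.X[co], weights=panel.weights[co],
            covariate_names=panel.covariate_names,
        )
        try:
            atts[r] = float(estimator(placebo_panel).att)
        except Exception:
            failures += 1
            if failures > max_failure_share * R:
                raise RuntimeError(
                    f"placebo estimator failed in {failures} replicates "
                    f"(> {max_failure_share:.0%} of R={R})"
                )
            continue
        r += 1
    p = float(np.mean(np.abs(atts) > abs(observed)))
    return PlaceboResult(
        observed_att=observed, placebo_atts=atts, p_value=p,
        n_replicates=R, n_failures=failures,
    )


def _cluster_coef_p(Z, y, w, clusters, col):
    fit = wls_fit(Z, y, weights=w, clusters=clusters)
    se = fit.bse()
    if se is None or not np.isfinite(se[col]) or se[col] == 0:
        return None
    G = fit.n_clusters
    t = abs(fit.params[col]) / se[col]
    return float(2.0 * stats.t.sf(t, max(G - 1, 1)))


def pretrend_test(panel: PanelDataset) -> float:
    """Cluster-robust p-value for equal pre-treatment linear trends.

    Fits the pre-period outcomes on unit effects (within transformation),
    time effects and a treated x centered-time interaction, weighting by
    the frequency weights and clustering on units; returns the p-value of
    the interaction.  Small p rejects parallel pre-trends.
    """
    if panel.T0 < 3:
        raise ValueError("pretrend test needs T0 >= 3 pre-treatment periods")
    n, T0 = panel.n_units, panel.T0
    N = n * T0
    y = panel.y[:, :T0].ravel()
    w = panel.weights[:, :T0].ravel()
    unit_idx = np.repeat(np.arange(n), T0)
    t_idx = np.tile(np.arange(T0, dtype=float), n)
    time_d = (t_idx[:, None] == np.arange(1, T0)[None, :]).astype(float)
    X = panel.X[:, :T0, :].reshape(N, panel.n_covariates)
    inter = np.repeat(panel.treated.astype(float), T0) * (t_idx - t_idx.mean())
    Z = np.column_stack([time_d, X, inter])

    wsum = np.bincount(unit_idx, weights=w)
    means = np.stack(
        [np.bincount(unit_idx, weights=w * Z[:, j]) / wsum for j in range(Z.shape[1])],
        axis=1,
    )
    Zd = Z - means[unit_idx]
    yd = y - (np.bincount(unit_idx, weights=w * y) / wsum)[unit_idx]
    p = _cluster_coef_p(Zd, yd, w, unit_idx, Z.shape[1] - 1)
    if p is None:
        raise RuntimeError("pretrend test variance unavailable")
    return p


def conditional_independence_test(panel: PanelDataset) -> float:
    """Hold-out test of independence conditional on past outcomes.

    Regresses the final pre-period outcome ``Y_{i,T0}`` on the earlier
    pre-period outcomes, pre-averaged covariates and the treated-group
    label (one row per unit, heteroskedasticity-robust variance); returns
    the p-value on the treated coefficient.  Small p indicates the groups
    differ beyond what their outcome history explains.
    """
    if panel.T0 < 2:
        raise ValueError(
            "conditional independence test needs T0 >= 2 pre-treatment periods"
        )
    n, T0 = panel.n_units, panel.T0
    y = panel.y[:, T0 - 1]
    lags = panel.y[:, : T0 - 1]
    w_pre = panel.weights[:, : T0 - 1]
    covs = [
        (panel.X[:, : T0 - 1, j] * w_pre).sum(axis=1) / w_pre.sum(axis=1)
        for j in range(panel.n_covariates)
    ]
    Z = np.column_stack(
        [np.ones(n), lags] + covs + [panel.treated.astype(float)]
    )
    w = panel.weights[:, T0 - 1]
    p = _cluster_coef_p(Z, y, w, np.arange(n), Z.shape[1] - 1)
    if p is None:
        raise RuntimeError("conditional independence test variance unavailable")
    return p
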