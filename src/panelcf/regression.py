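"""Regression estimators of the ATT.

* :class:`DifferenceInDifferences` -- the two-way fixed-effects model

  .. math:: Y_{it} = X_{it}\\beta + \\alpha_i + \\delta_t + \\tau D_{it} + \\varepsilon_{it}

  identified under parallel trends: unobserved unit confounders are
  absorbed by the unit effects provided their loading is constant in time.

* :class:`LaggedDependentVariable` -- ANCOVA-style OLS on the
  post-treatment rows only,

  .. math:: Y_{it} = X_{it}\\beta + \\sum_{k=1}^{T_0}\\theta_k Y_{ik} + \\tau D_i + \\nu_{it},

  identified under independence conditional on past outcomes: the full
  vector of pre-treatment outcomes proxies the (possibly time-varying)
  effect of unobserved confounders.

Both apply frequency weights as weighted least squares and report CR1
cluster-robust standard errors, clustering on units.  Unit fixed effects
in the DiD model are removed by weighted within-unit demeaning of every
regressor (Frisch-Waugh), which is numerically identical to the explicit
dummy-variable regression.

With several post-treatment periods the treatment indicator is saturated
(one effect per post period) and the reported ATT is the treated-weight-mass
average of the per-period effects, with its standard error from the joint
covariance; with a single post period -- the case in all canonical
simulation scenarios -- this is exactly the coefficient on the pooled
``D_it``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .panel import PanelDataset
from .results import EstimateResult
from .wls import WLSFit, wls_fit

__all__ = [
    "DifferenceInDifferences",
    "LaggedDependentVariable",
    "DiDResults",
    "LDVResults",
    "fit_did",
    "fit_ldv",
]


def _t_pvalue(att: float, se: float, df: int) -> float | None:
    if se is None or se == 0 or df < 1:
        return None
    return float(2.0 * stats.t.sf(abs(att) / se, df))


def _period_weights(panel: PanelDataset) -> np.ndarray:
    """Treated frequency-weight mass per post period, normalized."""
    w = panel.weights[panel.treated, panel.T0:].sum(axis=0)
    return w / w.sum()


def _combine(taus: np.ndarray, vcov_tt: np.ndarray | None, omega: np.ndarray):
    att = float(omega @ taus)
    se = None
    if vcov_tt is not None and np.all(np.isfinite(vcov_tt)):
        se = float(np.sqrt(omega @ vcov_tt @ omega))
    return att, se


class DiDResults(EstimateResult):
    """Two-way FE fit: ATT plus coefficients, effects and residuals."""

    def __init__(self, *, beta, beta_names, time_effects, unit_effects,
                 residuals, vcov_tau, **kw):
        self.beta = beta
        self.beta_names = beta_names
        self.time_effects = time_effects
        self.unit_effects = unit_effects
        self.residuals = residuals
        self.vcov_tau = vcov_tau
        super().__init__(**kw)


class DifferenceInDifferences:
    """Two-way fixed-effects DiD model for a balanced panel.

    Examples
    --------
    >>> res = DifferenceInDifferences(panel).fit()      # doctest: +SKIP
    >>> res.att, res.se                                 # doctest: +SKIP
    """

    def __init__(self, panel: PanelDataset):
        self.panel = panel

    def fit(self) -> DiDResults:
        p = self.panel
        n, T, q = p.n_units, p.T, p.T - p.T0
        N = n * T
        y = p.y.ravel()
        w = p.weights.ravel()
        unit_idx = np.repeat(np.arange(n), T)
        t_idx = np.tile(np.arange(T), n)

        # time dummies (reference: first period), covariates, saturated D
        time_d = (t_idx[:, None] == np.arange(1, T)[None, :]).astype(float)
        X = p.X.reshape(N, p.n_covariates)
        treat = np.repeat(p.treated.astype(float), T)
        d_cols = np.column_stack(
            [treat * (t_idx == p.T0 + s) for s in range(q)]
        )
        Z = np.column_stack([time_d, X, d_cols])

        # weighted within-unit demeaning of y and all regressors (FWL)
        wsum = np.bincount(unit_idx, weights=w)

        def demean(M):
            M = np.atleast_2d(M.T).T
            means = np.empty((n, M.shape[1]))
            for j in range(M.shape[1]):
                means[:, j] = np.bincount(unit_idx, weights=w * M[:, j]) / wsum
            return M - means[unit_idx]

        yd = demean(y[:, None])[:, 0]
        Zd = demean(Z)
        fit: WLSFit = wls_fit(Zd, yd, weights=w, clusters=unit_idx)

        k_td, k_x = T - 1, p.n_covariates
        taus = fit.params[k_td + k_x:]
        vcov_tau = None
        if fit.vcov is not None:
            vcov_tau = fit.vcov[k_td + k_x:, k_td + k_x:]
        omega = _period_weights(p)
        att, se = _combine(np.nan_to_num(taus), vcov_tau, omega)
        G = fit.n_clusters or n
        p_value = _t_pvalue(att, se, G - 1) if se else None

        beta = fit.params[k_td:k_td + k_x]
        time_effects = fit.params[:k_td]
        # unit effects recovered from the undemeaned model: weighted mean of
        # y - Z theta per unit
        theta = np.nan_to_num(fit.params)
        alpha = np.bincount(unit_idx, weights=w * (y - Z @ theta)) / wsum
        return DiDResults(
            att=att, att_by_period=taus, period_weights=omega,
            se=se, p_value=p_value, method="did",
            n_treated=p.n_treated, n_control=p.n_control,
            beta=beta, beta_names=list(p.covariate_names),
            time_effects=time_effects, unit_effects=alpha,
            residuals=(y - Z @ theta - alpha[unit_idx]).reshape(n, T),
            vcov_tau=vcov_tau,
        )


class LDVResults(EstimateResult):
    """LDV fit: ATT plus covariate and lag coefficients and residuals."""

    def __init__(self, *, beta, beta_names, theta, residuals, vcov_tau, **kw):
        self.beta = beta
        self.beta_names = beta_names
        self.theta = theta
        self.residuals = residuals
        self.vcov_tau = vcov_tau
        super().__init__(**kw)


class LaggedDependentVariable:
    """Lagged-dependent-variable (ANCOVA) model on post-treatment rows.

    Parameters
    ----------
    panel : PanelDataset
    use_lags : bool
        Include all T0 pre-treatment outcomes as regressors (default).
        ``False`` reduces the model to a cross-sectional post-period
        comparison adjusted for covariates only.
    """

    def __init__(self, panel: PanelDataset, use_lags: bool = True):
        self.panel = panel
        self.use_lags = use_lags

    def fit(self) -> LDVResults:
        p = self.panel
        n, T0, q = p.n_units, p.T0, p.T - p.T0
        n_lags = T0 if self.use_lags else 0
        k = 1 + p.n_covariates + n_lags + (q - 1) + q
        N = n * q
        deficit = k - N
        if deficit >= 0:
            raise ValueError(
                f"insufficient degrees of freedom for LDV fit: {N} post-period "
                f"rows for {k} parameters (need {deficit + 1} more rows)"
            )

        lags = p.y[:, :T0]  # (n, T0)
        rows_y, rows_Z, rows_w, rows_u = [], [], [], []
        for s in range(q):
            t = T0 + s
            block = [np.ones(n)]
            block.append(p.X[:, t, :].reshape(n, p.n_covariates))
            if self.use_lags:
                block.append(lags)
            if q > 1:
                pd_dum = np.zeros((n, q - 1))
                if s > 0:
                    pd_dum[:, s - 1] = 1.0
                block.append(pd_dum)
            dsat = np.zeros((n, q))
            dsat[:, s] = p.treated.astype(float)
            block.append(dsat)
            rows_Z.append(np.column_stack(block))
            rows_y.append(p.y[:, t])
            rows_w.append(p.weights[:, t])
            rows_u.append(np.arange(n))
        Z = np.vstack(rows_Z)
        y = np.concatenate(rows_y)
        w = np.concatenate(rows_w)
        units = np.concatenate(rows_u)

        fit = wls_fit(Z, y, weights=w, clusters=units)
        k_head = 1 + p.n_covariates + n_lags + (q - 1)
        taus = fit.params[k_head:]
        vcov_tau = fit.vcov[k_head:, k_head:] if fit.vcov is not None else None
        omega = _period_weights(p)
        att, se = _combine(np.nan_to_num(taus), vcov_tau, omega)
        G = fit.n_clusters or n
        p_value = _t_pvalue(att, se, G - 1) if se else None
        beta = fit.params[1:1 + p.n_covariates]
        theta = fit.params[1 + p.n_covariates: 1 + p.n_covariates + n_lags]
        return LDVResults(
            att=att, att_by_period=taus, period_weights=omega,
            se=se, p_value=p_value, method="ldv",
            n_treated=p.n_treated, n_control=p.n_control,
            beta=beta, beta_names=list(p.covariate_names),
            theta=theta, residuals=fit.residuals, vcov_tau=vcov_tau,
        )


def fit_did(panel: PanelDataset) -> DiDResults:
    """Two-way fixed-effects DiD estimate of the ATT (see
    :class:`DifferenceInDifferences`)."""
    return DifferenceInDifferences(panel).fit()


def fit_ldv(panel: PanelDataset, use_lags: bool = True) -> LDVResults:
    """Lagged-dependent-variable estimate of the ATT (see
    :class:`LaggedDependentVariable`)."""
    return LaggedDependentVariable(panel, use_lags=use_lags).fit()
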