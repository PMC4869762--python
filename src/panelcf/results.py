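"""Shared results container for the ATT estimators.

Every estimator in the package reports an average treatment effect on the
treated (ATT): the post-period contrast between treated outcomes and the
estimator's counterfactual, averaged (weight-consistently) over the
post-treatment periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EstimateResult"]


@dataclass
class EstimateResult:
    """ATT estimate with per-post-period effects and (where available)
    a cluster-robust standard error.

    Attributes
    ----------
    att : float
        ATT averaged over the post-treatment periods; always the
        ``period_weights``-weighted mean of ``att_by_period``.
    att_by_period : ndarray, one entry per post period.
    period_weights : ndarray
        Treated weight mass per post period (normalized), the weights under
        which ``att`` averages ``att_by_period``.
    se : float or None
        Cluster-robust standard error; None for estimators whose inference
        is by placebo test.
    p_value : float or None
    method : str
    n_treated, n_control : int
    """

    att: float
    att_by_period: np.ndarray
    method: str
    n_treated: int
    n_control: int
    period_weights: np.ndarray = None  # type: ignore[assignment]
    se: float | None = None
    p_value: float | None = None
    extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.att_by_period = np.atleast_1d(np.asarray(self.att_by_period, float))
        if self.period_weights is None:
            self.period_weights = np.full(
                len(self.att_by_period), 1.0 / len(self.att_by_period)
            )
        self.period_weights = np.asarray(self.period_weights, float)
        self.period_weights = self.period_weights / self.period_weights.sum()
        avg = float(self.period_weights @ self.att_by_period)
        if not np.isclose(self.att, avg, rtol=1e-7, atol=1e-9):
            raise ValueError(
                f"att={self.att} is not the weight-consistent mean "
                f"{avg} of att_by_period"
            )
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.se is not None and self.se < 0:
            raise ValueError("se must be nonnegative")

    def summary(self) -> str:
        lines = [
            f"ATT estimate ({self.method})",
            "=" * 40,
            f"  ATT (avg over post periods): {self.att: .6g}",
        ]
        if self.se is not None:
            lines.append(f"  cluster-robust SE:           {self.se: .6g}")
        if self.p_value is not None:
            lines.append(f"  p-value:                     {self.p_value: .4g}")
        lines.append(
            f"  treated / control units:     {self.n_treated} / {self.n_control}"
        )
        if len(self.att_by_period) > 1:
            per = ", ".join(f"{v:.4g}" for v in self.att_by_period)
            lines.append(f"  per-post-period effects:     {per}")
        return "\n".join(lines)
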