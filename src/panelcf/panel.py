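"""Balanced-panel data model, CSV I/O and group-balance diagnostics.

A :class:`PanelDataset` holds a balanced unit x time panel: one outcome
``Y_it`` per unit-period, an optional covariate vector ``X_it``, a binary
treated-group label per unit, and a positive frequency weight per
unit-period (admissions per hospital-quarter in the motivating setting).
Treatment switches on after period ``T0``, so ``D_it = treated_i * 1(t > T0)``.

Time periods are consecutive integers ``1..T``; calendar labels are the
caller's concern.  Missing rows are rejected rather than imputed: the
estimators in this package all assume a balanced panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PanelDataset",
    "BalanceTable",
    "PanelValidationError",
    "PanelSchemaError",
    "read_panel_csv",
    "write_panel_csv",
    "standardized_differences",
]


class PanelSchemaError(ValueError):
    """A required column is missing or mis-declared."""


class PanelValidationError(ValueError):
    """The data violate the balanced-panel invariants."""


@dataclass(frozen=True)
class PanelDataset:
    """A validated, balanced unit x time panel in wide (array) layout.

    Parameters
    ----------
    units : array of shape (n,)
        Opaque unit labels, order fixed.
    y : array of shape (n, T)
        Outcome, ``y[i, t-1]`` is Y_it.
    treated : bool array of shape (n,)
        Treated-group indicator per unit.
    T0 : int
        Number of pre-treatment periods, ``1 <= T0 < T``.
    X : array of shape (n, T, p)
        Time-varying covariates (p may be 0).
    weights : array of shape (n, T)
        Strictly positive frequency weights (default all one).
    covariate_names : tuple of str
        Column names for the p covariates.
    """

    units: np.ndarray
    y: np.ndarray
    treated: np.ndarray
    T0: int
    X: np.ndarray = None  # type: ignore[assignment]
    weights: np.ndarray = None  # type: ignore[assignment]
    covariate_names: tuple = ()

    def __post_init__(self):
        units = np.asarray(self.units)
        y = np.asarray(self.y, dtype=float)
        treated = np.asarray(self.treated, dtype=bool)
        if y.ndim != 2:
            raise PanelValidationError("y must be a 2-d (n, T) array")
        n, T = y.shape
        X = self.X
        if X is None:
            X = np.empty((n, T, 0))
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:  # single covariate given as (n, T)
            X = X[:, :, None]
        w = self.weights
        if w is None:
            w = np.ones((n, T))
        w = np.asarray(w, dtype=float)
        object.__setattr__(self, "units", units)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "treated", treated)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "weights", w)
        names = tuple(self.covariate_names)
        if not names:
            names = tuple(f"x{j + 1}" for j in range(X.shape[2]))
        object.__setattr__(self, "covariate_names", names)
        self._validate()

    # -- shape helpers -------------------------------------------------
    @property
    def n_units(self) -> int:
        return self.y.shape[0]

    @property
    def T(self) -> int:
        return self.y.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[2]

    @property
    def n_treated(self) -> int:
        return int(self.treated.sum())

    @property
    def n_control(self) -> int:
        return int((~self.treated).sum())

    @property
    def post_periods(self) -> np.ndarray:
        """1-based post-treatment period indices ``T0+1..T``."""
        return np.arange(self.T0 + 1, self.T + 1)

    @property
    def d(self) -> np.ndarray:
        """Treatment exposure indicator D_it, shape (n, T)."""
        out = np.zeros((self.n_units, self.T))
        out[self.treated, self.T0:] = 1.0
        return out

    def _validate(self) -> None:
        n, T = self.y.shape
        if len(self.units) != n:
            raise PanelValidationError("units length does not match y rows")
        if len(np.unique(self.units)) != n:
            raise PanelValidationError("unit labels must be unique")
        if self.treated.shape != (n,):
            raise PanelValidationError("treated must have one entry per unit")
        if not (isinstance(self.T0, (int, np.integer)) and 1 <= self.T0 < T):
            raise PanelValidationError(
                f"T0 must satisfy 1 <= T0 < T; got T0={self.T0}, T={T}"
            )
        if self.X.shape[:2] != (n, T):
            raise PanelValidationError("X must have shape (n, T, p)")
        if len(self.covariate_names) != self.X.shape[2]:
            raise PanelValidationError("covariate_names length must equal p")
        if self.weights.shape != (n, T):
            raise PanelValidationError("weights must have shape (n, T)")
        if self.n_treated == 0 or self.n_control == 0:
            raise PanelValidationError(
                "need at least one treated and one control unit"
            )
        if not np.all(np.isfinite(self.y)):
            raise PanelValidationError("outcomes must be finite")
        if not np.all(np.isfinite(self.X)):
            raise PanelValidationError("covariates must be finite")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise PanelValidationError("weights must be strictly positive")

    # -- constructors --------------------------------------------------
    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        T0: int,
        unit_col: str = "unit",
        time_col: str = "time",
        outcome_col: str = "outcome",
        treated_col: str = "treated",
        weight_col: str | None = "weight",
        covariate_cols: list[str] | None = None,
    ) -> "PanelDataset":
        """Build a panel from a long-format DataFrame (one row per unit-period)."""
        for col in (unit_col, time_col, outcome_col, treated_col):
            if col not in df.columns:
                raise PanelSchemaError(f"missing required column {col!r}")
        if covariate_cols is None:
            reserved = {unit_col, time_col, outcome_col, treated_col, weight_col}
            covariate_cols = [c for c in df.columns if c not in reserved]
        else:
            for col in covariate_cols:
                if col not in df.columns:
                    raise PanelSchemaError(f"missing covariate column {col!r}")
        df = df.sort_values([unit_col, time_col], kind="mergesort")
        times = np.unique(df[time_col].to_numpy())
        T = len(times)
        if not np.array_equal(times, np.arange(1, T + 1)):
            raise PanelValidationError(
                "time index must be the consecutive integers 1..T; "
                f"found {times.tolist()[:10]}"
            )
        counts = df.groupby(unit_col, sort=True)[time_col].agg(["size", "nunique"])
        bad = counts.index[(counts["size"] != T) | (counts["nunique"] != T)]
        if len(bad):
            raise PanelValidationError(
                "panel is unbalanced; offending units: "
                + ", ".join(str(u) for u in bad[:20])
            )
        units = counts.index.to_numpy()
        n = len(units)

        def wide(col):
            return df[col].to_numpy(dtype=float).reshape(n, T)

        y = wide(outcome_col)
        treat_wide = wide(treated_col)
        if np.any(treat_wide != treat_wide[:, :1]):
            raise PanelValidationError("treated indicator must be constant per unit")
        treated = treat_wide[:, 0] != 0
        if weight_col is not None and weight_col in df.columns:
            w = wide(weight_col)
        else:
            w = np.ones((n, T))
        X = (
            np.stack([wide(c) for c in covariate_cols], axis=2)
            if covariate_cols
            else np.empty((n, T, 0))
        )
        return cls(
            units=units, y=y, treated=treated, T0=T0, X=X, weights=w,
            covariate_names=tuple(covariate_cols),
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format DataFrame, one row per unit-period, sorted by (unit, time)."""
        n, T = self.y.shape
        out = {
            "unit": np.repeat(self.units, T),
            "time": np.tile(np.arange(1, T + 1), n),
            "treated": np.repeat(self.treated.astype(int), T),
            "outcome": self.y.ravel(),
        }
        for j, name in enumerate(self.covariate_names):
            out[name] = self.X[:, :, j].ravel()
        if not np.allclose(self.weights, 1.0):
            out["weight"] = self.weights.ravel()
        return pd.DataFrame(out)

    def subset(self, mask: np.ndarray) -> "PanelDataset":
        """Panel restricted to the units selected by a boolean mask."""
        return PanelDataset(
            units=self.units[mask], y=self.y[mask], treated=self.treated[mask],
            T0=self.T0, X=self.X[mask], weights=self.weights[mask],
            covariate_names=self.covariate_names,
        )

    def with_treated(self, treated: np.ndarray) -> "PanelDataset":
        """Same data with a replacement treated-group assignment."""
        return PanelDataset(
            units=self.units, y=self.y, treated=np.asarray(treated, bool),
            T0=self.T0, X=self.X, weights=self.weights,
            covariate_names=self.covariate_names,
        )


def read_panel_csv(
    path,
    T0: int,
    unit_col: str = "unit",
    time_col: str = "time",
    outcome_col: str = "outcome",
    treated_col: str = "treated",
    weight_col: str | None = "weight",
    covariate_cols: list[str] | None = None,
) -> PanelDataset:
    """Read a long-format RFC-4180 CSV into a validated :class:`PanelDataset`.

    Columns other than the declared unit/time/outcome/treated/weight columns
    are treated as covariates unless ``covariate_cols`` narrows them.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    return PanelDataset.from_long(
        df, T0=T0, unit_col=unit_col, time_col=time_col,
        outcome_col=outcome_col, treated_col=treated_col,
        weight_col=weight_col, covariate_cols=covariate_cols,
    )


def write_panel_csv(panel: PanelDataset, path) -> None:
    """Write the panel as long-format CSV at full float precision.

    The weight column is emitted only when some weight differs from 1; a
    panel without covariates has no covariate columns.  Round-trips with
    :func:`read_panel_csv`.
    """
    panel.to_long().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Balance diagnostics
# ---------------------------------------------------------------------------

@dataclass
class BalanceTable:
    """Treated-vs-comparison balance on pre-period outcomes and covariates.

    ``table`` has one row per balance variable with columns
    ``treated_mean, comparison_mean, std_diff_pct, t_p, ks_p``.
    Standardized difference is the Rubin/Stuart convention
    ``100 * (m_t - m_c) / sqrt((s_t^2 + s_c^2) / 2)``; values above 10 % are
    conventionally read as imbalance.
    """

    table: pd.DataFrame = field(repr=False)

    @property
    def std_diff_pct(self) -> pd.Series:
        return self.table["std_diff_pct"]

    def max_abs_std_diff(self) -> float:
        return float(self.table["std_diff_pct"].abs().max())

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:10.4f}")


def _balance_variables(panel: PanelDataset) -> tuple[np.ndarray, list[str]]:
    """Per-unit balance variables: each pre-period outcome, then each
    covariate averaged (weight-consistent) over the pre-period."""
    cols = [panel.y[:, t] for t in range(panel.T0)]
    names = [f"y_pre{t + 1}" for t in range(panel.T0)]
    w_pre = panel.weights[:, : panel.T0]
    for j, name in enumerate(panel.covariate_names):
        xj = panel.X[:, : panel.T0, j]
        cols.append((xj * w_pre).sum(axis=1) / w_pre.sum(axis=1))
        names.append(f"{name}_pre_mean")
    return np.column_stack(cols), names


def standardized_differences(
    panel: PanelDataset, assignment: np.ndarray | None = None
) -> BalanceTable:
    """Balance table between two groups of units.

    Parameters
    ----------
    panel : PanelDataset
    assignment : bool array per unit, optional
        Grouping to compare; defaults to the panel's treated indicator.
        (Matched analyses pass the matched-sample assignment instead.)

    For each pre-period outcome and each pre-averaged covariate the table
    reports group means, the standardized difference in percent, a Welch
    two-sample t-test p-value and a two-sample Kolmogorov-Smirnov p-value.
    A variable with zero variance in both groups but unequal means gets an
    infinite standardized difference, with a warning.
    """
    g = panel.treated if assignment is None else np.asarray(assignment, bool)
    if g.sum() == 0 or (~g).sum() == 0:
        raise PanelValidationError("both groups must be nonempty")
    if g.sum() < 2 or (~g).sum() < 2:
        raise PanelValidationError("need >= 2 units per group for variance terms")
    vals, names = _balance_variables(panel)
    rows = []
    for k, name in enumerate(names):
        a, b = vals[g, k], vals[~g, k]
        ma, mb = a.mean(), b.mean()
        va, vb = a.var(ddof=1), b.var(ddof=1)
        pooled = np.sqrt((va + vb) / 2.0)
        if pooled == 0.0:
            if ma == mb:
                sd = 0.0
            else:
                warnings.warn(
                    f"zero pooled variance with unequal means for {name!r}; "
                    "standardized difference is infinite"
                )
                sd = np.inf if ma > mb else -np.inf
        else:
            sd = 100.0 * (ma - mb) / pooled
        if va == 0.0 and vb == 0.0:
            t_p = 1.0 if ma == mb else 0.0
        else:
            t_p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        ks_p = float(stats.ks_2samp(a, b).pvalue)
        rows.append((name, ma, mb, sd, t_p, ks_p))
    table = pd.DataFrame(
        rows,
        columns=[
            "variable", "treated_mean", "comparison_mean",
            "std_diff_pct", "t_p", "ks_p",
        ],
    ).set_index("variable")
    return BalanceTable(table)
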