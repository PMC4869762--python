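"""Multivariate (genetic-style) matching on pre-treatment outcomes and
covariates, followed by DiD on the matched sample.

Each treated unit is matched 1:1 with replacement to the control unit
nearest under a weighted Mahalanobis metric

.. math:: d(u, v) = \\sqrt{(u - v)' (S^{-1/2})' M S^{-1/2} (u - v)},

where ``S`` is the sample covariance of the balance variables (each
pre-period outcome plus each pre-averaged covariate) and ``M`` is a
diagonal weight matrix.  An evolutionary search over ``M`` maximizes the
achieved balance, scored lexicographically on the sorted vector of paired
t-test and Kolmogorov-Smirnov p-values (maximize the minimum p, then the
next smallest, and so on -- the canonical generalized-matching criterion).
With the outcome-priority flag the p-values of the pre-treatment outcome
variables are compared first.

The matched sample then feeds the two-way FE DiD estimator, with each
matched control entering at its original frequency weight times its
multiplicity; inference is conditional on the matched data.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel import BalanceTable, PanelDataset, standardized_differences
from .regression import DiDResults, fit_did
from .results import EstimateResult

__all__ = [
    "MatchSpec",
    "MatchResult",
    "GeneticMatchingDiD",
    "MatchingDiDResults",
    "weighted_mahalanobis",
    "balance_loss",
    "genetic_search",
    "fit_match_did",
]


@dataclass(frozen=True)
class MatchSpec:
    """Search settings for the evolutionary balance optimization.

    ``population``/``generations`` size the search (the identity metric is
    always in the initial population, so the result can never score worse
    than plain Mahalanobis matching); ``mutation_scale`` is the SD of the
    log-normal perturbations of the metric weights.  Matching is always
    1:1 nearest-neighbour with replacement.
    """

    population: int = 50
    generations: int = 20
    outcome_priority: bool = True
    mutation_scale: float = 0.5
    seed: int | None = None
    with_replacement: bool = True  # fixed; documented for clarity

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not self.with_replacement:
            raise ValueError("only matching with replacement is supported")


@dataclass
class MatchResult:
    """Outcome of the balance search.

    ``match_idx[i]`` is the index (into the control subset) of the control
    matched to treated unit i; ``multiplicity`` counts how often each
    selected control is used.  ``loss_key`` is the lexicographic balance
    key actually optimized (higher is better); ``trace`` records the best
    key per generation.
    """

    treated_units: np.ndarray
    control_units: np.ndarray
    match_idx: np.ndarray
    metric_weights: np.ndarray
    loss_key: tuple
    balance: BalanceTable | None = None
    trace: list = field(default_factory=list, repr=False)

    @property
    def mapping(self) -> dict:
        return {
            t: self.control_units[j]
            for t, j in zip(self.treated_units.tolist(), self.match_idx.tolist())
        }

    @property
    def multiplicity(self) -> Counter:
        return Counter(self.control_units[j] for j in self.match_idx)


def _inv_sqrt(S: np.ndarray) -> np.ndarray:
    """Symmetric pseudo-inverse square root; singular directions are
    collapsed (with a warning) rather than exploded."""
    S = np.asarray(S, float)
    vals, vecs = np.linalg.eigh((S + S.T) / 2.0)
    tol = max(vals.max(), 0.0) * 1e-12
    keep = vals > tol
    if not np.all(keep):
        warnings.warn(
            "singular covariance in Mahalanobis metric; "
            f"collapsed {int((~keep).sum())} component(s) via pseudo-inverse"
        )
    inv_sqrt_vals = np.where(keep, 1.0 / np.sqrt(np.where(keep, vals, 1.0)), 0.0)
    return (vecs * inv_sqrt_vals) @ vecs.T


def weighted_mahalanobis(
    u: np.ndarray, v: np.ndarray, S: np.ndarray, M: np.ndarray
) -> float:
    """Weighted Mahalanobis distance between two predictor vectors."""
    M = np.asarray(M, float)
    if np.any(M < 0):
        raise ValueError("metric weights must be nonnegative")
    Z = _inv_sqrt(S)
    d = Z @ (np.asarray(u, float) - np.asarray(v, float))
    return float(np.sqrt(d @ (M * d)))


def _balance_matrix(panel: PanelDataset) -> tuple[np.ndarray, int]:
    """(n, K) balance variables (pre-period outcomes then pre-averaged
    covariates) and the count of outcome variables."""
    cols = [panel.y[:, : panel.T0]]
    w_pre = panel.weights[:, : panel.T0]
    for j in range(panel.n_covariates):
        xj = panel.X[:, : panel.T0, j]
        cols.append(((xj * w_pre).sum(axis=1) / w_pre.sum(axis=1))[:, None])
    return np.hstack(cols), panel.T0


def _paired_t_p(diffs: np.ndarray) -> np.ndarray:
    """Two-sided paired t-test p-values per column of a difference matrix."""
    n, K = diffs.shape
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    p = np.ones(K)
    ok = sd > 0
    tstat = np.abs(mean[ok]) / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(tstat, n - 1)
    p[(~ok) & (mean != 0)] = 0.0
    return p


def _ks_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized asymptotic two-sample KS p-values per column."""
    n1, K = a.shape
    n2 = b.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    order = np.argsort(pooled, axis=0, kind="stable")
    from_a = (order < n1).astype(float)
    cdf1 = np.cumsum(from_a, axis=0) / n1
    cdf2 = np.cumsum(1.0 - from_a, axis=0) / n2
    # the ECDF gap is only defined at the upper edge of a run of tied values
    vals = np.take_along_axis(pooled, order, axis=0)
    run_end = np.vstack([vals[1:] != vals[:-1], np.ones((1, K), bool)])
    d = np.where(run_end, np.abs(cdf1 - cdf2), 0.0).max(axis=0)
    en = np.sqrt(n1 * n2 / (n1 + n2))
    return stats.kstwobign.sf(np.maximum((en + 0.12 + 0.11 / en) * d, 1e-12))


def _loss_key_from_pvalues(
    t_p: np.ndarray, ks_p: np.ndarray, n_outcomes: int, outcome_priority: bool
) -> tuple:
    """Lexicographic balance key, higher is better.  Sorted ascending so the
    first comparison maximizes the minimum p-value."""
    if outcome_priority and 0 < n_outcomes < len(t_p):
        head = np.sort(np.concatenate([t_p[:n_outcomes], ks_p[:n_outcomes]]))
        tail = np.sort(np.concatenate([t_p[n_outcomes:], ks_p[n_outcomes:]]))
        return tuple(np.concatenate([head, tail]))
    return tuple(np.sort(np.concatenate([t_p, ks_p])))


def balance_loss(
    panel: PanelDataset,
    match_idx: np.ndarray,
    outcome_priority: bool = True,
) -> tuple:
    """Lexicographic balance key of a matching (higher key = better balance).

    For each balance variable the key collects a paired t-test p-value
    (treated unit vs its matched control) and a two-sample KS p-value
    (treated sample vs the multiplicity-expanded matched sample); the key
    is the ascending sort of these p-values, with the pre-treatment
    outcome variables' block compared first when ``outcome_priority`` is
    on.  A variable degenerate in both groups contributes p = 1.
    """
    B, n_out = _balance_matrix(panel)
    Bt, Bc = B[panel.treated], B[~panel.treated]
    match_idx = np.asarray(match_idx, int)
    matched = Bc[match_idx]
    zero_var = (Bt.std(axis=0) == 0) & (matched.std(axis=0) == 0) \
        & (np.abs(Bt.mean(axis=0) - matched.mean(axis=0)) < 1e-300)
    t_p = _paired_t_p(Bt - matched)
    ks_p = _ks_p(Bt, matched)
    t_p[zero_var] = 1.0
    ks_p[zero_var] = 1.0
    return _loss_key_from_pvalues(t_p, ks_p, n_out, outcome_priority)


def genetic_search(panel: PanelDataset, spec: MatchSpec) -> MatchResult:
    """Evolutionary search over diagonal metric weights.

    Each candidate ``M`` induces a nearest-neighbour matching with
    replacement (ties broken toward the lowest control index); the best
    balance key found is returned.  The search is elitist (the incumbent
    survives every generation) and fully reproducible under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    B, n_out = _balance_matrix(panel)
    K = B.shape[1]
    S = np.cov(B, rowvar=False, ddof=1)
    if K == 1:
        S = np.atleast_2d(S)
    Z = _inv_sqrt(S)
    Bt, Bc = B[panel.treated] @ Z.T, B[~panel.treated] @ Z.T
    # precomputed squared coordinate differences: (n_t, n_c, K)
    D2 = (Bt[:, None, :] - Bc[None, :, :]) ** 2

    def match_for(M):
        return np.argmin(D2 @ M, axis=1)

    cache: dict = {}

    def evaluate(M):
        idx = match_for(M)
        key_id = idx.tobytes()
        if key_id not in cache:
            cache[key_id] = balance_loss(panel, idx, spec.outcome_priority)
        return idx, cache[key_id]

    pop = [np.ones(K)]
    pop += [np.exp(rng.normal(0.0, 1.0, size=K)) for _ in range(spec.population - 1)]
    best_M, best_idx, best_key = None, None, None
    trace = []
    for _ in range(spec.generations):
        for M in pop:
            idx, key = evaluate(M)
            if best_key is None or key > best_key:
                best_M, best_idx, best_key = M, idx, key
        trace.append(best_key)
        n_fresh = max(1, spec.population // 4)
        pop = [best_M]
        pop += [
            best_M * np.exp(rng.normal(0.0, spec.mutation_scale, size=K))
            for _ in range(spec.population - 1 - n_fresh)
        ]
        pop += [np.exp(rng.normal(0.0, 1.0, size=K)) for _ in range(n_fresh)]
    result = MatchResult(
        treated_units=panel.units[panel.treated],
        control_units=panel.units[~panel.treated],
        match_idx=best_idx,
        metric_weights=best_M / best_M.sum(),
        loss_key=best_key,
        trace=trace,
    )
    return result


def _matched_panel(panel: PanelDataset, match_idx: np.ndarray) -> PanelDataset:
    """Treated units plus the matched controls, the latter with weights
    scaled by their multiplicity."""
    ctrl_pos = np.where(~panel.treated)[0]
    counts = Counter(np.asarray(match_idx, int).tolist())
    mult = np.ones(panel.n_units)
    for k, c in counts.items():
        mult[ctrl_pos[k]] = c
    mask = panel.treated.copy()
    mask[ctrl_pos[sorted(counts)]] = True
    return PanelDataset(
        units=panel.units[mask], y=panel.y[mask], treated=panel.treated[mask],
        T0=panel.T0, X=panel.X[mask],
        weights=(panel.weights * mult[:, None])[mask],
        covariate_names=panel.covariate_names,
    )


class MatchingDiDResults(EstimateResult):
    def __init__(self, *, match: MatchResult, did: DiDResults, **kw):
        self.match = match
        self.did = did
        super().__init__(**kw)


class GeneticMatchingDiD:
    """Genetic matching on pre-treatment outcomes/covariates followed by
    two-way FE DiD on the matched sample."""

    def __init__(self, panel: PanelDataset, spec: MatchSpec | None = None):
        self.panel = panel
        self.spec = spec if spec is not None else MatchSpec()

    def fit(self) -> MatchingDiDResults:
        panel = self.panel
        match = genetic_search(panel, self.spec)
        matched = _matched_panel(panel, match.match_idx)
        did = fit_did(matched)
        # achieved balance on the matched (multiplicity-weighted) sample
        try:
            match.balance = standardized_differences(matched)
        except Exception:  # < 2 distinct controls selected
            match.balance = None
        return MatchingDiDResults(
            att=did.att, att_by_period=did.att_by_period,
            period_weights=did.period_weights, se=did.se,
            p_value=did.p_value, method="match",
            n_treated=panel.n_treated, n_control=panel.n_control,
            match=match, did=did,
        )


def fit_match_did(
    panel: PanelDataset, spec: MatchSpec | None = None
) -> tuple[MatchingDiDResults, MatchResult]:
    """Matched-sample DiD estimate of the ATT (see
    :class:`GeneticMatchingDiD`)."""
    res = GeneticMatchingDiD(panel, spec).fit()
    return res, res.match
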