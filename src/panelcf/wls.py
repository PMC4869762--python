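"""Weighted least squares with cluster-robust (CR1) variance.

Shared least-squares core for the regression estimators.  Collinear columns
are dropped deterministically (leftmost kept) so that reference categories
and fit results are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["WLSFit", "wls_fit", "CollinearityWarning"]


class CollinearityWarning(UserWarning):
    pass


@dataclass
class WLSFit:
    """Solution of a weighted least-squares problem.

    ``params``/``vcov`` are full-size; dropped (collinear) columns carry
    NaN entries.  ``vcov`` is the CR1 cluster sandwich when cluster labels
    were supplied and at least two clusters exist, else None.
    """

    params: np.ndarray
    vcov: np.ndarray | None
    residuals: np.ndarray
    kept: np.ndarray  # boolean mask of retained columns
    n_clusters: int | None = None

    def bse(self) -> np.ndarray | None:
        if self.vcov is None:
            return None
        return np.sqrt(np.diag(self.vcov))


def _independent_columns(Xw: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Greedy left-to-right selection of a linearly independent column set
    via modified Gram-Schmidt.  Leftmost of any collinear set is kept."""
    n, k = Xw.shape
    basis: list[np.ndarray] = []
    kept = np.zeros(k, dtype=bool)
    norms = np.linalg.norm(Xw, axis=0)
    scale = norms.max() if k else 0.0
    for j in range(k):
        v = Xw[:, j].copy()
        for b in basis:
            v -= (b @ v) * b
        # second pass for numerical stability
        for b in basis:
            v -= (b @ v) * b
        nv = np.linalg.norm(v)
        if nv > rtol * max(norms[j], scale * 1e-3, 1e-300):
            basis.append(v / nv)
            kept[j] = True
    return kept


def wls_fit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    clusters: np.ndarray | None = None,
) -> WLSFit:
    """Weighted least squares with CR1 cluster-robust variance.

    Parameters
    ----------
    X : (N, k) design matrix.
    y : (N,) response.
    weights : (N,) strictly positive frequency weights (default 1).
    clusters : (N,) cluster labels for the sandwich variance, or None.

    Notes
    -----
    The CR1 small-sample correction is
    ``(G / (G - 1)) * ((N - 1) / (N - k))`` applied to the cluster sandwich.
    With fewer than two clusters the variance is unavailable (``vcov=None``).
    Collinear columns are dropped (leftmost kept) with a
    :class:`CollinearityWarning`.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    N, k = X.shape
    if weights is None:
        weights = np.ones(N)
    weights = np.asarray(weights, float)
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    sw = np.sqrt(weights)
    Xw = X * sw[:, None]
    yw = y * sw

    kept = _independent_columns(Xw)
    r = int(kept.sum())
    if r == 0:
        raise ValueError("design matrix has rank zero")
    if r < k:
        warnings.warn(
            f"dropped {k - r} collinear column(s); leftmost kept",
            CollinearityWarning,
            stacklevel=2,
        )
    Xk = Xw[:, kept]
    beta_k, *_ = np.linalg.lstsq(Xk, yw, rcond=None)
    params = np.full(k, np.nan)
    params[kept] = beta_k
    resid = y - X[:, kept] @ beta_k  # unweighted-scale residuals

    vcov = None
    n_clusters = None
    if clusters is not None:
        clusters = np.asarray(clusters)
        labels, inv = np.unique(clusters, return_inverse=True)
        G = len(labels)
        n_clusters = G
        if G >= 2:
            XtWX = Xk.T @ Xk
            bread = np.linalg.pinv(XtWX)
            # cluster score sums: s_g = sum_i w_i x_i u_i
            wu = weights * resid
            scores = np.zeros((G, r))
            np.add.at(scores, inv, X[:, kept] * wu[:, None])
            meat = scores.T @ scores
            dof = max(N - r, 1)
            c = (G / (G - 1)) * ((N - 1) / dof)
            v_k = c * bread @ meat @ bread
            vcov = np.full((k, k), np.nan)
            idx = np.where(kept)[0]
            vcov[np.ix_(idx, idx)] = v_k
    return WLSFit(
        params=params, vcov=vcov, residuals=resid, kept=kept,
        n_clusters=n_clusters,
    )
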