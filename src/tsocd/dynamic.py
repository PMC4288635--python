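"""Dynamic PPI network construction from time-course expression data.

An aggregate (static) interaction network mixes interactions that exist at
all times with interactions that assemble only transiently. This module
splits the two classes and builds one network per time point:

* an interaction is **stable** when its endpoints are globally co-expressed —
  the Pearson correlation of their expression profiles exceeds a cutoff
  ``delta``. The cutoff can be fixed (0.3 by default) or estimated from the
  crossing point of a two-component Gaussian mixture fitted to the PCC
  values of all interactions by EM;
* every other interaction is **transient** and is present at time ``t`` only
  when both endpoints are *active*, i.e. expressed at or above their
  per-protein three-sigma activity threshold

      AT(i) = mu(i) + 3 * sigma(i) * (1 - F(i)),   F(i) = 1 / (1 + sigma(i)^2),

  where ``mu`` and ``sigma`` are the mean and (population) standard deviation
  of the protein's profile. ``F`` down-weights the three-sigma margin for
  quiet genes so that a flat profile has AT = mu.

The result is a series of binary adjacency matrices ``A[t]`` sharing a node
set, each containing every stable edge plus the transient edges active at t.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix, StaticNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "compute_edge_pcc",
    "PccGaussianMixture",
    "fit_pcc_gmm",
    "choose_stable_cutoff",
    "classify_stable",
    "ActivityThresholds",
    "compute_active_thresholds",
    "DynamicNetworkSeries",
    "build_dynamic_networks",
]


def compute_edge_pcc(net: StaticNetwork, ge: ExpressionMatrix) -> dict[tuple[str, str], float]:
    """Pearson correlation of the endpoint expression profiles of each edge.

    A zero-variance (constant) profile on either endpoint yields PCC 0:
    the correlation is undefined and a constant gene carries no
    co-expression evidence, so such an edge can never be called stable.
    """
    if ge.n_times < 2:
        raise ValueError("need at least two time points to correlate")
    idx = ge.index
    missing = [g for g in net.nodes if g not in idx]
    if missing:
        raise ValueError(f"nodes without expression rows: {missing[:5]}")
    X = ge.values
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # population convention
    ok = sd[:, 0] > 0
    Z = np.zeros_like(X)
    np.divide(X - mu, sd, out=Z, where=sd > 0)
    table: dict[tuple[str, str], float] = {}
    for u, v in net.edges:
        i, j = idx[u], idx[v]
        if ok[i] and ok[j]:
            r = float(np.clip((Z[i] * Z[j]).mean(), -1.0, 1.0))
        else:
            r = 0.0
        table[(u, v)] = r
    return table


# ---------------------------------------------------------------------------
# two-component Gaussian mixture over edge PCC values


class PccGaussianMixture(BaseEstimator):
    """Univariate two-component Gaussian mixture fitted by EM.

    Models the distribution of edge-wise PCC values as
    ``eta * N(mu1, s1^2) + (1 - eta) * N(mu2, s2^2)`` with components
    relabelled so ``mu1 <= mu2``: the left component corresponds to
    transient interactions, the right one to stable interactions.

    Parameters
    ----------
    max_iter : maximum EM iterations per restart.
    tol : absolute log-likelihood improvement below which EM stops.
    n_restarts : restarts (first from a median split, then random
        responsibilities); the best final log-likelihood wins.
    var_floor : lower bound on component variances.
    random_state : seed for the random restarts.

    Attributes
    ----------
    weights_ : (2,) mixing proportions, left component first.
    means_ : (2,) component means, ascending.
    variances_ : (2,) component variances.
    loglik_trace_ : per-iteration log-likelihood of the winning restart
        (non-decreasing).
    n_iter_ : iterations used by the winning restart.
    """

    def __init__(self, max_iter=500, tol=1e-8, n_restarts=5, var_floor=1e-6, random_state=None):
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.var_floor = var_floor
        self.random_state = random_state

    # -- EM internals -------------------------------------------------------

    def _em(self, x: np.ndarray, resp: np.ndarray):
        """Run EM from initial responsibilities; return fit or None if degenerate."""
        n = x.size
        trace = []
        w = m = v = None
        for it in range(self.max_iter):
            # M step
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-8):
                return None
            w = nk / n
            m = (resp * x[:, None]).sum(axis=0) / nk
            v = (resp * (x[:, None] - m) ** 2).sum(axis=0) / nk
            v = np.maximum(v, self.var_floor)
            # E step + log-likelihood
            log_comp = (
                np.log(w)
                - 0.5 * np.log(2 * np.pi * v)
                - (x[:, None] - m) ** 2 / (2 * v)
            )
            log_norm = np.logaddexp(log_comp[:, 0], log_comp[:, 1])
            ll = float(log_norm.sum())
            trace.append(ll)
            resp = np.exp(log_comp - log_norm[:, None])
            if it > 0 and trace[-1] - trace[-2] < self.tol:
                break
        if np.any(v <= self.var_floor * (1 + 1e-12)) and np.ptp(m) < 1e-6:
            return None  # collapsed onto one point
        return w, m, v, np.asarray(trace)

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 20:
            raise ValueError(f"need at least 20 values to fit a mixture, got {x.size}")
        if np.ptp(x) == 0:
            raise ValueError("all input values identical; mixture is degenerate")
        rng = np.random.default_rng(self.random_state)
        best = None
        for restart in range(self.n_restarts):
            if restart == 0:
                # k-means-style split at the median
                resp = np.zeros((x.size, 2))
                left = x <= np.median(x)
                resp[left, 0] = 1.0
                resp[~left, 1] = 1.0
                if resp[:, 1].sum() == 0:  # >half the data at the median
                    resp[np.argmax(x), :] = [0.0, 1.0]
            else:
                p = rng.uniform(0.2, 0.8, size=x.size)
                resp = np.column_stack([p, 1 - p])
            out = self._em(x, resp)
            if out is None:
                continue
            if best is None or out[3][-1] > best[3][-1]:
                best = out
        if best is None:
            raise RuntimeError("EM failed on every restart (variance collapse)")
        w, m, v, trace = best
        order = np.argsort(m)
        self.weights_ = w[order]
        self.means_ = m[order]
        self.variances_ = v[order]
        self.loglik_trace_ = trace
        self.loglik_ = float(trace[-1])
        self.n_iter_ = len(trace)
        return self

    # -- inference ----------------------------------------------------------

    def predict_proba(self, X):
        x = np.asarray(X, dtype=float).ravel()
        log_comp = (
            np.log(self.weights_)
            - 0.5 * np.log(2 * np.pi * self.variances_)
            - (x[:, None] - self.means_) ** 2 / (2 * self.variances_)
        )
        log_norm = np.logaddexp(log_comp[:, 0], log_comp[:, 1])
        return np.exp(log_comp - log_norm[:, None])

    def predict(self, X):
        """0 = left (transient-like) component, 1 = right (stable-like)."""
        return np.argmax(self.predict_proba(X), axis=1)

    def crossing_cutoff(self, fallback: float = 0.3) -> float:
        return choose_stable_cutoff(self, fallback=fallback)


def fit_pcc_gmm(pccs, seed=None, max_iter=500, tol=1e-8) -> PccGaussianMixture:
    """Functional wrapper: fit the two-component mixture to PCC values."""
    vals = np.asarray(list(pccs.values()) if isinstance(pccs, dict) else pccs, dtype=float)
    return PccGaussianMixture(max_iter=max_iter, tol=tol, random_state=seed).fit(vals)


def choose_stable_cutoff(fit: PccGaussianMixture, fallback: float = 0.3) -> float:
    """Crossing point of the weighted component densities inside (mu1, mu2).

    Solves ``eta * N(x; mu1, s1^2) = (1 - eta) * N(x; mu2, s2^2)``; the log
    ratio is a quadratic in x, solved in closed form. If no root lies
    strictly between the means (e.g. one component dominates everywhere),
    the ``fallback`` cutoff is returned with a warning.
    """
    w1, w2 = fit.weights_
    m1, m2 = fit.means_
    v1, v2 = fit.variances_
    # log(w1) - (x-m1)^2/2v1 - log(s1) = log(w2) - (x-m2)^2/2v2 - log(s2)
    a = 1.0 / (2 * v2) - 1.0 / (2 * v1)
    b = m1 / v1 - m2 / v2
    c = (
        m2**2 / (2 * v2)
        - m1**2 / (2 * v1)
        + np.log(w1)
        - np.log(w2)
        + 0.5 * np.log(v2 / v1)
    )
    if abs(a) < 1e-14:
        roots = [] if abs(b) < 1e-14 else [-c / b]
    else:
        disc = b * b - 4 * a * c
        roots = [] if disc < 0 else [(-b + s * np.sqrt(disc)) / (2 * a) for s in (1.0, -1.0)]
    inside = [r for r in roots if m1 < r < m2]
    if not inside:
        warnings.warn(
            f"no density crossing in ({m1:.3f}, {m2:.3f}); using fallback cutoff {fallback}",
            stacklevel=2,
        )
        return float(fallback)
    return float(min(inside))  # leftmost crossing inside the gap


def classify_stable(
    net: StaticNetwork, pccs: dict[tuple[str, str], float], delta: float
) -> np.ndarray:
    """Binary N x N stable-interaction mask: edge exists and PCC > delta (strict)."""
    if not (-1 <= delta <= 1):
        raise ValueError(f"delta must lie in [-1, 1], got {delta}")
    idx = net.index
    S = np.zeros((net.n_nodes, net.n_nodes))
    for (u, v), r in pccs.items():
        if r > delta:
            i, j = idx[u], idx[v]
            S[i, j] = S[j, i] = 1.0
    return S


# ---------------------------------------------------------------------------
# three-sigma activity thresholds and network assembly


@dataclass
class ActivityThresholds:
    """Per-protein profile statistics and active thresholds.

    ``f_weight = 1 / (1 + sigma^2)`` and ``at = mu + 3 * sigma * (1 - f_weight)``;
    a flat profile (sigma = 0) has f_weight 1 and at = mu.
    """

    mu: np.ndarray
    sigma: np.ndarray
    f_weight: np.ndarray
    at: np.ndarray


def compute_active_thresholds(ge: ExpressionMatrix, ddof: int = 0) -> ActivityThresholds:
    """Three-sigma activity threshold of every protein.

    ``ddof=0`` (population standard deviation) is the default convention;
    pass ``ddof=1`` for the sample convention.
    """
    mu = ge.values.mean(axis=1)
    sigma = ge.values.std(axis=1, ddof=ddof)
    f = 1.0 / (1.0 + sigma**2)
    at = mu + 3.0 * sigma * (1.0 - f)
    return ActivityThresholds(mu=mu, sigma=sigma, f_weight=f, at=at)


@dataclass
class DynamicNetworkSeries:
    """T binary adjacency matrices plus the stable mask over a fixed node set."""

    A: list[np.ndarray]
    S: np.ndarray
    delta: float
    nodes: list[str]

    @property
    def n_times(self) -> int:
        return len(self.A)


def build_dynamic_networks(
    net: StaticNetwork,
    ge: ExpressionMatrix,
    S: np.ndarray,
    at: ActivityThresholds,
    delta: float = 0.3,
) -> DynamicNetworkSeries:
    """Assemble the per-time-point networks.

    Edge (i, j) is present at time t iff it is stable, or it exists in the
    static network and both endpoints are active at t
    (``GE[i, t] >= AT(i)``, non-strict).
    """
    idx = ge.index
    order = [idx[g] for g in net.nodes]
    expr = ge.values[order, :]
    thr = at.at[order]
    active = expr >= thr[:, None]  # N x T
    adj = net.adjacency_matrix()
    A = []
    for t in range(ge.n_times):
        on = active[:, t].astype(float)
        At = np.maximum(S, adj * np.outer(on, on))
        np.fill_diagonal(At, 0.0)
        A.append(At)
    return DynamicNetworkSeries(A=A, S=S, delta=delta, nodes=list(net.nodes))
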