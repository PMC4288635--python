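"""Time-smoothed overlapping complex detection by symmetric factorization.

Each per-time network ``A[t]`` (binary, symmetric, zero diagonal) is modelled
through a nonnegative membership matrix ``H[t]`` of shape N x r: the derived
co-membership matrix ``U[t] = H[t] @ H[t].T`` gives, for every protein pair,
the (relaxed) number of complexes containing both. Edges are treated as
Poisson counts with mean ``U[t]``, stable pairs are encouraged to keep their
co-membership steady between consecutive time points, and a trace-norm
surrogate shrinks superfluous columns. The joint objective minimized is

    sum_t sum_{i != j} [ U[t]_ij - A[t]_ij * log U[t]_ij ]
    + lam  * sum_{t >= 2} sum_ij S_ij * (U[t]_ij - U[t-1]_ij)^2
    + beta * sum_t ||H[t]||_F^2

where ``||U||_* = ||H||_F^2`` for symmetric PSD ``U = H H^T`` makes the last
term an exact trace-norm penalty. Optimization is by per-time-point
multiplicative updates (gradient descent with automatic step size that
preserves nonnegativity), with a geometric backtracking guard that makes the
objective provably non-increasing sweep to sweep.

Continuous memberships are discretized by thresholding at ``tau`` after a
row-wise normalization (see :func:`discretize`); columns with fewer than
three members, duplicate and subset columns, and detections that are not
dense in their own network are dropped, so the effective number of detected
complexes adapts to the data rather than to the chosen rank.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "objective_value",
    "gradient",
    "update_timepoint",
    "TSOCD",
    "fit_tsocd",
    "discretize",
]


def _check_H(H_list):
    for t, H in enumerate(H_list):
        H = np.asarray(H, dtype=float)
        if np.any(H < 0):
            raise ValueError(f"negative entry in H[{t}]")
        if not np.all(np.isfinite(H)):
            raise ValueError(f"non-finite entry in H[{t}]")


def _recon_term(U: np.ndarray, A: np.ndarray, eps: float) -> float:
    """Poisson reconstruction loss over off-diagonal entries."""
    off = U.sum() - np.trace(U)
    logU = np.log(np.maximum(U, eps))
    return float(off - (A * logU).sum())


def _smooth_term(U1: np.ndarray, U0: np.ndarray, S: np.ndarray) -> float:
    D = U1 - U0
    return float((S * D * D).sum())


def objective_value(H_list, A_list, S, lam: float, beta: float, eps: float = 1e-10) -> float:
    """Full objective; ``U[t]`` is recomputed from ``H[t]`` on the fly."""
    _check_H(H_list)
    U = [H @ H.T for H in H_list]
    total = 0.0
    for t, A in enumerate(A_list):
        total += _recon_term(U[t], A, eps)
        total += beta * float((H_list[t] ** 2).sum())
        if t >= 1:
            total += lam * _smooth_term(U[t], U[t - 1], S)
    return total


def _local_objective(H_list, U_list, A_list, S, t, lam, beta, eps):
    """Only the objective terms that depend on H[t] (for backtracking)."""
    val = _recon_term(U_list[t], A_list[t], eps) + beta * float((H_list[t] ** 2).sum())
    if t >= 1:
        val += lam * _smooth_term(U_list[t], U_list[t - 1], S)
    if t + 1 < len(H_list):
        val += lam * _smooth_term(U_list[t + 1], U_list[t], S)
    return val


def _gradient_split(H_list, U_list, A_list, S, t, lam, beta, eps):
    """Positive and negative parts of d(objective)/dH[t], neighbors fixed."""
    H = H_list[t]
    U = U_list[t]
    A = A_list[t]
    # reconstruction: d/dH sum_{i!=j} U_ij = 2 (1 1^T - I) H ; the log part
    # gives -2 (A / U) H (A has zero diagonal).
    pos = 2.0 * (H.sum(axis=0)[None, :] - H)
    ratio = A / np.maximum(U, eps)
    neg = 2.0 * (ratio @ H)
    # trace-norm surrogate
    pos = pos + 2.0 * beta * H
    # smoothness with each existing neighbor:
    # d/dH lam * sum S_ij (U - U_nb)^2_ij = 4 lam [S o (U - U_nb)] H
    for nb in (t - 1, t + 1):
        if 0 <= nb < len(H_list):
            pos = pos + 4.0 * lam * ((S * U) @ H)
            neg = neg + 4.0 * lam * ((S * U_list[nb]) @ H)
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
        raise FloatingPointError(f"non-finite gradient at t={t}")
    return pos, neg


def gradient(H_list, A_list, S, t, lam, beta, eps=1e-10):
    """Analytic gradient of the objective w.r.t. H[t] (neighbors fixed)."""
    U = [H @ H.T for H in H_list]
    pos, neg = _gradient_split(H_list, U, A_list, S, t, lam, beta, eps)
    return pos - neg


def _sweep(H_list, U_list, A_list, S, t, lam, beta, eps, max_backtracks=30):
    """Guarded multiplicative sweep on H[t], updating U_list[t] in place.

    ``U_list`` must hold the current co-membership matrices. Returns
    ``(H_new, n_backtracks)``; on success ``U_list[t]`` is the new
    co-membership.
    """
    H = H_list[t]
    pos, neg = _gradient_split(H_list, U_list, A_list, S, t, lam, beta, eps)
    ratio = np.maximum(neg, 0.0) / np.maximum(pos, eps)
    obj_old = _local_objective(H_list, U_list, A_list, S, t, lam, beta, eps)
    alpha = 1.0
    n_back = 0
    tol = 1e-12 * max(abs(obj_old), 1.0)
    U_old = U_list[t]
    while True:
        H_new = np.maximum(H * ratio**alpha, eps)
        trial = list(H_list)
        trial[t] = H_new
        U_list[t] = H_new @ H_new.T
        obj_new = _local_objective(trial, U_list, A_list, S, t, lam, beta, eps)
        if obj_new <= obj_old + tol:
            return H_new, n_back
        n_back += 1
        if n_back >= max_backtracks:
            logger.debug("sweep at t=%d could not decrease objective; keeping H", t)
            U_list[t] = U_old
            return H, n_back
        alpha *= 0.5


def update_timepoint(
    H_list,
    A_list,
    S,
    t,
    lam: float,
    beta: float,
    eps: float = 1e-10,
    max_backtracks: int = 30,
):
    """One guarded multiplicative sweep on H[t].

    The candidate is ``H * (grad_neg / grad_pos)``; if it raises the (local)
    objective beyond tolerance, the step is halved by geometric interpolation
    toward the previous iterate (``H * ratio**alpha`` with alpha = 1, 1/2,
    1/4, ...). Returns ``(H_new, n_backtracks)``.
    """
    U_list = [H @ H.T for H in H_list]
    return _sweep(H_list, U_list, A_list, S, t, lam, beta, eps, max_backtracks)




def _edge_density(A: np.ndarray, members) -> float:
    """Within-member edge density of ``A`` (1.0 for fewer than 2 members)."""
    ix = sorted(members)
    k = len(ix)
    if k < 2:
        return 1.0
    sub = A[np.ix_(ix, ix)]
    return float(np.triu(sub, 1).sum() / (k * (k - 1) / 2))


class TSOCD(BaseEstimator):
    """Temporal overlapping complex detector.

    Parameters
    ----------
    n_components : int, default 1000
        Per-time-point factor rank r (capped at N). Chosen generously; the
        trace-norm penalty prunes unused columns.
    smooth_weight : float, default 2**-4
        Weight ``lam`` of the stable-pair temporal smoothness penalty.
    lowrank_weight : float, default 2**4
        Weight ``beta`` of the trace-norm (squared Frobenius) penalty.
    tau : float, default 0.3
        Discretization threshold on the normalized memberships.
    max_iter : int, default 150
        Maximum outer iterations (each sweeps t = 1..T in order).
    tol : float, default 1e-5
        Relative objective-change stopping criterion; 0 disables early stop.
    eps : float, default 1e-10
        Positivity floor inside logs, denominators and factor entries.
    normalize : {'row', 'column', 'raw'}, default 'row'
        Membership normalization applied before thresholding (see
        :func:`discretize`).
    min_size : int, default 3
        Minimum members for a detected complex to be kept.
    min_density : float, default 0.7
        Minimum within-complex edge density in the complex's own network
        ``A[t]``. The Poisson loss will happily cover a star or path of
        incidental edges with a single column, and any such acyclic cover
        has density ``2/k <= 2/3``; requiring density above that bound keeps
        only genuinely dense modules. Set to 0 to disable.
    random_state : int or None
        Seed for factor initialization; a fixed seed gives bitwise-identical
        factors across runs.

    Attributes
    ----------
    factors_ : list of N x r arrays, the continuous memberships per time point.
    objective_trace_ : objective after every sweep (non-increasing).
    n_iter_ : outer iterations used.
    n_backtracks_ : total backtracking events over the whole fit.
    assignments_ : list of binary N x r_t arrays after discretization.
    complexes_ : list (per t) of lists of member-index frozensets.
    """

    def __init__(
        self,
        n_components: int = 1000,
        smooth_weight: float = 2.0**-4,
        lowrank_weight: float = 2.0**4,
        tau: float = 0.3,
        max_iter: int = 150,
        tol: float = 1e-5,
        eps: float = 1e-10,
        normalize: str = "row",
        min_size: int = 3,
        min_density: float = 0.7,
        random_state=None,
    ):
        self.n_components = n_components
        self.smooth_weight = smooth_weight
        self.lowrank_weight = lowrank_weight
        self.tau = tau
        self.max_iter = max_iter
        self.tol = tol
        self.eps = eps
        self.normalize = normalize
        self.min_size = min_size
        self.min_density = min_density
        self.random_state = random_state

    def _validate(self):
        if self.smooth_weight < 0 or self.lowrank_weight < 0:
            raise ValueError("smooth_weight and lowrank_weight must be >= 0")
        if not (0 < self.tau < 1):
            raise ValueError(f"tau must lie in (0, 1), got {self.tau}")
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    def fit(self, X, y=None, S=None, H_init=None):
        """Fit the factorization to a series of adjacency matrices.

        Parameters
        ----------
        X : sequence of T symmetric binary N x N arrays (or a T x N x N array).
        S : binary N x N stable-pair mask; defaults to all zeros (no
            smoothness coupling).
        H_init : optional list of T initial factor matrices (overrides the
            seeded random initialization).
        """
        self._validate()
        A_list = [np.asarray(A, dtype=float) for A in X]
        if not A_list:
            raise ValueError("need at least one time point")
        N = A_list[0].shape[0]
        for A in A_list:
            if A.shape != (N, N):
                raise ValueError("all adjacency matrices must be N x N")
        if S is None:
            S = np.zeros((N, N))
        S = np.asarray(S, dtype=float)
        T = len(A_list)
        r = min(self.n_components, N)
        lam, beta, eps = self.smooth_weight, self.lowrank_weight, self.eps

        if H_init is not None:
            H_list = [np.maximum(np.asarray(H, dtype=float).copy(), eps) for H in H_init]
        else:
            ss = np.random.SeedSequence(self.random_state)
            scale = np.sqrt(max(float(np.mean(A_list)), 1e-6) / r)
            H_list = [
                np.maximum(np.random.default_rng(child).uniform(0.0, 1.0, size=(N, r)) * scale, eps)
                for child in ss.spawn(T)
            ]

        # incremental objective bookkeeping: per-time reconstruction +
        # Frobenius terms and per-consecutive-pair smoothness terms
        U_list = [H @ H.T for H in H_list]
        recon = [_recon_term(U_list[t], A_list[t], eps) + beta * float((H_list[t] ** 2).sum())
                 for t in range(T)]
        smooth = [lam * _smooth_term(U_list[t], U_list[t - 1], S) for t in range(1, T)]
        trace = [sum(recon) + sum(smooth)]
        n_back_total = 0
        it = 0
        for it in range(1, self.max_iter + 1):
            for t in range(T):
                H_list[t], nb = _sweep(H_list, U_list, A_list, S, t, lam, beta, eps)
                n_back_total += nb
                recon[t] = _recon_term(U_list[t], A_list[t], eps) + beta * float(
                    (H_list[t] ** 2).sum()
                )
                if t >= 1:
                    smooth[t - 1] = lam * _smooth_term(U_list[t], U_list[t - 1], S)
                if t + 1 < T:
                    smooth[t] = lam * _smooth_term(U_list[t + 1], U_list[t], S)
                trace.append(sum(recon) + sum(smooth))
            prev = trace[-1 - T]
            if self.tol > 0 and abs(prev - trace[-1]) <= self.tol * max(abs(prev), 1.0):
                break

        self.factors_ = H_list
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = it
        self.n_backtracks_ = n_back_total
        self.assignments_ = []
        self.complexes_ = []
        for t, H in enumerate(H_list):
            B, cxs = discretize(
                H,
                tau=self.tau,
                min_size=self.min_size,
                normalize=self.normalize,
            )
            if self.min_density > 0 and cxs:
                keep = [
                    k
                    for k, c in enumerate(cxs)
                    if _edge_density(A_list[t], c) >= self.min_density
                ]
                B = B[:, keep]
                cxs = [cxs[k] for k in keep]
            self.assignments_.append(B)
            self.complexes_.append(cxs)
        return self

    def fit_predict(self, X, y=None, S=None):
        return self.fit(X, S=S).complexes_


def fit_tsocd(A_list, S=None, **params) -> list[np.ndarray]:
    """Functional wrapper returning the continuous factors only."""
    return TSOCD(**params).fit(A_list, S=S).factors_


def discretize(
    H: np.ndarray,
    tau: float = 0.3,
    min_size: int = 3,
    normalize: str = "row",
    dead_tol: float = 1e-6,
) -> tuple[np.ndarray, list[frozenset[int]]]:
    """Threshold a continuous membership matrix into binary complexes.

    The objective constrains only the co-membership ``U = H H^T``, so the
    column-wise scale of ``H`` is not identified: a complex may be encoded by
    one strong column or split across several proportional weak ones.
    Thresholding therefore normalizes per **row** by default: protein ``i``
    joins complex ``k`` when ``h_ik >= tau * max_k' h_ik'``, i.e. when the
    membership is within ``tau`` of the protein's strongest membership. This
    is invariant to column splitting and does not revive columns that the
    trace-norm penalty shrank toward zero. ``normalize='column'`` divides
    each column by its maximum instead, and ``normalize='raw'`` thresholds
    the untransformed values.

    In row mode a protein is additionally required to reach a co-membership
    of at least ``tau**2`` with some other protein (``max_j U_ij >= tau^2``
    with ``U = H H^T``): row normalization alone would always keep each
    protein's strongest membership however small it is in absolute terms,
    and the co-membership matrix — unlike the column scale of ``H`` — is
    what the objective actually identifies. A membership propensity of
    ``tau`` corresponds to a co-membership of ``tau^2`` between two such
    members, hence the floor.

    Entries below ``dead_tol`` (the shrunken floor) never count as
    memberships. Thresholded columns with fewer than ``min_size`` members
    are dropped, duplicate columns are collapsed, and columns whose member
    set is a strict subset of another column's are removed — the same
    co-membership block can be decomposed into one full column plus partial
    ones, and a subset column adds no membership information beyond its
    superset.

    Returns the binary N x r_t matrix and the list of member-index sets.
    """
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise ValueError("membership matrix must be nonnegative")
    if normalize not in ("row", "column", "raw"):
        raise ValueError(f"normalize must be 'row', 'column' or 'raw', got {normalize!r}")
    colmax = H.max(axis=0)
    live = colmax > dead_tol
    Hl = H[:, live]
    eligible = np.ones(H.shape[0], dtype=bool)
    if normalize == "column" and Hl.size:
        Hn = Hl / Hl.max(axis=0, keepdims=True)
    elif normalize == "row" and Hl.size:
        rowmax = Hl.max(axis=1, keepdims=True)
        Hn = np.divide(Hl, rowmax, out=np.zeros_like(Hl), where=rowmax > dead_tol)
        U = Hl @ Hl.T
        np.fill_diagonal(U, 0.0)
        eligible = U.max(axis=1) >= tau * tau
    else:
        Hn = Hl
    B = ((Hn >= tau) & (Hl > dead_tol) & eligible[:, None]).astype(float)
    keep = B.sum(axis=0) >= min_size
    B = B[:, keep]
    # collapse duplicate columns, preserving first-occurrence order
    seen: dict[bytes, int] = {}
    cols = []
    for k in range(B.shape[1]):
        key = B[:, k].tobytes()
        if key not in seen:
            seen[key] = k
            cols.append(k)
    B = B[:, cols]
    sets = [frozenset(np.flatnonzero(B[:, k]).tolist()) for k in range(B.shape[1])]
    # drop strict subsets of other columns
    keep_idx = [
        k
        for k, c in enumerate(sets)
        if not any(o != k and c < sets[o] for o in range(len(sets)))
    ]
    B = B[:, keep_idx]
    complexes = [sets[k] for k in keep_idx]
    return B, complexes
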