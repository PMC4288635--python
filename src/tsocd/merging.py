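"""Merging near-duplicate complexes detected at different time points.

Complexes driven by stable interactions are re-detected at every time point
in nearly identical form. The per-time binary assignment matrices are
concatenated column-wise into ``Y`` (N proteins x L detected complexes) and
factorized as ``Y ~ W @ V`` with nonnegative factors; each column (complex)
is assigned to the latent group where its ``V`` column peaks, and complexes
within a group are merged by membership union. The group count ``K`` is a
cap, not a target: unused latent dimensions stay empty, and time-specific
complexes that land alone in a group pass through untouched.

A simpler greedy overlap-threshold merger (repeatedly fuse the most similar
pair above a neighborhood-affinity threshold) is provided as a baseline
alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .evaluation import neighborhood_affinity

logger = logging.getLogger(__name__)

__all__ = [
    "ConcatAssignment",
    "concat_assignments",
    "MergeNMF",
    "nmf_factorize",
    "assign_groups",
    "merge_within_groups",
    "merge_by_overlap",
]


@dataclass
class ConcatAssignment:
    """N x L binary matrix of all detected complexes with column provenance."""

    Y: np.ndarray
    column_origin: list[tuple[int, int]]  # (time index, local complex index)

    @property
    def n_columns(self) -> int:
        return self.Y.shape[1]


def concat_assignments(assignment_list) -> ConcatAssignment:
    """Concatenate per-time binary assignment matrices column-wise.

    Columns are ordered by (time point, local complex index); an empty time
    point contributes no columns.
    """
    mats = [np.asarray(B, dtype=float) for B in assignment_list]
    sizes = {B.shape[0] for B in mats if B.size}
    if len(sizes) > 1:
        raise ValueError(f"inconsistent node counts across time points: {sorted(sizes)}")
    n = sizes.pop() if sizes else 0
    cols = []
    origin = []
    for t, B in enumerate(mats):
        if B.size == 0:
            continue
        for k in range(B.shape[1]):
            cols.append(B[:, k])
            origin.append((t, k))
    Y = np.column_stack(cols) if cols else np.zeros((n, 0))
    return ConcatAssignment(Y=Y, column_origin=origin)


class MergeNMF(BaseEstimator):
    """Nonnegative factorization ``Y ~ W V`` by multiplicative updates.

    Frobenius loss by default (``loss='kl'`` switches to the generalized
    Kullback-Leibler divergence). ``n_groups`` is clamped to the number of
    columns with a warning when it exceeds it.

    Attributes
    ----------
    W_ : N x K nonnegative basis.
    V_ : K x L nonnegative encoding.
    groups_ : per-column argmax group id (ties -> lowest id).
    error_trace_ : per-iteration reconstruction error (non-increasing).
    """

    def __init__(self, n_groups=1000, max_iter=300, tol=1e-6, eps=1e-10,
                 loss="frobenius", random_state=None):
        self.n_groups = n_groups
        self.max_iter = max_iter
        self.tol = tol
        self.eps = eps
        self.loss = loss
        self.random_state = random_state

    def _error(self, Y, W, V):
        if self.loss == "frobenius":
            return float(((Y - W @ V) ** 2).sum())
        R = np.maximum(W @ V, self.eps)
        return float((R - Y * np.log(R)).sum())

    def fit(self, Y, y=None):
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.loss not in ("frobenius", "kl"):
            raise ValueError(f"unknown loss {self.loss!r}")
        Y = np.asarray(Y, dtype=float)
        if np.any(Y < 0):
            raise ValueError("Y must be nonnegative")
        n, L = Y.shape
        if L == 0:
            self.W_ = np.zeros((n, 0))
            self.V_ = np.zeros((0, 0))
            self.groups_ = np.zeros(0, dtype=int)
            self.error_trace_ = np.zeros(0)
            return self
        K = self.n_groups
        if K > L:
            warnings.warn(f"n_groups={K} exceeds number of complexes L={L}; clamping to {L}",
                          stacklevel=2)
            K = L
        eps = self.eps
        rng = np.random.default_rng(self.random_state)
        scale = np.sqrt(max(Y.mean(), 1e-6) / K)
        W = np.maximum(rng.uniform(0, 1, size=(n, K)) * scale, eps)
        V = np.maximum(rng.uniform(0, 1, size=(K, L)) * scale, eps)
        trace = [self._error(Y, W, V)]
        for _ in range(self.max_iter):
            if self.loss == "frobenius":
                W *= (Y @ V.T) / np.maximum(W @ (V @ V.T), eps)
                V *= (W.T @ Y) / np.maximum((W.T @ W) @ V, eps)
            else:  # generalized KL
                R = np.maximum(W @ V, eps)
                W *= ((Y / R) @ V.T) / np.maximum(V.sum(axis=1)[None, :], eps)
                R = np.maximum(W @ V, eps)
                V *= (W.T @ (Y / R)) / np.maximum(W.sum(axis=0)[:, None], eps)
            np.maximum(W, eps, out=W)
            np.maximum(V, eps, out=V)
            trace.append(self._error(Y, W, V))
            if abs(trace[-2] - trace[-1]) <= self.tol * max(abs(trace[-2]), 1.0):
                break
        self.W_ = W
        self.V_ = V
        groups = assign_groups(V, eps=eps)
        # identical complexes are trivially "very similar": with a
        # degenerate (collinear) basis the per-column subproblem is not
        # strictly convex and byte-identical columns could drift into
        # different argmax groups, so unify them explicitly.
        first_group: dict[bytes, int] = {}
        for l in range(L):
            key = Y[:, l].tobytes()
            groups[l] = first_group.setdefault(key, int(groups[l]))
        self.groups_ = groups
        self.error_trace_ = np.asarray(trace)
        return self


def nmf_factorize(Y, K, seed=None, max_iter=300, tol=1e-6) -> MergeNMF:
    """Functional wrapper around :class:`MergeNMF`."""
    return MergeNMF(n_groups=K, max_iter=max_iter, tol=tol, random_state=seed).fit(Y)


def assign_groups(V: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Group id of each complex: row index where its V column peaks.

    Ties break to the lowest group id (numpy argmax convention). A column
    that is numerically all-zero gets a fresh singleton group with a warning.
    """
    V = np.asarray(V, dtype=float)
    K, L = V.shape
    groups = np.argmax(V, axis=0)
    dead = V.max(axis=0) <= eps * (1 + 1e-9)
    if np.any(dead):
        warnings.warn(f"{int(dead.sum())} complex column(s) have all-zero factor; "
                      "assigning singleton groups", stacklevel=2)
        next_id = K
        for l in np.flatnonzero(dead):
            groups[l] = next_id
            next_id += 1
    return groups


def merge_within_groups(
    concat: ConcatAssignment, groups, min_size: int = 3
) -> list[frozenset[int]]:
    """Union the member sets of the complexes in each group.

    Singleton groups pass their complex through unchanged. The merged list
    is deduplicated and filtered to ``min_size`` members; order follows the
    first column of each group.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != concat.n_columns:
        raise ValueError("groups must cover every column")
    members = [frozenset(np.flatnonzero(concat.Y[:, l]).tolist()) for l in range(concat.n_columns)]
    by_group: dict[int, frozenset[int]] = {}
    order: list[int] = []
    for l, g in enumerate(groups):
        g = int(g)
        if g not in by_group:
            by_group[g] = members[l]
            order.append(g)
        else:
            by_group[g] = by_group[g] | members[l]
    out: list[frozenset[int]] = []
    for g in order:
        c = by_group[g]
        if len(c) >= min_size and c not in out:
            out.append(c)
    return out


def merge_by_overlap(complexes, threshold: float = 0.65) -> list[frozenset]:
    """Greedy overlap merging: repeatedly fuse the most similar pair.

    Similarity is the neighborhood affinity ``|p & q|^2 / (|p| |q|)``. While
    some pair scores at or above ``threshold``, the highest-scoring pair
    (ties broken lexicographically on sorted members) is replaced by its
    union. Deterministic and idempotent.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    pool = [frozenset(c) for c in complexes]
    # drop exact duplicates up front
    uniq: list[frozenset] = []
    for c in pool:
        if c not in uniq:
            uniq.append(c)
    pool = uniq
    while len(pool) > 1:
        best = None
        for a in range(len(pool)):
            for b in range(a + 1, len(pool)):
                na = neighborhood_affinity(pool[a], pool[b])
                if na >= threshold:
                    key = (-na, sorted(pool[a]), sorted(pool[b]))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        if best is None:
            break
        _, a, b = best
        merged = pool[a] | pool[b]
        pool = [c for k, c in enumerate(pool) if k not in (a, b)]
        pool.append(merged)
    return pool
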