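"""Scoring predicted protein complexes against a reference catalogue.

Two complementary scores are provided. The **f-measure** counts whole-complex
matches: a predicted complex matches a reference complex when their
neighborhood affinity ``NA(p, b) = |p & b|^2 / (|p| |b|)`` reaches a
threshold ``omega`` (0.25 by default, the common choice in the complex
evaluation literature); precision is the matched fraction of predictions,
recall the matched fraction of references, and f their harmonic mean. The
**PR metric** instead averages the best per-complex overlap percentages:
P is the mean over predictions of the largest fraction of the prediction
covered by some reference, R the mean over references of the largest
fraction covered by some prediction, and PR their harmonic mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

logger = logging.getLogger(__name__)

__all__ = [
    "neighborhood_affinity",
    "EvalReport",
    "f_measure",
    "pr_metric",
    "filter_reference",
]


def neighborhood_affinity(p, b) -> float:
    """Overlap score ``|p & b|^2 / (|p| |b|)`` between two protein sets."""
    p, b = set(p), set(b)
    if not p or not b:
        raise ValueError("neighborhood affinity of an empty set is undefined")
    inter = len(p & b)
    return inter * inter / (len(p) * len(b))


@dataclass
class EvalReport:
    """Complex-level match scores of a prediction against a reference set."""

    precision: float
    recall: float
    f_measure: float
    pr_metric: float
    omega: float
    n_predicted: int
    n_reference: int
    n_matched_pred: int
    n_matched_ref: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _complex_list(cs):
    return [frozenset(c) for c in cs]


def f_measure(pred, ref, omega: float = 0.25) -> EvalReport:
    """Match-based precision/recall/f of predicted vs reference complexes.

    A predicted complex is matched when some reference complex has
    ``NA >= omega``, and symmetrically for reference complexes. Empty
    inputs give all-zero scores with a warning.
    """
    if not (0 < omega <= 1):
        raise ValueError(f"omega must lie in (0, 1], got {omega}")
    P = _complex_list(pred)
    B = _complex_list(ref)
    if not P or not B:
        warnings.warn("empty prediction or reference set; scores are 0", stacklevel=2)
        return EvalReport(0.0, 0.0, 0.0, 0.0, omega, len(P), len(B), 0, 0)
    na = [[neighborhood_affinity(p, b) for b in B] for p in P]
    matched_pred = sum(1 for row in na if max(row) >= omega)
    matched_ref = sum(1 for j in range(len(B)) if max(row[j] for row in na) >= omega)
    precision = matched_pred / len(P)
    recall = matched_ref / len(B)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return EvalReport(
        precision=precision,
        recall=recall,
        f_measure=f,
        pr_metric=pr_metric(P, B),
        omega=omega,
        n_predicted=len(P),
        n_reference=len(B),
        n_matched_pred=matched_pred,
        n_matched_ref=matched_ref,
    )


def pr_metric(pred, ref) -> float:
    """Harmonic mean of mean best overlap percentages in both directions."""
    P = _complex_list(pred)
    B = _complex_list(ref)
    if not P or not B:
        warnings.warn("empty prediction or reference set; PR metric is 0", stacklevel=2)
        return 0.0
    p_cov = sum(max(len(p & b) for b in B) / len(p) for p in P) / len(P)
    r_cov = sum(max(len(p & b) for p in P) / len(b) for b in B) / len(B)
    if p_cov + r_cov == 0:
        return 0.0
    return 2 * p_cov * r_cov / (p_cov + r_cov)


def filter_reference(ref, nodes, min_size: int = 3) -> list[frozenset]:
    """Restrict reference complexes to proteins present in the network.

    Mirrors the usual gold-standard preprocessing: members absent from the
    evaluated network are removed, then complexes below ``min_size`` are
    dropped.
    """
    node_set = set(nodes)
    out = []
    for c in ref:
        kept = frozenset(c) & node_set
        if len(kept) >= min_size and kept not in out:
            out.append(kept)
    return out
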