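"""Readers and writers for the plain-text formats the pipeline consumes.

Three kinds of files are handled:

* **edge lists** — two tab/whitespace-separated protein IDs per line, one
  undirected interaction each (the usual DIP/BioGrid flat export shape);
* **expression tables** — TSV with a header of time labels and one row per
  gene, optionally collapsible over replicate cycles;
* **complex catalogues** — one complex per line, tab-separated member IDs
  (CYC2008/MIPS style).

Everything downstream works on the in-memory containers defined here; node
index order is fixed at read time and shared by every matrix in the pipeline.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StaticNetwork",
    "ExpressionMatrix",
    "ComplexSet",
    "read_edge_list",
    "write_edge_list",
    "read_expression",
    "write_expression",
    "restrict_to_common",
    "read_complexes",
    "write_complexes",
]


def _canon(u: str, v: str) -> tuple[str, str]:
    """Canonical (sorted) form of an undirected edge."""
    return (u, v) if u <= v else (v, u)


@dataclass
class StaticNetwork:
    """An undirected, unweighted protein-protein interaction graph.

    ``nodes`` fixes the integer index 0..N-1 used by every matrix built from
    this network. ``edges`` holds canonical (lexicographically sorted) ID
    pairs; self-loops and duplicates are rejected.
    """

    nodes: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node IDs")
        node_set = set(self.nodes)
        canon = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint {u!r}/{v!r} not in node list")
            canon.add(_canon(u, v))
        self.edges = canon

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency with zero diagonal."""
        idx = self.index
        A = np.zeros((self.n_nodes, self.n_nodes))
        for u, v in self.edges:
            i, j = idx[u], idx[v]
            A[i, j] = A[j, i] = 1.0
        return A


@dataclass
class ExpressionMatrix:
    """N x T table of (nonnegative) expression values with gene IDs."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length must match number of rows")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.values.shape[1] < 2:
            raise ValueError("need at least two time points")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class ComplexSet:
    """A list of protein-ID sets, optionally stamped with a 1-based time point."""

    complexes: list[frozenset[str]]
    time_labels: list[int] | None = None

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        if self.time_labels is not None and len(self.time_labels) != len(self.complexes):
            raise ValueError("time_labels length must match complexes")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def filtered(self, min_size: int = 3) -> "ComplexSet":
        """Drop complexes below ``min_size``; dedup when not time-stamped."""
        if self.time_labels is None:
            seen: list[frozenset[str]] = []
            for c in self.complexes:
                if len(c) >= min_size and c not in seen:
                    seen.append(c)
            return ComplexSet(seen)
        keep = [(c, t) for c, t in zip(self.complexes, self.time_labels) if len(c) >= min_size]
        return ComplexSet([c for c, _ in keep], [t for _, t in keep])


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(path) -> StaticNetwork:
    """Read a 2+ column edge list; extra columns (e.g. weights) are ignored.

    Node order is first-appearance order. Self-loops and duplicate edges are
    dropped with a logged count. Lines starting with ``#`` are comments.
    """
    nodes: list[str] = []
    seen: set[str] = set()
    edges: set[tuple[str, str]] = set()
    n_self = n_dup = 0
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns, got {len(parts)}")
            n_lines += 1
            u, v = parts[0], parts[1]
            for g in (u, v):
                if g not in seen:
                    seen.add(g)
                    nodes.append(g)
            if u == v:
                n_self += 1
                continue
            e = _canon(u, v)
            if e in edges:
                n_dup += 1
            else:
                edges.add(e)
    if n_lines == 0:
        raise ValueError(f"{path}: empty edge list")
    if n_self or n_dup:
        logger.info("read_edge_list(%s): dropped %d self-loops, %d duplicates", path, n_self, n_dup)
    return StaticNetwork(nodes=nodes, edges=edges)


def write_edge_list(net: StaticNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# expression tables


def read_expression(path, average_cycles: bool = False, n_cycles: int = 3) -> ExpressionMatrix:
    """Read a TSV expression table (header of time labels, one row per gene).

    With ``average_cycles=True`` the T*n_cycles columns are interpreted as
    ``n_cycles`` successive replicate cycles of T time points each and
    collapsed to T columns by averaging the replicates of each time point
    (the usual treatment of multi-cycle time-course microarrays).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two time-point columns")
    dup = df.index[df.index.duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate gene ID(s): {dup[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(~np.isfinite(numeric.to_numpy(dtype=float)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at gene {df.index[i]!r}, column {df.columns[j]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    if average_cycles:
        n, total = values.shape
        if total % n_cycles:
            raise ValueError(f"{path}: {total} columns not divisible by {n_cycles} cycles")
        t = total // n_cycles
        values = values.reshape(n, n_cycles, t).mean(axis=1)
    return ExpressionMatrix(gene_ids=list(df.index), values=values)


def write_expression(ge: ExpressionMatrix, path) -> None:
    cols = [f"t{j + 1}" for j in range(ge.n_times)]
    pd.DataFrame(ge.values, index=pd.Index(ge.gene_ids, name="gene"), columns=cols).to_csv(
        path, sep="\t", float_format="%.6g"
    )


def restrict_to_common(
    net: StaticNetwork, ge: ExpressionMatrix
) -> tuple[StaticNetwork, ExpressionMatrix]:
    """Restrict both inputs to the IDs they share, with aligned index order.

    The shared order is the network's node order filtered to the
    intersection; edges with an endpoint lacking expression are removed.
    """
    have = set(ge.gene_ids)
    common = [g for g in net.nodes if g in have]
    if not common:
        raise ValueError("no IDs shared between network and expression matrix")
    common_set = set(common)
    edges = {e for e in net.edges if e[0] in common_set and e[1] in common_set}
    idx = ge.index
    values = ge.values[[idx[g] for g in common], :]
    return StaticNetwork(nodes=common, edges=edges), ExpressionMatrix(common, values)


# ---------------------------------------------------------------------------
# complex catalogues


_TIME_PREFIX = re.compile(r"^t(\d+):$")


def read_complexes(path, min_size: int | None = None) -> ComplexSet:
    """Read one complex per line (tab/whitespace-separated member IDs).

    A leading ``t<k>:`` token is interpreted as a 1-based time stamp.
    ``min_size`` drops smaller complexes at read time; pass ``min_size=3``
    to keep only the complexes considered in standard evaluations.
    """
    complexes: list[frozenset[str]] = []
    labels: list[int] = []
    any_label = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                logger.warning("read_complexes(%s): skipping empty line %d", path, lineno)
                continue
            tokens = line.split()
            label = 0
            m = _TIME_PREFIX.match(tokens[0])
            if m:
                any_label = True
                label = int(m.group(1))
                tokens = tokens[1:]
            members = frozenset(tokens)
            if min_size is not None and len(members) < min_size:
                continue
            complexes.append(members)
            labels.append(label)
    return ComplexSet(complexes, labels if any_label else None)


def write_complexes(cs: ComplexSet, path) -> None:
    """Write one complex per line with sorted members (deterministic output)."""
    with open(path, "w", encoding="utf-8") as fh:
        for k, c in enumerate(cs.complexes):
            prefix = ""
            if cs.time_labels is not None:
                prefix = f"t{cs.time_labels[k]}:\t"
            fh.write(prefix + "\t".join(sorted(c)) + "\n")
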