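"""Thresholding connectivity matrices into undirected graphs.

A correlation matrix becomes a graph in three caller-ordered moves: select
the connectivity members (positive / negative / full), threshold by absolute
strength or by sparsity (edge density), and optionally binarize. Weighted
graphs keep |c_ij| as the edge weight; the strength threshold is strict
(|c| > r_thr retained).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "MEMBERS",
    "BrainGraph",
    "ThresholdSpec",
    "select_members",
    "threshold_strength",
    "threshold_sparsity",
    "to_binary",
    "graph_series",
]

MEMBERS = ("positive", "negative", "full")


@dataclass(frozen=True)
class BrainGraph:
    """Undirected graph as a symmetric nonnegative adjacency matrix."""

    adjacency: np.ndarray
    kind: str  # "binary" | "weighted"
    member: str = "full"

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-12, rtol=0):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed (diagonal must be zero)")
        if np.any(a < 0):
            raise ValueError("edge weights must be nonnegative")
        if self.kind not in ("binary", "weighted"):
            raise ValueError(f"unknown graph kind {self.kind!r}")
        if self.kind == "binary" and not np.all(np.isin(a, (0.0, 1.0))):
            raise ValueError("binary adjacency entries must be 0 or 1")
        object.__setattr__(self, "adjacency", a)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2) if n > 1 else 0.0

    def edge_list(self) -> np.ndarray:
        """Edges as rows (i, j, w) with i < j, 0-based node indices."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([i, j, self.adjacency[i, j]])


@dataclass(frozen=True)
class ThresholdSpec:
    """An ordered list of thresholds under one thresholding method.

    ``method`` is "strength" (absolute correlation cutoff, identical across
    subjects) or "sparsity" (target edge density, giving a subject-specific
    strength cutoff). Values must be strictly increasing within [0, 1].
    """

    method: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.method not in ("strength", "sparsity"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        vals = tuple(float(v) for v in self.values)
        if not vals:
            raise ValueError("threshold list is empty")
        if any(not 0 <= v <= 1 for v in vals):
            raise ValueError("thresholds must lie in [0, 1]")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "values", vals)

    @classmethod
    def default_grid(cls, method: str = "sparsity") -> "ThresholdSpec":
        """0.04 to 1.0 in steps of 0.04 (the conventional 26-point sweep
        starts at the first nonzero step for sparsity)."""
        return cls(method, tuple(np.round(np.arange(0.04, 1.0001, 0.04), 10)))


def select_members(C: ConnectivityMatrix, member: str) -> ConnectivityMatrix:
    """Keep one connectivity member: positive, negative, or full.

    positive keeps positive correlations and zeroes the rest; negative keeps
    the absolute values of negative correlations; full takes |c| everywhere.
    All downstream thresholding operates on the returned nonnegative matrix.
    """
    if member not in MEMBERS:
        raise ValueError(f"unknown member {member!r}; expected one of {MEMBERS}")
    c = C.r
    if member == "positive":
        out = np.where(c > 0, c, 0.0)
    elif member == "negative":
        out = np.where(c < 0, -c, 0.0)
    else:
        out = np.abs(c)
    return ConnectivityMatrix(out, C.node_names)


def threshold_strength(C: ConnectivityMatrix, r_thr: float) -> BrainGraph:
    """Retain |c_ij| as an edge weight wherever |c_ij| > r_thr (strict)."""
    if not 0 <= r_thr <= 1:
        raise ValueError(f"strength threshold {r_thr} not in [0, 1]")
    a = np.abs(C.r)
    w = np.where(a > r_thr, a, 0.0)
    return BrainGraph(w, "weighted")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def threshold_sparsity(C: ConnectivityMatrix, s: float) -> BrainGraph:
    """Retain the E* strongest connections, E* = round(s * N(N-1)/2).

    Rounding is half-away-from-zero so edge counts are platform-stable.
    Ties at the cutoff are broken deterministically: descending |c|, then
    ascending (i, j) lexicographic. Zero entries are never edges, so the
    achieved count can fall below E* on sparse matrices.
    """
    if not 0 < s <= 1:
        raise ValueError(f"sparsity {s} not in (0, 1]")
    n = C.n_nodes
    target = _round_half_away(s * n * (n - 1) / 2)
    if target == 0:
        warnings.warn(f"sparsity {s} yields zero edges for N={n}", stacklevel=2)
        return BrainGraph(np.zeros_like(C.r), "weighted")
    a = np.abs(C.r)
    iu, ju = np.nonzero(np.triu(a, k=1))
    w = a[iu, ju]
    order = np.lexsort((ju, iu, -w))  # primary: descending |c|; then (i, j)
    keep = order[:target]
    out = np.zeros_like(a)
    out[iu[keep], ju[keep]] = w[keep]
    out += out.T
    return BrainGraph(out, "weighted")


def to_binary(G: BrainGraph) -> BrainGraph:
    """Binarize: a_ij = 1 wherever w_ij > 0."""
    return BrainGraph((G.adjacency > 0).astype(float), "binary", G.member)


def graph_series(
    C: ConnectivityMatrix, spec: ThresholdSpec, kind: str = "binary"
) -> list[BrainGraph]:
    """Threshold a matrix at every value of a spec, as binary or weighted graphs."""
    thresh = threshold_strength if spec.method == "strength" else threshold_sparsity
    graphs = [thresh(C, v) for v in spec.values]
    if kind == "binary":
        graphs = [to_binary(g) for g in graphs]
    elif kind != "weighted":
        raise ValueError(f"unknown network kind {kind!r}")
    return graphs
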