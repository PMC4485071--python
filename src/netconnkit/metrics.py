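"""Global and nodal graph-theoretic metrics for undirected graphs.

Implements the standard battery used in connectomics: clustering coefficient
(Watts-Strogatz; Onnela for weighted graphs), characteristic path length as
the harmonic mean distance, local and global efficiency, Newman modularity
with a deterministic greedy (CNM) optimizer, degree/strength assortativity,
the hierarchy exponent beta of C(k) ~ k^(-beta), Laplacian synchronizability
lambda_2/lambda_max, nodal degree/efficiency/betweenness, and the trapezoid
area under a metric-versus-threshold curve.

Edge lengths are 1 for binary graphs and the reciprocal of the connection
weight for weighted graphs, so stronger connections are shorter. All-pairs
shortest paths switch between the Floyd-Warshall algorithm (graph density
above 10%) and Johnson's algorithm (sparser), which agree to rounding.

Metrics that are mathematically undefined for an input (assortativity of a
regular graph, synchronizability of a disconnected graph, hierarchy with too
few eligible nodes) raise :class:`UndefinedMetricError` rather than return a
fabricated number; the curve/AUC layer converts these to NaN and skips them.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import floyd_warshall, johnson

from .exceptions import UndefinedMetricError
from .graphs import BrainGraph

__all__ = [
    "DistanceMatrix",
    "GlobalMetrics",
    "NodalMetrics",
    "MetricCurve",
    "GLOBAL_METRIC_NAMES",
    "shortest_paths",
    "clustering_coefficient",
    "char_path_length",
    "efficiency_global",
    "efficiency_local",
    "modularity_q",
    "modularity",
    "assortativity",
    "hierarchy",
    "synchronization",
    "nodal_centralities",
    "global_metrics",
    "auc",
]

GLOBAL_METRIC_NAMES = (
    "Cp",
    "Lp",
    "Eloc",
    "Eg",
    "Q",
    "assortativity",
    "hierarchy",
    "synchronization",
)

DENSITY_SWITCH = 0.10  # above this, use Floyd-Warshall; else Johnson


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest path lengths; unreachable pairs are +inf."""

    d: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class GlobalMetrics:
    """One row of global topology; undefined entries are NaN."""

    Cp: float
    Lp: float
    Eloc: float
    Eg: float
    Q: float
    assortativity: float
    hierarchy: float
    synchronization: float
    partition: np.ndarray | None = field(default=None, compare=False)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in GLOBAL_METRIC_NAMES}


@dataclass(frozen=True)
class NodalMetrics:
    """Per-node centralities, each an N-vector."""

    degree: np.ndarray
    nodal_efficiency: np.ndarray
    betweenness: np.ndarray


def _length_matrix(G: BrainGraph) -> np.ndarray:
    """Edge lengths: 1 for binary edges, 1/w for weighted edges; 0 = no edge."""
    a = G.adjacency
    with np.errstate(divide="ignore"):
        lengths = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0)
    if G.kind == "binary":
        lengths = (a > 0).astype(float)
    return lengths


def shortest_paths(G: BrainGraph) -> DistanceMatrix:
    """All-pairs shortest path lengths with a density-based algorithm switch."""
    lengths = _length_matrix(G)
    if G.density > DENSITY_SWITCH:
        d = floyd_warshall(lengths, directed=False)
    else:
        d = johnson(csr_matrix(lengths), directed=False)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d)


def clustering_coefficient(G: BrainGraph) -> tuple[float, np.ndarray]:
    """Mean and per-node clustering coefficient.

    Binary: C_i = 2 t_i / (k_i (k_i - 1)) with t_i the triangle count at i.
    Weighted: Onnela's geometric-mean triangle intensity on weights rescaled
    by the graph maximum (keeping C_i in [0, 1]), with the binary degree in
    the denominator. Nodes with fewer than two neighbors contribute 0.
    """
    a = G.adjacency
    k = (a > 0).sum(axis=1).astype(float)
    if G.kind == "binary":
        t = np.diag(a @ a @ a) / 2.0
    else:
        wmax = a.max()
        w3 = np.cbrt(a / wmax) if wmax > 0 else a
        t = np.diag(w3 @ w3 @ w3) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(denom > 0, 2.0 * t / denom, 0.0)
    return float(ci.mean()), ci


def char_path_length(D: DistanceMatrix) -> float:
    """Harmonic-mean characteristic path length.

    Lp = N(N-1) / sum_{i != j} 1/d_ij with 1/inf = 0, which stays finite
    under disconnection; an edgeless graph returns +inf.
    """
    n = D.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    inv = _inverse_distances(D.d)
    total = inv.sum()
    return float(n * (n - 1) / total) if total > 0 else math.inf


def _inverse_distances(d: np.ndarray) -> np.ndarray:
    inv = np.zeros_like(d)
    off = ~np.eye(d.shape[0], dtype=bool)
    finite = off & np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return inv


def efficiency_global(D: DistanceMatrix) -> float:
    """Mean inverse shortest-path length over all ordered pairs."""
    n = D.n_nodes
    if n < 2:
        return 0.0
    return float(_inverse_distances(D.d).sum() / (n * (n - 1)))


def efficiency_local(G: BrainGraph) -> tuple[float, np.ndarray]:
    """Mean and per-node local efficiency.

    Eloc_i is the global efficiency of the subgraph induced by the neighbors
    of i, with edge weights inherited; nodes with fewer than two neighbors
    contribute 0.
    """
    a = G.adjacency
    n = G.n_nodes
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i] > 0)
        if nbrs.size < 2:
            continue
        sub = BrainGraph(a[np.ix_(nbrs, nbrs)], G.kind, G.member)
        eloc[i] = efficiency_global(shortest_paths(sub))
    return float(eloc.mean()), eloc


def modularity_q(adjacency: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity Q of a partition on a (weighted) adjacency matrix.

    Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j).
    """
    a = np.asarray(adjacency, dtype=float)
    labels = np.asarray(labels)
    two_m = a.sum()
    if two_m == 0:
        raise ValueError("modularity undefined for an empty graph")
    k = a.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((a - np.outer(k, k) / two_m) * same).sum() / two_m)


def modularity(G: BrainGraph) -> tuple[float, np.ndarray]:
    """Greedy agglomerative (CNM) modularity optimization.

    Starts from singleton communities and repeatedly merges the connected
    pair with the largest modularity gain (ties broken by the smallest
    community index pair) until one community remains, returning the
    partition with the highest Q encountered. Deterministic by construction.
    """
    a = G.adjacency
    n = G.n_nodes
    two_m = a.sum()
    if two_m == 0:
        raise ValueError("modularity undefined for an empty graph")
    # e[u, v]: fraction of edge weight between communities u and v;
    # a_frac[u]: fraction of edge ends in community u.
    e = a / two_m
    a_frac = e.sum(axis=1)
    labels = np.arange(n)
    alive = np.ones(n, dtype=bool)
    best_q = modularity_q(a, labels)
    best_labels = labels.copy()
    current_q = best_q
    for _ in range(n - 1):
        idx = np.flatnonzero(alive)
        if idx.size < 2:
            break
        sub_e = e[np.ix_(idx, idx)]
        gain = 2.0 * (sub_e - np.outer(a_frac[idx], a_frac[idx]))
        connected = sub_e > 0
        np.fill_diagonal(gain, -np.inf)
        np.fill_diagonal(connected, False)
        gain = np.where(connected, gain, -np.inf)
        if not np.isfinite(gain).any():
            break  # disconnected community graph: no further merges
        flat = np.argmax(gain)  # first occurrence = smallest (u, v) on ties
        u_loc, v_loc = divmod(int(flat), idx.size)
        best_gain = gain[u_loc, v_loc]
        u, v = int(idx[u_loc]), int(idx[v_loc])
        if u > v:
            u, v = v, u
        current_q += best_gain
        # merge v into u
        e[u, :] += e[v, :]
        e[:, u] += e[:, v]
        e[v, :] = 0.0
        e[:, v] = 0.0
        a_frac[u] += a_frac[v]
        a_frac[v] = 0.0
        alive[v] = False
        labels[labels == v] = u
        if current_q > best_q + 1e-12:
            best_q = current_q
            best_labels = labels.copy()
    # relabel communities consecutively
    _, compact = np.unique(best_labels, return_inverse=True)
    return float(best_q), compact


def assortativity(G: BrainGraph) -> float:
    """Degree (binary) or strength (weighted) assortativity over all edges.

    Pearson correlation of endpoint degrees over every edge counted in both
    orientations; weighted graphs use node strengths with each edge term
    weighted by its connection weight (Leung-Chau). Raises
    UndefinedMetricError when the edge degree pairs are degenerate — every
    edge joining the same (unordered) degree pair, as in regular graphs and
    stars — since a correlation over a one-point distribution is vacuous.
    """
    a = G.adjacency
    i, j = np.nonzero(np.triu(a, k=1))
    if i.size == 0:
        raise UndefinedMetricError("assortativity undefined for an empty graph")
    if G.kind == "binary":
        deg = (a > 0).sum(axis=1).astype(float)
        ew = np.ones(i.size)
    else:
        deg = a.sum(axis=1)
        ew = a[i, j]
    pairs = {(min(p), max(p)) for p in zip(deg[i], deg[j])}
    if len(pairs) == 1:
        raise UndefinedMetricError(
            "assortativity undefined: every edge joins the same degree pair"
        )
    # both orientations: endpoints (x, y) and (y, x)
    x = np.concatenate([deg[i], deg[j]])
    y = np.concatenate([deg[j], deg[i]])
    w = np.concatenate([ew, ew])
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    vx = (w * (x - mx) ** 2).sum() / wsum
    my = (w * y).sum() / wsum
    vy = (w * (y - my) ** 2).sum() / wsum
    if vx <= 0 or vy <= 0:
        raise UndefinedMetricError(
            "assortativity undefined: zero degree variance over edge endpoints"
        )
    cov = (w * (x - mx) * (y - my)).sum() / wsum
    return float(cov / math.sqrt(vx * vy))


def hierarchy(G: BrainGraph) -> float:
    """Hierarchy exponent beta of the power law C(k) ~ k^(-beta).

    beta is minus the least-squares slope of log C_i on log k_i over nodes
    with binary degree >= 2 and positive clustering (weighted graphs pair
    the weighted C_i with the binary degree). Natural logs; the base cancels
    in the slope. Requires at least two eligible nodes with distinct degrees.
    """
    _, ci = clustering_coefficient(G)
    k = (G.adjacency > 0).sum(axis=1).astype(float)
    eligible = (k >= 2) & (ci > 0)
    if eligible.sum() < 2 or np.unique(k[eligible]).size < 2:
        raise UndefinedMetricError(
            "hierarchy undefined: need >= 2 eligible nodes with distinct degrees"
        )
    logk = np.log(k[eligible])
    logc = np.log(ci[eligible])
    slope = np.polyfit(logk, logc, 1)[0]
    return float(-slope)


def synchronization(G: BrainGraph) -> float:
    """Laplacian eigenratio lambda_2 / lambda_max (synchronizability).

    L = D - A with the (strength) degree diagonal. A disconnected graph has
    lambda_2 = 0 and raises UndefinedMetricError.
    """
    a = G.adjacency
    lap = np.diag(a.sum(axis=1)) - a
    eig = np.linalg.eigvalsh(lap)
    lam_max = eig[-1]
    if lam_max <= 0:
        raise UndefinedMetricError("synchronization undefined for an empty graph")
    lam2 = eig[1]
    if lam2 <= 1e-10 * lam_max:
        raise UndefinedMetricError("synchronization undefined: disconnected graph")
    return float(lam2 / lam_max)


def _betweenness_brandes(lengths: np.ndarray) -> np.ndarray:
    """Brandes accumulation on an undirected graph given a length matrix.

    Unweighted graphs (all lengths equal 1) use BFS; otherwise Dijkstra.
    Returns unnormalized betweenness over unordered pairs.
    """
    n = lengths.shape[0]
    nbrs = [np.flatnonzero(lengths[v] > 0) for v in range(n)]
    unweighted = np.all(lengths[lengths > 0] == 1.0) if np.any(lengths > 0) else True
    bc = np.zeros(n)
    for s in range(n):
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, np.inf)
        dist[s] = 0.0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        if unweighted:
            queue = [s]
            head = 0
            while head < len(queue):
                v = queue[head]
                head += 1
                order.append(v)
                for w in nbrs[v]:
                    if np.isinf(dist[w]):
                        dist[w] = dist[v] + 1
                        queue.append(int(w))
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
        else:
            seen = np.zeros(n, dtype=bool)
            heap: list[tuple[float, int]] = [(0.0, s)]
            while heap:
                dv, v = heapq.heappop(heap)
                if seen[v]:
                    continue
                seen[v] = True
                order.append(v)
                for w in nbrs[v]:
                    alt = dv + lengths[v, w]
                    if alt < dist[w] - 1e-14:
                        dist[w] = alt
                        sigma[w] = sigma[v]
                        preds[w] = [v]
                        heapq.heappush(heap, (alt, int(w)))
                    elif not seen[w] and abs(alt - dist[w]) <= 1e-14:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
        delta = np.zeros(n)
        for v in reversed(order):
            for p in preds[v]:
                delta[p] += sigma[p] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    return bc / 2.0  # each unordered pair counted from both endpoints


def nodal_centralities(
    G: BrainGraph,
    D: DistanceMatrix | None = None,
    normalized: bool = False,
) -> NodalMetrics:
    """Nodal degree/strength, efficiency and betweenness centrality.

    Degree is the edge count for binary graphs and the strength (summed
    weight) for weighted graphs. Nodal efficiency of i is the mean inverse
    distance from i to all other nodes. Betweenness uses Brandes'
    accumulation on reciprocal-weight lengths and is reported unnormalized
    unless ``normalized`` divides by (N-1)(N-2)/2.
    """
    a = G.adjacency
    n = G.n_nodes
    if D is None:
        D = shortest_paths(G)
    degree = (a > 0).sum(axis=1).astype(float) if G.kind == "binary" else a.sum(axis=1)
    neff = _inverse_distances(D.d).sum(axis=1) / max(n - 1, 1)
    bc = _betweenness_brandes(_length_matrix(G))
    if normalized and n > 2:
        bc = bc / ((n - 1) * (n - 2) / 2.0)
    return NodalMetrics(degree, neff, bc)


def global_metrics(G: BrainGraph) -> GlobalMetrics:
    """All eight global metrics for one graph; undefined entries become NaN."""
    D = shortest_paths(G)
    cp, _ = clustering_coefficient(G)
    lp = char_path_length(D)
    eloc, _ = efficiency_local(G)
    eg = efficiency_global(D)
    try:
        q, part = modularity(G)
    except ValueError:
        q, part = math.nan, None
    vals = {}
    for name, fn in (
        ("assortativity", assortativity),
        ("hierarchy", hierarchy),
        ("synchronization", synchronization),
    ):
        try:
            vals[name] = fn(G)
        except UndefinedMetricError:
            vals[name] = math.nan
    return GlobalMetrics(
        Cp=cp, Lp=lp, Eloc=eloc, Eg=eg, Q=q, partition=part, **vals
    )


def auc(thresholds: np.ndarray, values: np.ndarray) -> float:
    """Trapezoid-rule area under a metric-versus-threshold curve.

    Intervals touching a NaN or infinite metric value (an undefined-signal
    propagated from a metric) are skipped, with a warning reporting how many
    trapezoids were dropped.
    """
    x = np.asarray(thresholds, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("thresholds and values must have the same length")
    if x.size < 2:
        raise ValueError("need at least 2 thresholds for an AUC")
    if np.any(np.diff(x) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    ok = np.isfinite(y)
    pair_ok = ok[:-1] & ok[1:]
    skipped = int((~pair_ok).sum())
    if skipped:
        warnings.warn(f"AUC skipped {skipped} trapezoid(s) with undefined values",
                      stacklevel=2)
    dx = np.diff(x)[pair_ok]
    trap = ((y[:-1] + y[1:]) / 2.0)[pair_ok]
    return float((dx * trap).sum())


@dataclass(frozen=True)
class MetricCurve:
    """A metric swept over an ordered threshold list, with its AUC."""

    thresholds: tuple[float, ...]
    values: tuple[float, ...]
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "auc", auc(np.asarray(self.thresholds), np.asarray(self.values))
        )
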