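"""Independent reference implementations used to cross-check graph metrics.

Everything here goes through networkx (or explicit enumeration) rather than
the package's own code paths, so agreement is a genuine dual-route check.
"""

import itertools

import networkx as nx
import numpy as np

from netconnkit.graphs import BrainGraph


def to_nx(G: BrainGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(G.n_nodes))
    i, j = np.nonzero(np.triu(G.adjacency, k=1))
    for a, b in zip(i, j):
        w = G.adjacency[a, b]
        g.add_edge(int(a), int(b), weight=w, dist=1.0 / w)
    return g


def nx_distances(G: BrainGraph) -> np.ndarray:
    g = to_nx(G)
    n = G.n_nodes
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    weight = None if G.kind == "binary" else "dist"
    for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight=weight):
        for dst, val in lengths.items():
            d[src, dst] = val
    return d


def nx_char_path_length(G: BrainGraph) -> float:
    d = nx_distances(G)
    n = d.shape[0]
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    total = inv.sum()
    return n * (n - 1) / total if total > 0 else np.inf


def nx_global_efficiency(G: BrainGraph) -> float:
    d = nx_distances(G)
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d) & (d > 0)
    return float((1.0 / d[finite]).sum() / (n * (n - 1)))


def nx_local_efficiency(G: BrainGraph) -> np.ndarray:
    a = G.adjacency
    out = np.zeros(G.n_nodes)
    for i in range(G.n_nodes):
        nbrs = np.flatnonzero(a[i] > 0)
        if nbrs.size < 2:
            continue
        sub = BrainGraph(a[np.ix_(nbrs, nbrs)], G.kind, G.member)
        out[i] = nx_global_efficiency(sub)
    return out


def nx_clustering(G: BrainGraph) -> np.ndarray:
    g = to_nx(G)
    weight = None if G.kind == "binary" else "weight"
    vals = nx.clustering(g, weight=weight)
    return np.array([vals[k] for k in range(G.n_nodes)])


def nx_betweenness(G: BrainGraph) -> np.ndarray:
    g = to_nx(G)
    weight = None if G.kind == "binary" else "dist"
    vals = nx.betweenness_centrality(g, normalized=False, weight=weight)
    return np.array([vals[k] for k in range(G.n_nodes)])


def nx_modularity_q(G: BrainGraph, labels: np.ndarray) -> float:
    g = to_nx(G)
    communities = [
        {int(n) for n in np.flatnonzero(labels == lab)} for lab in np.unique(labels)
    ]
    return nx.community.modularity(g, communities, weight="weight")


def nx_assortativity(G: BrainGraph) -> float:
    """networkx degree assortativity (binary graphs only)."""
    return nx.degree_assortativity_coefficient(to_nx(G))


def weighted_assortativity_oracle(G: BrainGraph) -> float:
    """Direct Leung-Chau formula: edge-weight-weighted correlation of
    endpoint strengths over both edge orientations."""
    a = G.adjacency
    strength = a.sum(axis=1)
    i, j = np.nonzero(np.triu(a, k=1))
    x = np.concatenate([strength[i], strength[j]])
    y = np.concatenate([strength[j], strength[i]])
    w = np.concatenate([a[i, j], a[i, j]])
    H = w.sum()
    term1 = (w * x * y).sum() / H
    mean = ((w * (x + y) / 2).sum() / H) ** 2
    var = (w * (x**2 + y**2) / 2).sum() / H - mean
    return (term1 - mean) / var


def hierarchy_oracle(G: BrainGraph) -> float:
    ci = nx_clustering(G)
    k = (G.adjacency > 0).sum(axis=1).astype(float)
    mask = (k >= 2) & (ci > 0)
    logk, logc = np.log(k[mask]), np.log(ci[mask])
    slope = np.polyfit(logk, logc, 1)[0]
    return -slope


def laplacian_eigenratio_oracle(G: BrainGraph) -> float:
    g = to_nx(G)
    lap = nx.laplacian_matrix(g, weight="weight").toarray()
    eig = np.sort(np.linalg.eigvalsh(lap))
    return eig[1] / eig[-1]


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1 :]
        yield [[first]] + part


def exhaustive_best_modularity(G: BrainGraph) -> float:
    """Best Q over every partition of the node set (feasible for N <= 8)."""
    best = -np.inf
    nodes = list(range(G.n_nodes))
    from netconnkit.metrics import modularity_q

    for part in set_partitions(nodes):
        labels = np.empty(G.n_nodes, dtype=int)
        for c, block in enumerate(part):
            labels[block] = c
        best = max(best, modularity_q(G.adjacency, labels))
    return best


def random_graphs(n_graphs, max_nodes=7, seed=0, weighted_fraction=0.5):
    """Connected-or-not random test graphs, a mix of binary and weighted."""
    rng = np.random.default_rng(seed)
    graphs = []
    made = 0
    while made < n_graphs:
        n = int(rng.integers(3, max_nodes + 1))
        p = float(rng.uniform(0.2, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
        if g.number_of_edges() == 0:
            continue
        a = nx.to_numpy_array(g)
        if rng.uniform() < weighted_fraction:
            w = np.triu(rng.uniform(0.05, 1.0, size=(n, n)), k=1)
            a = a * (w + w.T)
            graphs.append(BrainGraph(a, "weighted"))
        else:
            graphs.append(BrainGraph(a, "binary"))
        made += 1
    return graphs


def atlas_graphs(max_nodes=5):
    """All non-isomorphic graphs with at most ``max_nodes`` nodes and >= 1 edge."""
    out = []
    for g in nx.graph_atlas_g():
        if 2 <= g.number_of_nodes() <= max_nodes and g.number_of_edges() >= 1:
            out.append(BrainGraph(nx.to_numpy_array(g), "binary"))
    return out


def small_world_pattern_counts(seed, n_replicates=20, M=20):
    """Replicated Watts-Strogatz vs degree-matched nulls: count replicates
    where gamma > 1 and sigma > 1 (and collect the full metric ratios)."""
    from netconnkit.graphs import BrainGraph as BG
    from netconnkit.nullmodels import build_ensemble, normalized_metrics

    wins = 0
    tables = []
    for rep in range(n_replicates):
        g = nx.watts_strogatz_graph(100, 6, 0.1, seed=seed + rep)
        graph = BG(nx.to_numpy_array(g), "binary")
        table = normalized_metrics(graph, build_ensemble(graph, M, seed + 1000 + rep))
        tables.append(table)
        gamma = table.loc["gamma", "ratio"]
        sigma = table.loc["sigma", "ratio"]
        if gamma > 1 and sigma > 1:
            wins += 1
    return wins, tables
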