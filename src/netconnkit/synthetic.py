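"""Seeded generators for synthetic inputs with known statistical structure.

The generators emulate the statistics the pipeline assumes about regional
recordings: a block (modular) spatial correlation structure, AR(1) temporal
autocorrelation, additive white noise and slow linear drift. They make every
module testable without any external data, and double as the input source
for the worked examples. Each generator is a pure function of its spec and
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.signal import lfilter

from .connectivity import pearson_matrix
from .graphs import BrainGraph
from .preprocess import BoldTimeSeries
from .stats import GroupDesign

__all__ = [
    "DEFAULT_SEED",
    "SynthSpec",
    "gen_modular_timeseries",
    "gen_group_dataset",
    "gen_toy_graphs",
]

DEFAULT_SEED = 20150630


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the modular multivariate signal generator.

    Defaults mirror a typical resting-state acquisition block: 200 time
    points at dt = 2 s over 20 regions in four equal modules, within-module
    correlation 0.6 against a 0.1 background, mild temporal autocorrelation
    (AR(1) phi = 0.3), measurement noise at 10% of signal SD, and no drift
    unless requested.
    """

    n_regions: int = 20
    n_timepoints: int = 200
    dt: float = 2.0
    block_sizes: tuple[int, ...] = (5, 5, 5, 5)
    rho_in: float = 0.6
    rho_out: float = 0.1
    ar_coeff: float = 0.3
    noise_sd: float = 0.1
    drift_amplitude: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if sum(self.block_sizes) != self.n_regions:
            raise ValueError("block sizes must sum to n_regions")
        if not 0 <= self.rho_out <= self.rho_in < 1:
            raise ValueError("need 0 <= rho_out <= rho_in < 1")
        if not -1 < self.ar_coeff < 1:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")

    def target_correlation(self) -> np.ndarray:
        """The block correlation matrix the generator aims at (unit diagonal)."""
        n = self.n_regions
        target = np.full((n, n), self.rho_out)
        start = 0
        for size in self.block_sizes:
            target[start : start + size, start : start + size] = self.rho_in
            start += size
        np.fill_diagonal(target, 1.0)
        return target


def _correlated_draws(
    target: np.ndarray, T: int, rng: np.random.Generator
) -> np.ndarray:
    try:
        chol = np.linalg.cholesky(target)
    except np.linalg.LinAlgError as exc:
        raise ValueError("target correlation matrix is not positive definite") from exc
    return rng.standard_normal((T, target.shape[0])) @ chol.T


def gen_modular_timeseries(spec: SynthSpec, seed: int | None = None) -> BoldTimeSeries:
    """Draw one T x N block with the spec's spatial and temporal structure.

    Spatially correlated Gaussian innovations (Cholesky of the block target)
    are colored by an identical AR(1) filter per column — which preserves
    the zero-lag cross-correlations — then white noise and an optional
    linear drift spanning [-amplitude, +amplitude] are added.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    x = _correlated_draws(spec.target_correlation(), spec.n_timepoints, rng)
    if spec.ar_coeff != 0:
        x = lfilter([1.0], [1.0, -spec.ar_coeff], x, axis=0)
        x *= np.sqrt(1.0 - spec.ar_coeff**2)  # restore unit stationary variance
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal(x.shape)
    if spec.drift_amplitude != 0:
        ramp = np.linspace(-1.0, 1.0, spec.n_timepoints)[:, None]
        x = x + spec.drift_amplitude * ramp
    return BoldTimeSeries(x, spec.dt)


def gen_group_dataset(
    spec: SynthSpec,
    n_per_group: int,
    effect_edges: tuple[tuple[int, int], ...] = (),
    delta_rho: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, GroupDesign]:
    """Two-group stack of subject connectivity matrices with a planted effect.

    Group 2's target correlations are raised by ``delta_rho`` on
    ``effect_edges`` (checked to keep the matrix positive definite); each
    subject is an independent time-series draw run through the Pearson
    estimator. Returns (subjects x N x N array, GroupDesign) with group 1
    first.
    """
    master = spec.seed if seed is None else seed
    target1 = spec.target_correlation()
    target2 = target1.copy()
    for i, j in effect_edges:
        if not (0 <= i < spec.n_regions and 0 <= j < spec.n_regions and i != j):
            raise ValueError(f"effect edge ({i}, {j}) out of range")
        target2[i, j] = target2[j, i] = target2[i, j] + delta_rho
    if np.any(np.abs(target2) > 1):
        raise ValueError("effect pushes a correlation outside [-1, 1]")
    try:
        np.linalg.cholesky(target2)
    except np.linalg.LinAlgError as exc:
        raise ValueError("effect breaks positive definiteness") from exc

    # spawned child streams: statistically independent across subjects AND
    # across nearby master seeds (a master+offset scheme would make
    # replicate datasets overlap almost entirely)
    children = np.random.SeedSequence(master).spawn(2 * n_per_group)
    mats = []
    for s in range(2 * n_per_group):
        rng = np.random.default_rng(children[s])
        target = target1 if s < n_per_group else target2
        x = _correlated_draws(target, spec.n_timepoints, rng)
        if spec.ar_coeff != 0:
            x = lfilter([1.0], [1.0, -spec.ar_coeff], x, axis=0)
            x *= np.sqrt(1.0 - spec.ar_coeff**2)
        if spec.noise_sd > 0:
            x = x + spec.noise_sd * rng.standard_normal(x.shape)
        mats.append(pearson_matrix(BoldTimeSeries(x, spec.dt)).r)
    design = GroupDesign(
        subject_ids=tuple(f"sub{s + 1:03d}" for s in range(2 * n_per_group)),
        groups=np.repeat([1, 2], n_per_group),
    )
    return np.stack(mats), design


@dataclass(frozen=True)
class ToyGraph:
    """A named deterministic fixture graph with its known metric values."""

    name: str
    graph: BrainGraph
    known: dict[str, object] = field(default_factory=dict)


def _from_nx(g: nx.Graph, kind: str = "binary") -> BrainGraph:
    a = nx.to_numpy_array(g, nodelist=sorted(g.nodes()))
    return BrainGraph((a > 0).astype(float) if kind == "binary" else a, kind)


def gen_toy_graphs(seed: int = DEFAULT_SEED) -> dict[str, ToyGraph]:
    """Deterministic fixture graphs with analytically known metric values.

    Includes complete graphs, a path, a star (with its exact betweenness and
    leaf efficiency), the (20, 4) ring lattice (Cp = 0.5), two K4 cliques
    bridged by one edge (known optimal modularity), and seeded
    Watts-Strogatz and Erdos-Renyi graphs that regenerate bit-identically.
    """
    fixtures = {}
    fixtures["K5"] = ToyGraph(
        "K5", _from_nx(nx.complete_graph(5)),
        {"Cp": 1.0, "Lp": 1.0, "Eg": 1.0, "Eloc": 1.0, "Q": 0.0,
         "betweenness": (0.0,) * 5, "synchronization": 1.0},
    )
    fixtures["P3"] = ToyGraph(
        "P3", _from_nx(nx.path_graph(3)),
        {"Lp": 1.2, "Eg": 5.0 / 6.0, "synchronization": 1.0 / 3.0},
    )
    fixtures["P4"] = ToyGraph("P4", _from_nx(nx.path_graph(4)), {})
    fixtures["star5"] = ToyGraph(
        "star5", _from_nx(nx.star_graph(4)),
        {"Cp": 0.0, "betweenness": (6.0, 0.0, 0.0, 0.0, 0.0),
         "center_efficiency": 1.0, "leaf_efficiency": 0.625, "Eloc": 0.0},
    )
    fixtures["ring_20_4"] = ToyGraph(
        "ring_20_4", _from_nx(nx.watts_strogatz_graph(20, 4, 0.0, seed=seed)),
        {"Cp": 0.5},
    )
    two_cliques = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    two_cliques.add_edge(0, 4)
    fixtures["bridged_cliques"] = ToyGraph(
        "bridged_cliques", _from_nx(two_cliques),
        {"Q_optimal": 12.0 / 13.0 - 0.5,
         "partition": (0, 0, 0, 0, 1, 1, 1, 1)},
    )
    fixtures["ws_100_6"] = ToyGraph(
        "ws_100_6", _from_nx(nx.watts_strogatz_graph(100, 6, 0.1, seed=seed)), {}
    )
    fixtures["er_30"] = ToyGraph(
        "er_30", _from_nx(nx.gnp_random_graph(30, 0.2, seed=seed)), {}
    )
    return fixtures
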