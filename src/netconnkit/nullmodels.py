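"""Degree-preserving null models and normalized (small-world) metrics.

Real networks are benchmarked against ensembles of Maslov-Sneppen rewired
graphs that keep the node count, edge count and exact degree sequence, and
against phase-randomized surrogate time series that keep each signal's
power spectrum while destroying its temporal structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import BrainGraph
from .metrics import GLOBAL_METRIC_NAMES, global_metrics
from .preprocess import BoldTimeSeries

__all__ = [
    "NullEnsemble",
    "rewire",
    "build_ensemble",
    "normalized_metrics",
    "phase_randomize",
]


@dataclass(frozen=True)
class NullEnsemble:
    """A reference graph with M degree-matched rewired surrogates."""

    reference: BrainGraph
    nulls: tuple[BrainGraph, ...]
    seed: int

    @property
    def size(self) -> int:
        return len(self.nulls)


def rewire(
    G: BrainGraph,
    seed: int | np.random.Generator,
    n_swaps: int | None = None,
    max_attempt_factor: int = 100,
) -> BrainGraph:
    """Degree-preserving double-edge-swap (Maslov-Sneppen) randomization.

    Repeatedly picks two edges (i1, j1), (i2, j2); when the crossed pairs
    (i1, j2) and (i2, j1) are absent and introduce no self-loop, the swap is
    applied. By default 2E *successful* swaps are performed (E = edge
    count), with an attempt cap of ``max_attempt_factor * E``; hitting the
    cap leaves the graph partially mixed and warns. Weighted graphs carry
    each weight with its moved edge, so the weight multiset is preserved
    but the strength sequence is not.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = G.adjacency.copy()
    edges = np.argwhere(np.triu(a, k=1) > 0)
    n_edges = len(edges)
    if n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    target = 2 * n_edges if n_swaps is None else n_swaps
    max_attempts = max_attempt_factor * n_edges
    done = 0
    attempts = 0
    while done < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, n_edges, size=2)
        if e1 == e2:
            continue
        i1, j1 = edges[e1]
        i2, j2 = edges[e2]
        if rng.integers(0, 2):  # random orientation of the second edge
            i2, j2 = j2, i2
        if i1 == j2 or i2 == j1:
            continue  # would create a self-loop
        if a[i1, j2] > 0 or a[i2, j1] > 0:
            continue  # would create a multi-edge
        w1, w2 = a[i1, j1], a[i2, j2]
        a[i1, j1] = a[j1, i1] = 0.0
        a[i2, j2] = a[j2, i2] = 0.0
        a[i1, j2] = a[j2, i1] = w1
        a[i2, j1] = a[j1, i2] = w2
        edges[e1] = sorted((i1, j2))
        edges[e2] = sorted((i2, j1))
        done += 1
    if done < target:
        warnings.warn(
            f"rewire reached the attempt cap after {done}/{target} swaps "
            "(graph too dense or too small to mix further)",
            stacklevel=2,
        )
    return BrainGraph(a, G.kind, G.member)


def build_ensemble(G: BrainGraph, M: int, seed: int) -> NullEnsemble:
    """M independent rewired nulls with per-null seeds = master seed + index."""
    if M < 1:
        raise ValueError("ensemble size must be >= 1")
    nulls = tuple(rewire(G, seed + k) for k in range(M))
    return NullEnsemble(G, nulls, seed)


def normalized_metrics(G: BrainGraph, ensemble: NullEnsemble) -> pd.DataFrame:
    """Real-versus-null summary for every global metric.

    Returns a table with the real value, null mean and SD, and the ratio
    real / null-mean per metric, plus the small-world rows: gamma (Cp
    ratio), lambda (Lp ratio) and sigma = gamma / lambda. Metrics undefined
    on some nulls are averaged over the nulls where they are defined.
    """
    real = global_metrics(G).as_dict()
    null_vals = {name: [] for name in GLOBAL_METRIC_NAMES}
    for null in ensemble.nulls:
        for name, val in global_metrics(null).as_dict().items():
            null_vals[name].append(val)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for name in GLOBAL_METRIC_NAMES:
            arr = np.asarray(null_vals[name], dtype=float)
            mean = float(np.nanmean(arr)) if np.isfinite(arr).any() else np.nan
            sd = float(np.nanstd(arr, ddof=1)) if np.isfinite(arr).sum() > 1 else np.nan
            ratio = real[name] / mean if np.isfinite(mean) and mean != 0 else np.nan
            rows.append((name, real[name], mean, sd, ratio))
    table = pd.DataFrame(
        rows, columns=["metric", "real", "null_mean", "null_sd", "ratio"]
    ).set_index("metric")
    gamma = table.loc["Cp", "ratio"]
    lam = table.loc["Lp", "ratio"]
    sigma = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam != 0 else np.nan
    for name, val in (("gamma", gamma), ("lambda", lam), ("sigma", sigma)):
        table.loc[name] = [np.nan, np.nan, np.nan, val]
    return table


def phase_randomize(
    ts: BoldTimeSeries,
    seed: int | np.random.Generator,
    mode: str = "independent",
) -> BoldTimeSeries:
    """Surrogate time series with the original per-column power spectrum.

    Each column's Fourier amplitudes are kept; phases of the non-DC,
    non-Nyquist bins are randomized. ``mode`` = "independent" replaces each
    column's phases with independent uniform draws (destroying cross-column
    correlation); ``mode`` = "common" rotates every column's phases by one
    shared uniform offset per bin, which keeps the relative phases and hence
    the zero-lag cross-correlation structure.
    """
    if ts.n_timepoints < 4:
        raise ValueError("need at least 4 time points for phase randomization")
    if mode not in ("independent", "common"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T, P = ts.data.shape
    spec = np.fft.rfft(ts.data, axis=0)
    n_bins = spec.shape[0]
    # bins 1..n_inner are free; DC (and Nyquist for even T) must stay real
    inner = slice(1, n_bins - 1 if T % 2 == 0 else n_bins)
    n_inner = (n_bins - 2) if T % 2 == 0 else (n_bins - 1)
    if mode == "common":
        offsets = rng.uniform(0, 2 * np.pi, size=(n_inner, 1))
        spec[inner] = spec[inner] * np.exp(1j * offsets)
    else:
        phases = rng.uniform(0, 2 * np.pi, size=(n_inner, P))
        spec[inner] = np.abs(spec[inner]) * np.exp(1j * phases)
    return BoldTimeSeries(np.fft.irfft(spec, n=T, axis=0), ts.dt)
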