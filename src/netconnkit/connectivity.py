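"""Connectivity representations: static, sliding-window and voxel-level.

Builds Pearson correlation matrices from time-series blocks, dynamic
matrix series over sliding windows, Fisher r-to-z group averages, and the
full family of voxel-wise degree-centrality maps (distance x sign x type).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .preprocess import BoldTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "DynamicConnectivitySeries",
    "VoxelDegreeMaps",
    "DISTANCE_CLASSES",
    "SIGN_CLASSES",
    "TYPE_CLASSES",
    "pearson_matrix",
    "sliding_window_matrices",
    "fisher_group_mean",
    "voxel_degree_maps",
    "strength_maps",
]

DISTANCE_CLASSES = ("short", "long", "full")
SIGN_CLASSES = ("positive", "negative", "absolute")
TYPE_CLASSES = ("binary", "weighted")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N x N correlation matrix with a zero diagonal."""

    r: np.ndarray
    node_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {r.shape}")
        if not np.all(np.isfinite(r)):
            raise ValueError("connectivity matrix contains non-finite values")
        if not np.allclose(r, r.T, atol=1e-12, rtol=0):
            raise ValueError("connectivity matrix not symmetric within 1e-12")
        if np.any(np.diag(r) != 0):
            raise ValueError("diagonal must be exactly zero")
        off = r[~np.eye(r.shape[0], dtype=bool)]
        if off.size and (off.min() < -1 or off.max() > 1):
            raise ValueError("off-diagonal entries must lie in [-1, 1]")
        names = tuple(self.node_names) if self.node_names else tuple(
            f"node{k + 1}" for k in range(r.shape[0])
        )
        if len(names) != r.shape[0]:
            raise ValueError("node_names length does not match matrix size")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "node_names", names)

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]


@dataclass(frozen=True)
class DynamicConnectivitySeries:
    """Ordered sliding-window correlation matrices with their window geometry."""

    matrices: tuple[ConnectivityMatrix, ...]
    window: int
    step: int
    starts: tuple[int, ...]

    @property
    def n_windows(self) -> int:
        return len(self.matrices)


@dataclass(frozen=True)
class VoxelDegreeMaps:
    """The 18 voxel-wise degree maps and the parameters that produced them.

    Keys of ``maps`` are (distance, sign, type) triples over
    {short, long, full} x {positive, negative, absolute} x {binary, weighted};
    each value is a length-P vector over the masked voxels.
    """

    maps: dict[tuple[str, str, str], np.ndarray]
    r_threshold: float
    d_threshold: float

    def __post_init__(self) -> None:
        expected = set(
            itertools.product(DISTANCE_CLASSES, SIGN_CLASSES, TYPE_CLASSES)
        )
        if set(self.maps) != expected:
            raise ValueError(
                f"expected {len(expected)} degree maps, got {len(self.maps)}"
            )

    @property
    def n_maps(self) -> int:
        return len(self.maps)


def _standardize(data: np.ndarray) -> np.ndarray:
    """Column-wise z-scoring; raises naming the first zero-variance column."""
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    # relative tolerance: a constant column's sd is rounding noise, not signal
    bad = np.flatnonzero(sd <= 1e-13 * (np.abs(mean) + 1.0))
    if bad.size:
        raise ValueError(f"zero-variance column at index {bad[0]}")
    return (data - mean) / sd


def pearson_matrix(ts: BoldTimeSeries, node_names: tuple[str, ...] = ()) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of all columns, diagonal forced to zero."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points for a correlation matrix")
    z = _standardize(ts.data)
    r = (z.T @ z) / ts.n_timepoints
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, node_names)


def sliding_window_matrices(
    ts: BoldTimeSeries, window: int, step: int
) -> DynamicConnectivitySeries:
    """One correlation matrix per sliding window of ``window`` points.

    Windows start at 0, step, 2*step, ... and must fit entirely inside the
    series; the number of windows is floor((T - W)/S) + 1.
    """
    T = ts.n_timepoints
    if not 3 <= window <= T:
        raise ValueError(f"window width {window} invalid for T={T}")
    if step < 1:
        raise ValueError("step must be >= 1")
    starts = tuple(range(0, T - window + 1, step))
    mats = tuple(
        pearson_matrix(BoldTimeSeries(ts.data[s : s + window], ts.dt))
        for s in starts
    )
    return DynamicConnectivitySeries(mats, window, step, starts)


def fisher_group_mean(mats: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Group-average correlation matrices through Fisher's r-to-z transform.

    Each matrix is mapped elementwise by atanh (after clipping |r| to
    1 - 1e-7 to keep the transform finite), averaged across subjects, and
    mapped back with tanh.
    """
    if not mats:
        raise ValueError("empty matrix list")
    n = mats[0].n_nodes
    for k, m in enumerate(mats):
        if m.n_nodes != n:
            raise ValueError(f"matrix {k} has {m.n_nodes} nodes, expected {n}")
    clip = 1.0 - 1e-7
    z = np.mean([np.arctanh(np.clip(m.r, -clip, clip)) for m in mats], axis=0)
    r = np.tanh(z)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, mats[0].node_names)


def voxel_degree_maps(
    ts: BoldTimeSeries,
    coords: np.ndarray,
    r_threshold: float,
    d_threshold: float,
    chunk_size: int = 2048,
) -> VoxelDegreeMaps:
    """All 18 voxel-wise degree-centrality maps in one pass.

    For voxel i, a peer j != i qualifies for a map keyed (distance, sign,
    type) when its Euclidean distance d_ij falls in the distance class
    (short: d <= d0; long: d > d0; full: any) and its correlation c_ij in
    the sign class (positive: c > r0; negative: c < -r0; absolute:
    |c| > r0; all strict). Binary maps count qualifying peers, weighted
    maps sum |c_ij| over them; the correlation matrix is traversed in row
    blocks of ``chunk_size`` so the P x P matrix never needs to be held
    whole, with results identical to the unchunked computation.
    """
    if not 0 <= r_threshold < 1:
        raise ValueError(f"correlation threshold {r_threshold} not in [0, 1)")
    if not d_threshold > 0:
        raise ValueError("distance threshold must be positive")
    coords = np.asarray(coords, dtype=float)
    P = ts.n_units
    if coords.shape != (P, 3):
        raise ValueError(
            f"coords shape {coords.shape} does not match {P} voxels (expected ({P}, 3))"
        )
    z = _standardize(ts.data)
    T = ts.n_timepoints

    acc = {
        key: np.zeros(P)
        for key in itertools.product(DISTANCE_CLASSES, SIGN_CLASSES, TYPE_CLASSES)
    }
    for lo in range(0, P, chunk_size):
        hi = min(lo + chunk_size, P)
        # row-wise products keep results bit-identical for any chunk size
        # (a blocked GEMM could re-associate the sums)
        c = np.stack([z[:, v] @ z for v in range(lo, hi)]) / T
        np.clip(c, -1.0, 1.0, out=c)
        d = np.linalg.norm(coords[lo:hi, None, :] - coords[None, :, :], axis=2)
        self_mask = np.zeros_like(c, dtype=bool)
        self_mask[np.arange(hi - lo), np.arange(lo, hi)] = True
        dist_masks = {
            "short": d <= d_threshold,
            "long": d > d_threshold,
            "full": np.ones_like(c, dtype=bool),
        }
        sign_masks = {
            "positive": c > r_threshold,
            "negative": c < -r_threshold,
            "absolute": np.abs(c) > r_threshold,
        }
        absc = np.abs(c)
        for dist_name, dmask in dist_masks.items():
            for sign_name, smask in sign_masks.items():
                qual = dmask & smask & ~self_mask
                acc[(dist_name, sign_name, "binary")][lo:hi] = qual.sum(axis=1)
                acc[(dist_name, sign_name, "weighted")][lo:hi] = np.where(
                    qual, absc, 0.0
                ).sum(axis=1)
    return VoxelDegreeMaps(acc, r_threshold, d_threshold)


def strength_maps(
    ts: BoldTimeSeries, r_threshold: float = 0.2
) -> dict[tuple[str, str], np.ndarray]:
    """The 6 voxel-wise connectivity-strength (degree centrality) maps.

    One map per network type x connectivity member combination —
    {binary, weighted} x {positive, negative, absolute} — i.e. the
    full-range slice of the degree-map family, with no distance split.
    """
    coords = np.zeros((ts.n_units, 3))  # distance split unused for full range
    full = voxel_degree_maps(ts, coords, r_threshold, d_threshold=1.0)
    return {
        (sign, kind): full.maps[("full", sign, kind)]
        for sign in SIGN_CLASSES
        for kind in TYPE_CLASSES
    }
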