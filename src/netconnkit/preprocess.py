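"""Temporal preprocessing of multivariate signal blocks.

Operations on BOLD-like time-series matrices (rows = time points, columns =
voxels or regions): removal of initial volumes, polynomial detrending, ideal
(FFT box) band-pass filtering and nuisance regression. Step order is
deliberately caller-controlled; the pipeline default is
remove -> detrend -> filter -> regress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoldTimeSeries",
    "ConfoundSet",
    "remove_volumes",
    "detrend",
    "ideal_bandpass",
    "expand_motion",
    "regress_confounds",
]


@dataclass(frozen=True)
class BoldTimeSeries:
    """A T x P sampled signal block with its sampling interval.

    Parameters
    ----------
    data : ndarray, shape (T, P)
        Signal values, time along rows. Units (columns) are voxels or regions.
    dt : float
        Sampling interval in seconds (the scanner's repetition time for fMRI).
    """

    data: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D (time x units), got ndim={data.ndim}")
        if data.shape[0] < 2:
            raise ValueError(f"need at least 2 time points, got {data.shape[0]}")
        if not np.all(np.isfinite(data)):
            raise ValueError("time series contains non-finite values")
        if not self.dt > 0:
            raise ValueError(f"sampling interval must be positive, got {self.dt}")
        object.__setattr__(self, "data", data)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist(self) -> float:
        """Highest representable frequency, 1/(2*dt), in Hz."""
        return 0.5 / self.dt


@dataclass(frozen=True)
class ConfoundSet:
    """Nuisance regressors aligned with a time-series block.

    ``regressors`` is T x K; ``labels`` names each column (e.g. motion1..6,
    their derivatives and squares, global/WM/CSF signals). Rank requirements
    are enforced at regression time, not at construction, so that degenerate
    but well-formed sets (e.g. an all-zero motion file) can still be built
    and inspected.
    """

    regressors: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        reg = np.asarray(self.regressors, dtype=float)
        if reg.ndim != 2:
            raise ValueError("regressors must be 2-D (time x confounds)")
        if not np.all(np.isfinite(reg)):
            raise ValueError("confound regressors contain non-finite values")
        labels = tuple(self.labels) if self.labels else tuple(
            f"confound{k + 1}" for k in range(reg.shape[1])
        )
        if len(labels) != reg.shape[1]:
            raise ValueError(
                f"{len(labels)} labels for {reg.shape[1]} regressor columns"
            )
        object.__setattr__(self, "regressors", reg)
        object.__setattr__(self, "labels", labels)

    @property
    def n_timepoints(self) -> int:
        return self.regressors.shape[0]

    @property
    def n_confounds(self) -> int:
        return self.regressors.shape[1]


def remove_volumes(
    ts: BoldTimeSeries,
    n_delete: int | None = None,
    n_retain: int | None = None,
) -> BoldTimeSeries:
    """Drop initial volumes acquired before magnetization equilibrium.

    Exactly one of ``n_delete`` (drop the first n rows) or ``n_retain``
    (keep the last n rows) must be given; the two modes coincide when
    n_retain = T - n_delete.
    """
    if (n_delete is None) == (n_retain is None):
        raise ValueError("give exactly one of n_delete or n_retain")
    T = ts.n_timepoints
    if n_delete is not None:
        if n_delete < 0 or n_delete >= T:
            raise ValueError(f"n_delete={n_delete} out of range for T={T}")
        kept = ts.data[n_delete:]
    else:
        if n_retain is None or n_retain < 2 or n_retain > T:
            raise ValueError(f"n_retain={n_retain} out of range for T={T}")
        kept = ts.data[T - n_retain:]
    if kept.shape[0] < 2:
        raise ValueError("fewer than 2 time points would remain")
    return BoldTimeSeries(kept.copy(), ts.dt)


def detrend(ts: BoldTimeSeries, order: int = 1) -> BoldTimeSeries:
    """Remove a least-squares polynomial trend of the given order per column.

    Order 0 removes the mean; order 1 additionally removes linear drift. The
    residual of each column is orthogonal to every monomial t^0 .. t^order.
    """
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    T = ts.n_timepoints
    if order >= T - 1:
        raise ValueError(f"order {order} too large for {T} time points")
    t = np.arange(T, dtype=float)
    # Vandermonde of normalized time; normalization only conditions the fit.
    basis = np.vander(2.0 * t / (T - 1) - 1.0, N=order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(basis, ts.data, rcond=None)
    return BoldTimeSeries(ts.data - basis @ coef, ts.dt)


def ideal_bandpass(ts: BoldTimeSeries, f_low: float, f_high: float) -> BoldTimeSeries:
    """Ideal (box) band-pass filter via the discrete Fourier transform.

    Each column is transformed with an FFT; bins whose exact frequency f
    satisfies f_low <= f <= f_high (closed band, no snapping) keep their
    amplitude, all others — including DC when f_low > 0 — are zeroed; the
    inverse transform is returned. Pass-band content on exact bins is
    untouched; stop-band content is annihilated.
    """
    nyq = ts.nyquist
    if not (0 <= f_low < f_high <= nyq + 1e-12):
        raise ValueError(
            f"band [{f_low}, {f_high}] invalid for Nyquist {nyq:.6g} Hz"
        )
    T = ts.n_timepoints
    spectrum = np.fft.rfft(ts.data, axis=0)
    freqs = np.fft.rfftfreq(T, d=ts.dt)
    keep = (freqs >= f_low) & (freqs <= f_high)
    spectrum[~keep] = 0.0
    return BoldTimeSeries(np.fft.irfft(spectrum, n=T, axis=0), ts.dt)


def expand_motion(motion: np.ndarray) -> ConfoundSet:
    """Expand 6 rigid-body motion parameters to the 24-parameter model.

    Output columns are [m, m^2, m_lag, m_lag^2] where m_lag is the one-step
    backward shift of each parameter, zero-padded in the first row (the
    backward-difference derivative convention enters through the lag terms).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must have exactly 6 columns, got shape {motion.shape}")
    lagged = np.zeros_like(motion)
    lagged[1:] = motion[:-1]
    block = np.hstack([motion, motion**2, lagged, lagged**2])
    labels = (
        [f"motion{k + 1}" for k in range(6)]
        + [f"motion{k + 1}_sq" for k in range(6)]
        + [f"motion{k + 1}_lag" for k in range(6)]
        + [f"motion{k + 1}_lag_sq" for k in range(6)]
    )
    return ConfoundSet(block, tuple(labels))


def regress_confounds(ts: BoldTimeSeries, conf: ConfoundSet) -> BoldTimeSeries:
    """Regress nuisance signals out of every column by ordinary least squares.

    The design matrix is [1 | regressors]; the returned columns are the OLS
    residuals, orthogonal to the intercept and to every confound column. An
    empty confound set therefore just demeans. Raises on a row-count mismatch
    or a rank-deficient design.
    """
    T = ts.n_timepoints
    if conf.n_timepoints != T:
        raise ValueError(
            f"confounds have {conf.n_timepoints} rows, time series has {T}"
        )
    design = np.column_stack([np.ones(T), conf.regressors])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient confound design (rank {rank} < {design.shape[1]} columns)"
        )
    coef, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    return BoldTimeSeries(ts.data - design @ coef, ts.dt)
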