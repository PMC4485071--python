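"""File formats: delimited text matrices and time series, plain .mat arrays,
NIfTI volumes/masks, degree-map output and design tables."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, VoxelDegreeMaps
from .preprocess import BoldTimeSeries
from .stats import GroupDesign

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_timeseries",
    "write_timeseries",
    "read_design",
    "load_nifti_timeseries",
    "write_degree_maps",
]


def _load_rectangular(path: str | Path) -> np.ndarray:
    """Load a whitespace-delimited numeric table, naming the first bad row."""
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                parsed = [float(tok) for tok in line.split()]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric cell on line {lineno}") from exc
            if rows and len(parsed) != len(rows[0]):
                raise ValueError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(parsed)} cells, expected {len(rows[0])})"
                )
            rows.append(parsed)
    if not rows:
        raise ValueError(f"{path}: empty file")
    return np.asarray(rows, dtype=float)


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    """Read an N x N connectivity matrix from text (or a plain numeric .mat).

    Asymmetry beyond 1e-6 is rejected with the offending entry's location;
    smaller asymmetry is symmetrized. A unit (correlation-convention)
    diagonal is accepted with a warning and zeroed.
    """
    path = Path(path)
    if path.suffix == ".mat":
        m = _load_mat_array(path)
    else:
        m = _load_rectangular(path)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got shape {m.shape}")
    delta = np.abs(m - m.T)
    if delta.max() > 1e-6:
        i, j = np.unravel_index(np.argmax(delta), delta.shape)
        raise ValueError(
            f"{path}: asymmetric beyond 1e-6 at ({i + 1}, {j + 1}): "
            f"{m[i, j]!r} vs {m[j, i]!r}"
        )
    m = (m + m.T) / 2.0
    diag = np.diag(m)
    if np.any(diag != 0):
        if np.allclose(diag, 1.0):
            warnings.warn(f"{path}: unit diagonal zeroed (correlation convention)",
                          stacklevel=2)
        else:
            warnings.warn(f"{path}: nonzero diagonal zeroed", stacklevel=2)
        np.fill_diagonal(m, 0.0)
    return ConnectivityMatrix(m)


def _load_mat_array(path: Path) -> np.ndarray:
    from scipy.io import loadmat

    contents = {k: v for k, v in loadmat(path).items() if not k.startswith("__")}
    arrays = [v for v in contents.values() if isinstance(v, np.ndarray)
              and v.dtype.kind in "fiu" and v.ndim == 2]
    if len(arrays) != 1:
        raise ValueError(
            f"{path}: expected exactly one plain numeric 2-D array, "
            f"found {len(arrays)}"
        )
    return arrays[0].astype(float)


def write_matrix(M: ConnectivityMatrix | np.ndarray, path: str | Path) -> None:
    """Write a matrix as whitespace-delimited text at full double precision."""
    arr = M.r if isinstance(M, ConnectivityMatrix) else np.asarray(M)
    np.savetxt(path, arr, fmt="%.17g")


def read_timeseries(path: str | Path, dt: float) -> BoldTimeSeries:
    """Read a T x P time-series block (rows = time points) from text."""
    return BoldTimeSeries(_load_rectangular(path), dt)


def write_timeseries(ts: BoldTimeSeries, path: str | Path) -> None:
    np.savetxt(path, ts.data, fmt="%.17g")


def read_design(path: str | Path) -> GroupDesign:
    """Read a delimited design table with a header (id, group, ...)."""
    df = pd.read_csv(path, sep=None, engine="python")
    return GroupDesign.from_frame(df)


def load_nifti_timeseries(
    img_path: str | Path, mask_path: str | Path
) -> tuple[BoldTimeSeries, np.ndarray]:
    """Masked voxels of a 4D NIfTI as columns, plus their world coordinates.

    Voxels are ordered by ascending linear index within the mask; the
    returned coords are voxel-center positions in mm from the image affine.
    The sampling interval is taken from the image header (pixdim[4]).
    """
    import nibabel as nib

    img = nib.load(str(img_path))
    mask = nib.load(str(mask_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{img_path}: expected 4D data, got {data.ndim}D")
    mask_arr = np.asanyarray(mask.dataobj) > 0
    if mask_arr.shape != data.shape[:3]:
        raise ValueError("mask shape does not match image volume")
    flat_idx = np.flatnonzero(mask_arr.ravel(order="C"))
    ijk = np.column_stack(np.unravel_index(flat_idx, mask_arr.shape))
    coords = nib.affines.apply_affine(img.affine, ijk)
    series = data.reshape(-1, data.shape[3], order="C")[flat_idx].T.astype(float)
    dt = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    if dt <= 0:
        dt = 1.0
    return BoldTimeSeries(series, dt), coords


def write_degree_maps(
    maps: VoxelDegreeMaps,
    mask_path: str | Path,
    out_dir: str | Path,
    summary_name: str = "degree_summary.tsv",
) -> list[Path]:
    """Write each of the 18 degree maps as a 3D NIfTI plus a summary table.

    Files are named ``degree_<distance>_<sign>_<type>.nii.gz``; the summary
    table reports per-map mean/min/max over the mask.
    """
    import nibabel as nib

    mask_img = nib.load(str(mask_path))
    mask_arr = np.asanyarray(mask_img.dataobj) > 0
    flat_idx = np.flatnonzero(mask_arr.ravel(order="C"))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    rows = []
    for (dist, sign, kind), values in sorted(maps.maps.items()):
        vol = np.zeros(mask_arr.size)
        vol[flat_idx] = values
        img = nib.Nifti1Image(
            vol.reshape(mask_arr.shape, order="C").astype(np.float32),
            mask_img.affine,
        )
        out = out_dir / f"degree_{dist}_{sign}_{kind}.nii.gz"
        nib.save(img, str(out))
        written.append(out)
        rows.append((dist, sign, kind, values.mean(), values.min(), values.max()))
    pd.DataFrame(
        rows, columns=["distance", "sign", "type", "mean", "min", "max"]
    ).to_csv(out_dir / summary_name, sep="\t", index=False)
    return written
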