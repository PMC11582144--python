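"""Loading and pre-processing of voxel time-series.

The pipeline currency is :class:`TimeSeriesMatrix`, a V x T matrix of voxel
time-series together with the sampling interval ``dt`` and a unit state.
Series typically come from a 4-D NIfTI volume restricted to a gray-matter
mask, or from a plain delimited table with one voxel per row.

Pre-processing mirrors what is commonly applied to stimulus-locked
high-temporal-resolution fMRI windows: a second-degree polynomial detrend,
percent scaling against a baseline (stimulus-omitted) run, and per-voxel
standardization before the series enter a classifier.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesMatrix",
    "BaselinePair",
    "load_dataset",
    "save_dataset",
    "detrend_poly",
    "percent_scale",
    "standardize",
    "decimate",
]

UNITS = ("raw", "percent", "standardized")


@dataclasses.dataclass
class TimeSeriesMatrix:
    """V x T matrix of voxel time-series with sampling metadata.

    Parameters
    ----------
    values : ndarray, shape (V, T)
        One row per voxel, one column per time point.
    dt : float
        Sampling interval in seconds (e.g. 0.075 for 75 ms effective TR).
    units : {"raw", "percent", "standardized"}
        Unit state of ``values``.
    voxel_ids : ndarray of int, shape (V,), optional
        Unique voxel identifiers; defaults to ``arange(V)``. For masked
        volumes these are ascending linear (C-order) voxel indices.
    spatial_index : ndarray of int, shape (V, 3), optional
        (x, y, z) grid coordinates per voxel, if known.
    """

    values: np.ndarray
    dt: float
    units: str = "raw"
    voxel_ids: np.ndarray | None = None
    spatial_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D (V, T), got shape {self.values.shape}")
        v, t = self.values.shape
        if t < 2:
            raise ValueError(f"need at least 2 time points, got T={t}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.units not in UNITS:
            raise ValueError(f"units must be one of {UNITS}, got {self.units!r}")
        if self.voxel_ids is None:
            self.voxel_ids = np.arange(v)
        else:
            self.voxel_ids = np.asarray(self.voxel_ids)
            if self.voxel_ids.shape != (v,):
                raise ValueError("voxel_ids length must equal the number of rows")
            if len(np.unique(self.voxel_ids)) != v:
                raise ValueError("voxel_ids must be unique")
        bad = ~np.isfinite(self.values)
        if bad.any():
            first = int(self.voxel_ids[np.argwhere(bad)[0, 0]])
            raise ValueError(f"non-finite value in time-series of voxel {first}")
        if self.units == "standardized":
            mu = self.values.mean(axis=1)
            sd = self.values.std(axis=1)
            if np.abs(mu).max() > 1e-8 or np.abs(sd - 1.0).max() > 1e-6:
                raise ValueError("units='standardized' but rows are not z-scored")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray, *, dt: float | None = None,
                  units: str | None = None) -> "TimeSeriesMatrix":
        return TimeSeriesMatrix(
            values=values,
            dt=self.dt if dt is None else dt,
            units=self.units if units is None else units,
            voxel_ids=self.voxel_ids.copy(),
            spatial_index=None if self.spatial_index is None else self.spatial_index.copy(),
        )


@dataclasses.dataclass
class BaselinePair:
    """Matched stimulus/baseline runs for percent scaling.

    The baseline run is the repeat where the stimulus was omitted; its
    per-voxel mean estimates the resting signal level.
    """

    stimulus: TimeSeriesMatrix
    baseline: TimeSeriesMatrix

    def __post_init__(self) -> None:
        s, b = self.stimulus, self.baseline
        if s.values.shape != b.values.shape:
            raise ValueError("stimulus and baseline must have identical shape")
        if s.dt != b.dt:
            raise ValueError("stimulus and baseline must share dt")
        if not np.array_equal(s.voxel_ids, b.voxel_ids):
            raise ValueError("stimulus and baseline voxel_ids must match in order")


def load_dataset(path: str | Path, mask: str | Path | None = None,
                 dt: float = 0.075) -> TimeSeriesMatrix:
    """Load a V x T time-series matrix from a 4-D NIfTI volume or a table.

    For NIfTI input, an optional 3-D mask restricts the voxels (mask > 0);
    rows follow the ascending linear (C-order) index of the masked volume.
    Delimited input (CSV/TSV, no header) is read as one voxel per row.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"expected a 4-D NIfTI volume, got {data.ndim}-D")
        grid = data.shape[:3]
        flat = data.reshape(-1, data.shape[3])
        if mask is not None:
            mimg = nib.load(str(Path(mask)))
            mdata = np.asarray(mimg.dataobj, dtype=float)
            if mdata.shape != grid:
                raise ValueError(
                    f"mask grid {mdata.shape} does not match data grid {grid}")
            keep = np.flatnonzero(mdata.reshape(-1) > 0)
        else:
            keep = np.arange(flat.shape[0])
        coords = np.stack(np.unravel_index(keep, grid), axis=1)
        return TimeSeriesMatrix(values=flat[keep], dt=dt, units="raw",
                                voxel_ids=keep, spatial_index=coords)
    table = pd.read_csv(path, sep=None, engine="python", header=None)
    return TimeSeriesMatrix(values=table.to_numpy(dtype=float), dt=dt, units="raw")


def save_dataset(m: TimeSeriesMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write the matrix as a delimited table plus a JSON sidecar (dt, units)."""
    path = Path(path)
    np.savetxt(path, m.values, delimiter=sep)
    sidecar = {
        "dt": m.dt,
        "units": m.units,
        "n_voxels": m.n_voxels,
        "n_timepoints": m.n_timepoints,
        "voxel_ids": [int(i) for i in m.voxel_ids],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def detrend_poly(m: TimeSeriesMatrix, degree: int = 2) -> TimeSeriesMatrix:
    """Subtract each row's least-squares polynomial fit of the given degree.

    Removes slow scanner drifts; ``degree=0`` reduces to mean-centering.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    t = m.n_timepoints
    if t <= degree + 1:
        raise ValueError(
            f"underdetermined fit: T={t} <= degree+1={degree + 1}")
    x = np.arange(t, dtype=float)
    design = np.polynomial.polynomial.polyvander(x, degree)  # (T, degree+1)
    coef, *_ = np.linalg.lstsq(design, m.values.T, rcond=None)
    fitted = design @ coef
    return m.copy_with(m.values - fitted.T)


def percent_scale(pair: BaselinePair) -> TimeSeriesMatrix:
    """Scale the stimulus run to percent signal change of the baseline mean.

    Row v becomes ``100 * (stim_v - mean(base_v)) / mean(base_v)``.
    """
    base_mean = pair.baseline.values.mean(axis=1)
    hazard = np.abs(base_mean) <= 1e-12
    if hazard.any():
        ids = pair.baseline.voxel_ids[hazard].tolist()
        raise ZeroDivisionError(
            f"baseline mean within 1e-12 of zero for voxels {ids}")
    scaled = 100.0 * (pair.stimulus.values - base_mean[:, None]) / base_mean[:, None]
    return pair.stimulus.copy_with(scaled, units="percent")


def standardize(m: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Z-score each row to zero mean and unit population (1/T) standard deviation."""
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, keepdims=True)
    degenerate = sd[:, 0] <= 0
    if degenerate.any():
        ids = m.voxel_ids[degenerate].tolist()
        raise ValueError(f"constant time-series cannot be standardized: voxels {ids}")
    return m.copy_with((m.values - mu) / sd, units="standardized")


def decimate(m: TimeSeriesMatrix, d: int) -> TimeSeriesMatrix:
    """Temporal downsampling by sample dropping: keep samples 0, d, 2d, ...

    No anti-alias filter is applied, so per-sample noise statistics are
    preserved (the autocorrelation-variance heuristic used to adapt the lag
    count assumes this). ``dt`` grows to ``d * dt`` and T to ``ceil(T/d)``.
    """
    d = int(d)
    if d < 1:
        raise ValueError("d must be a positive integer")
    if d >= m.n_timepoints:
        raise ValueError(f"d={d} >= T={m.n_timepoints} would leave < 2 samples")
    vals = m.values[:, ::d]
    units = m.units
    if units == "standardized":
        # subsampled rows are no longer exactly z-scored
        units = "raw"
    return m.copy_with(np.ascontiguousarray(vals), dt=m.dt * d, units=units)
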