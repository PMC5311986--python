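"""In-scope fMRI preprocessing: dummy-volume dropping, atlas ROI extraction,
linear detrending and temporal z-scoring.

Upstream corrections (slice timing, motion, spatial normalization, nuisance
regression) are delegated to standard neuroimaging tools and are expected to
have been applied before data reach this module.

The fixed stage order is: drop volumes -> extract ROI series -> detrend ->
z-score.  Detrending and normalization operate on ROI-averaged series by
default; because both are linear, applying them per voxel before averaging
differs only marginally, and the ROI-level order minimizes compute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .core import TimeSeries

__all__ = [
    "ROIMatrix",
    "drop_initial_volumes",
    "detrend_linear",
    "zscore",
    "extract_roi_series",
    "preprocess_matrix",
]


@dataclass
class ROIMatrix:
    """ROI-by-time matrix with sampling frequency and atlas labels.

    ``data`` has one row per ROI, ordered as ``roi_ids``.
    """

    data: np.ndarray
    fs: float
    roi_ids: list[int]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ROIMatrix data must be 2-D (ROIs x timepoints)")
        if self.data.shape[0] != len(self.roi_ids):
            raise ValueError("row count must equal number of roi_ids")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def to_series(self) -> list[TimeSeries]:
        return [TimeSeries(self.data[i], fs=self.fs, id=str(rid))
                for i, rid in enumerate(self.roi_ids)]


def drop_initial_volumes(data, n_drop: int):
    """Remove the first ``n_drop`` time points (non-equilibrium dummy scans).

    Accepts an :class:`ROIMatrix` (time along columns) or a 4-D array /
    NIfTI image (time along the last axis); returns the same type.
    """
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")

    if isinstance(data, ROIMatrix):
        if n_drop >= data.n_timepoints:
            raise ValueError(
                f"cannot drop {n_drop} of {data.n_timepoints} time points")
        return ROIMatrix(data.data[:, n_drop:], fs=data.fs, roi_ids=list(data.roi_ids))

    arr, img = _as_volume(data)
    if n_drop >= arr.shape[-1]:
        raise ValueError(f"cannot drop {n_drop} of {arr.shape[-1]} volumes")
    out = arr[..., n_drop:]
    if img is not None:
        import nibabel as nib
        return nib.Nifti1Image(out, img.affine, img.header)
    return out


def detrend_linear(x):
    """Remove the least-squares linear trend (intercept + slope).

    The output is orthogonal to both the constant and the linear ramp.
    Constant input yields zeros.  Accepts a vector or :class:`TimeSeries`.
    """
    if isinstance(x, TimeSeries):
        return TimeSeries(detrend_linear(x.values), fs=x.fs, id=x.id)
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to detrend")
    return scipy.signal.detrend(x, type="linear")


def zscore(x):
    """Temporal standardization: subtract the mean, divide by the SD.

    Uses the population standard deviation (ddof=0).  Zero-variance input is
    an error because the normalized series would be undefined.
    """
    if isinstance(x, TimeSeries):
        return TimeSeries(zscore(x.values), fs=x.fs, id=x.id)
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance series cannot be z-scored")
    return (x - x.mean()) / sd


def _as_volume(data):
    """Return (ndarray, nibabel image or None) for array/NIfTI input."""
    if hasattr(data, "get_fdata"):
        return np.asarray(data.get_fdata()), data
    return np.asarray(data, dtype=float), None


def extract_roi_series(volume, atlas, roi_ids: list[int], fs: float = 0.5) -> ROIMatrix:
    """Average voxel time courses within each atlas parcel.

    Parameters
    ----------
    volume : 4-D array or NIfTI image
        Functional data, time along the last axis.
    atlas : 3-D integer array or NIfTI image
        Parcellation on the same spatial grid; 0 is background.
    roi_ids : list of int
        Atlas labels to extract, in the desired output row order
        (e.g. AAL 1..90).
    """
    vol, _ = _as_volume(volume)
    atl, _ = _as_volume(atlas)
    atl = np.rint(atl).astype(int)
    if vol.ndim != 4:
        raise ValueError("volume must be 4-D")
    if atl.shape != vol.shape[:3]:
        raise ValueError(
            f"atlas grid {atl.shape} does not match volume grid {vol.shape[:3]}")
    if np.any(atl < 0):
        raise ValueError("atlas labels must be non-negative (0 = background)")

    rows = []
    for label in roi_ids:
        mask = atl == label
        if not mask.any():
            raise ValueError(f"atlas label {label} not present in atlas")
        rows.append(vol[mask].mean(axis=0))
    return ROIMatrix(np.vstack(rows), fs=fs, roi_ids=list(roi_ids))


def preprocess_matrix(mat: ROIMatrix, n_drop: int = 0) -> ROIMatrix:
    """Apply the fixed pipeline order to an ROI matrix: drop, detrend, z-score."""
    if n_drop:
        mat = drop_initial_volumes(mat, n_drop)
    out = np.empty_like(mat.data)
    for i in range(mat.n_rois):
        row = mat.data[i]
        if np.all(row == row[0]):
            raise ValueError(
                f"ROI {mat.roi_ids[i]}: constant series cannot be z-scored")
        try:
            out[i] = zscore(detrend_linear(row))
        except ValueError as exc:
            raise ValueError(f"ROI {mat.roi_ids[i]}: {exc}") from exc
    return ROIMatrix(out, fs=mat.fs, roi_ids=list(mat.roi_ids))
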