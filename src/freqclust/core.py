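"""Core containers shared across the pipeline.

A :class:`TimeSeries` is the unit every transform consumes: one ROI's BOLD
signal with its sampling frequency ``fs = 1/TR`` in Hz.  A
:class:`SubjectDataset` bundles one series per ROI for a single subject,
optionally carrying planted ground-truth cluster labels when the data are
synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries", "SubjectDataset"]

MIN_SERIES_LENGTH = 8


@dataclass
class TimeSeries:
    """One sampled signal.

    Parameters
    ----------
    values : array-like of float
        Signal samples, arbitrary units.
    fs : float
        Sampling frequency in Hz (for fMRI, ``1/TR``).
    id : str
        Opaque label, e.g. an ROI name or atlas index.
    """

    values: np.ndarray
    fs: float
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if self.values.size < MIN_SERIES_LENGTH:
            raise ValueError(
                f"TimeSeries needs at least {MIN_SERIES_LENGTH} samples, "
                f"got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TimeSeries values must be finite")
        if not self.fs > 0:
            raise ValueError("sampling frequency must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.values.size) / self.fs


@dataclass
class SubjectDataset:
    """Per-subject collection of ROI time series.

    All series must share length and sampling frequency.
    ``ground_truth_labels`` (1-based integers, one per ROI) is only present
    for synthetic data with planted cluster structure.
    """

    series: list[TimeSeries]
    subject_id: str = ""
    ground_truth_labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("SubjectDataset needs at least one series")
        n0, fs0 = self.series[0].n, self.series[0].fs
        for s in self.series:
            if s.n != n0 or s.fs != fs0:
                raise ValueError("all series must share length and fs")
        if self.ground_truth_labels is not None:
            labels = np.asarray(self.ground_truth_labels, dtype=int)
            if labels.size != len(self.series):
                raise ValueError("one ground-truth label per ROI required")
            if labels.min() < 1:
                raise ValueError("ground-truth labels must be >= 1")
            self.ground_truth_labels = labels

    @property
    def n_rois(self) -> int:
        return len(self.series)

    @property
    def fs(self) -> float:
        return self.series[0].fs

    def as_matrix(self) -> np.ndarray:
        """ROIs x timepoints matrix of the raw values."""
        return np.vstack([s.values for s in self.series])
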