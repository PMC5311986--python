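"""Synthetic BOLD-like signal generation.

Real resting-state BOLD series are short (140-220 samples at TR = 2 s) and
dominated by low-frequency power.  The generators here emulate that at the
spectrum level only — no hemodynamic or neuronal forward model — so that
every downstream stage (decomposition, instantaneous-frequency features,
clustering, label alignment) can be exercised with known ground truth.

Band-limited components are produced by spectral masking: white Gaussian
noise is transformed, bins outside the requested band are zeroed, and the
result is inverse-transformed.  This gives exact band control with no
filter-design ringing to tune.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TimeSeries, SubjectDataset

__all__ = [
    "gen_oscillation",
    "gen_bold_like",
    "gen_multisubject",
    "white_noise_series",
    "write_dataset",
    "read_dataset",
]

#: Default fixture length: a 225-volume acquisition minus five dummy volumes.
DEFAULT_N = 220
#: Default sampling frequency for TR = 2 s.
DEFAULT_FS = 0.5


def gen_oscillation(
    freq: float,
    amp: float = 1.0,
    n: int = DEFAULT_N,
    fs: float = DEFAULT_FS,
    phase: float = 0.0,
    seed: int | None = None,
) -> TimeSeries:
    """Pure cosine probe ``amp * cos(2*pi*freq*t + phase)``.

    Deterministic; ``seed`` is accepted for interface uniformity and ignored.
    Raises if ``freq`` is at or above the Nyquist frequency ``fs/2``.
    """
    if freq < 0:
        raise ValueError("frequency must be non-negative")
    if freq >= fs / 2:
        raise ValueError(
            f"frequency {freq} Hz at or above Nyquist ({fs / 2} Hz): "
            "the sampled tone would alias"
        )
    t = np.arange(n) / fs
    return TimeSeries(amp * np.cos(2 * np.pi * freq * t + phase), fs=fs, id=f"osc_{freq}Hz")


def _band_noise(rng: np.random.Generator, n: int, fs: float, low: float, high: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise via spectral masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < low) | (freqs > high)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:  # band so narrow no bin survived
        raise ValueError(f"band ({low}, {high}) Hz contains no spectral bin at n={n}, fs={fs}")
    return x / sd


def gen_bold_like(
    n: int = DEFAULT_N,
    fs: float = DEFAULT_FS,
    band_weights: list[tuple[float, float, float]] | None = None,
    seed: int | np.random.Generator = 0,
    id: str = "",
) -> TimeSeries:
    """BOLD-like series: weighted sum of band-limited noise, z-scored.

    Parameters
    ----------
    band_weights : list of (low_hz, high_hz, relative_power)
        Each component contributes band-limited Gaussian noise with variance
        proportional to ``relative_power``.  Defaults straddle the low- and
        mid-frequency bands typical of resting-state BOLD.
    seed : int or numpy Generator
        Reproducibility handle; the same seed yields the identical series.
    """
    if band_weights is None:
        band_weights = [(0.01, 0.03, 1.0), (0.03, 0.08, 0.6), (0.08, 0.2, 0.3)]
    if not band_weights:
        raise ValueError("band_weights must contain at least one band")
    weights = np.array([w for _, _, w in band_weights], dtype=float)
    if np.any(weights < 0):
        raise ValueError("band weights must be non-negative")
    if not np.any(weights > 0):
        raise ValueError("at least one band weight must be positive")
    for low, high, _ in band_weights:
        if not (0 < low < high < fs / 2 + 1e-12):
            raise ValueError(f"band ({low}, {high}) Hz must lie within (0, fs/2)")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.zeros(n)
    for low, high, w in band_weights:
        if w > 0:
            x += np.sqrt(w) * _band_noise(rng, n, fs, low, high)
    x = (x - x.mean()) / x.std()
    return TimeSeries(x, fs=fs, id=id or "bold_like")


def white_noise_series(n: int = DEFAULT_N, fs: float = DEFAULT_FS, seed: int = 0) -> TimeSeries:
    """White Gaussian noise probe used for decomposition ensemble studies."""
    rng = np.random.default_rng(seed)
    return TimeSeries(rng.standard_normal(n), fs=fs, id=f"wgn_{seed}")


def gen_multisubject(
    n_subjects: int,
    n_rois: int,
    cluster_spec: list[tuple[list[int], list[tuple[float, float, float]]]],
    n: int = DEFAULT_N,
    fs: float = DEFAULT_FS,
    seed: int = 0,
) -> list[SubjectDataset]:
    """Multi-subject datasets with planted spectral cluster structure.

    ``cluster_spec`` maps groups of 1-based ROI indices to band weights; the
    index sets must partition ``1..n_rois``.  ROIs in a group share band
    weights but receive independent noise realizations.  Ground-truth labels
    record the (1-based) group index of each ROI.

    Random streams are derived per subject and per ROI from the master seed,
    so adding subjects leaves earlier subjects' data unchanged.
    """
    seen: set[int] = set()
    for rois, _ in cluster_spec:
        s = set(rois)
        if s & seen:
            raise ValueError(f"overlapping ROI groups: indices {sorted(s & seen)} repeated")
        seen |= s
    if seen != set(range(1, n_rois + 1)):
        missing = sorted(set(range(1, n_rois + 1)) - seen)
        extra = sorted(seen - set(range(1, n_rois + 1)))
        raise ValueError(
            f"ROI groups must partition 1..{n_rois}; missing {missing}, out-of-range {extra}"
        )

    roi_group = {}
    roi_bands = {}
    for g, (rois, bands) in enumerate(cluster_spec, start=1):
        for r in rois:
            roi_group[r] = g
            roi_bands[r] = bands

    labels = np.array([roi_group[r] for r in range(1, n_rois + 1)])
    datasets = []
    for s_idx in range(n_subjects):
        series = []
        for r in range(1, n_rois + 1):
            rng = np.random.default_rng(np.random.SeedSequence([seed, s_idx, r]))
            ts = gen_bold_like(n=n, fs=fs, band_weights=roi_bands[r], seed=rng, id=f"roi{r:03d}")
            series.append(ts)
        datasets.append(
            SubjectDataset(series=series, subject_id=f"sub{s_idx + 1:03d}",
                           ground_truth_labels=labels.copy())
        )
    return datasets


def write_dataset(dataset: SubjectDataset, out_dir: str | Path, seed: int | None = None) -> Path:
    """Write one subject as CSV (rows = ROIs) plus a JSON sidecar.

    The CSV header row holds sample indices; the first column holds ROI ids.
    The sidecar records fs, ground-truth labels (if any) and the seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat = dataset.as_matrix()
    df = pd.DataFrame(mat, index=[s.id or f"roi{i + 1:03d}" for i, s in enumerate(dataset.series)],
                      columns=np.arange(mat.shape[1]))
    df.index.name = "roi_id"
    csv_path = out_dir / f"{dataset.subject_id or 'subject'}.csv"
    df.to_csv(csv_path)
    sidecar = {
        "fs": dataset.fs,
        "seed": seed,
        "ground_truth_labels": (
            None if dataset.ground_truth_labels is None
            else [int(v) for v in dataset.ground_truth_labels]
        ),
    }
    (csv_path.with_suffix(".json")).write_text(json.dumps(sidecar, indent=2))
    return csv_path


def read_dataset(csv_path: str | Path) -> SubjectDataset:
    """Read a subject written by :func:`write_dataset`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, index_col=0)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    fs = float(sidecar["fs"])
    series = [TimeSeries(row.to_numpy(dtype=float), fs=fs, id=str(rid))
              for rid, row in df.iterrows()]
    gt = sidecar.get("ground_truth_labels")
    return SubjectDataset(
        series=series,
        subject_id=csv_path.stem,
        ground_truth_labels=None if gt is None else np.asarray(gt, dtype=int),
    )
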