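"""Empirical mode decomposition (EMD) by the sifting algorithm.

EMD decomposes a signal into a finite set of intrinsic mode functions
(IMFs) plus a monotonic residue,

    x(t) = sum_i IMF_i(t) + r(t),

with the IMFs extracted in descending-frequency order.  An IMF must
(1) have numbers of local extrema and zero crossings that are equal or
differ by at most one, and (2) have a locally zero mean, i.e. the mean of
its upper (maxima-interpolating) and lower (minima-interpolating) envelopes
is everywhere close to zero.

Sifting iterates: find extrema, interpolate cubic-spline envelopes through
the maxima and minima, subtract the envelope mean, and repeat on the result
until the IMF conditions hold or a Cauchy-style step criterion

    SD = sum (h_prev - h)^2 / sum h_prev^2 < sd_threshold

is met.  Each accepted IMF is subtracted from the running residue and the
procedure repeats until the residue is monotonic (too few extrema to
envelope).  The decomposition is complete by construction: the IMFs and the
final residue sum back to the input up to floating-point rounding.

Boundary handling mirrors the two extrema nearest each end across the end
sample before spline fitting; this suppresses the envelope end-swings that
otherwise corrupt the low-frequency modes of short (~200-sample) series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .core import TimeSeries

__all__ = [
    "SiftConfig",
    "IMFSet",
    "find_extrema",
    "envelope_mean",
    "is_imf",
    "sift",
    "decompose",
    "MonotonicSignalError",
]


class MonotonicSignalError(ValueError):
    """Raised when a signal has too few extrema to build envelopes."""


@dataclass
class SiftConfig:
    """Stopping-rule constants for sifting.

    max_sift_iters : hard cap on sifting iterations per IMF.
    sd_threshold : Cauchy step criterion; iteration stops when the relative
        squared change between successive siftings falls below it.
    max_imfs : safety cap on the number of extracted IMFs (never binding for
        BOLD-length series).
    envelope_tolerance : the mean envelope is "zero" when its maximum
        magnitude is below this fraction of the candidate's SD.
    """

    max_sift_iters: int = 100
    sd_threshold: float = 0.2
    max_imfs: int = 12
    envelope_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if not (self.max_sift_iters > 0 and self.sd_threshold > 0
                and self.max_imfs > 0 and self.envelope_tolerance > 0):
            raise ValueError("all SiftConfig fields must be positive")


@dataclass
class IMFSet:
    """Ordered IMFs (first = highest frequency) plus the monotonic residue."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    fs: float
    source: np.ndarray = field(repr=False, default=None)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    @property
    def source_length(self) -> int:
        return self.residue.size

    def reconstruct(self) -> np.ndarray:
        """Sum of IMFs and residue; equals the input up to rounding."""
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def _run_length_encode(x: np.ndarray):
    """Starts and values of maximal runs of equal consecutive samples."""
    change = np.flatnonzero(np.diff(x) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [x.size - 1]))
    return starts, ends, x[starts]


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima.

    A flat plateau that is higher (lower) than both neighbouring runs counts
    as one maximum (minimum) at the plateau's midpoint index.  Endpoints are
    never extrema.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    starts, ends, vals = _run_length_encode(x)
    maxima, minima = [], []
    for j in range(1, len(vals) - 1):
        mid = (starts[j] + ends[j]) // 2
        if vals[j] > vals[j - 1] and vals[j] > vals[j + 1]:
            maxima.append(mid)
        elif vals[j] < vals[j - 1] and vals[j] < vals[j + 1]:
            minima.append(mid)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _mirror_knots(idx: np.ndarray, val: np.ndarray, n: int):
    """Extend extrema by mirroring the two nearest across each end."""
    k = min(2, idx.size)
    left_i = -idx[:k][::-1]
    left_v = val[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    right_v = val[-k:][::-1]
    all_i = np.concatenate([left_i, idx, right_i])
    all_v = np.concatenate([left_v, val, right_v])
    # mirroring can duplicate knots when an extremum sits at index 0 offset
    all_i, keep = np.unique(all_i, return_index=True)
    return all_i, all_v[keep]


def envelope_mean(x: np.ndarray) -> np.ndarray:
    """Mean of the cubic-spline upper and lower envelopes, per sample.

    Raises :class:`MonotonicSignalError` when fewer than two maxima or two
    minima exist — the caller treats the signal as (near-)monotonic.
    """
    x = np.asarray(x, dtype=float)
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise MonotonicSignalError(
            f"need >= 2 maxima and >= 2 minima, found {maxima.size}/{minima.size}")
    n = x.size
    t = np.arange(n)
    up_i, up_v = _mirror_knots(maxima, x[maxima], n)
    lo_i, lo_v = _mirror_knots(minima, x[minima], n)
    e_up = CubicSpline(up_i, up_v)(t)
    e_lo = CubicSpline(lo_i, lo_v)(t)
    return (e_up + e_lo) / 2.0


def _count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]  # exact zeros join the neighbouring sign
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def is_imf(x: np.ndarray, envelope_tolerance: float = 0.05) -> bool:
    """Test the two IMF conditions.

    True iff the extrema and zero-crossing counts differ by at most one and
    the mean envelope magnitude stays below ``envelope_tolerance`` times the
    signal SD.
    """
    x = np.asarray(x, dtype=float)
    try:
        maxima, minima = find_extrema(x)
    except ValueError:
        return False
    n_ext = maxima.size + minima.size
    n_zc = _count_zero_crossings(x)
    if abs(n_ext - n_zc) > 1:
        return False
    sd = x.std()
    if sd == 0:
        return False
    try:
        e_mean = envelope_mean(x)
    except MonotonicSignalError:
        return False
    return bool(np.max(np.abs(e_mean)) <= envelope_tolerance * sd)


def sift(x: np.ndarray, config: SiftConfig | None = None) -> np.ndarray:
    """Extract one IMF from ``x`` by iterative envelope-mean subtraction.

    Stops when the candidate satisfies the IMF conditions, when the Cauchy
    step criterion falls below ``sd_threshold``, or after
    ``max_sift_iters`` iterations.
    """
    config = config or SiftConfig()
    h = np.asarray(x, dtype=float).copy()
    if not np.all(np.isfinite(h)):
        raise ValueError("sift input must be finite")
    if is_imf(h, config.envelope_tolerance):
        return h
    for _ in range(config.max_sift_iters):
        try:
            m = envelope_mean(h)
        except MonotonicSignalError:
            break
        h_new = h - m
        denom = np.sum(h ** 2)
        sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
        h = h_new
        if is_imf(h, config.envelope_tolerance) or sd < config.sd_threshold:
            break
    return h


def decompose(x: TimeSeries | np.ndarray, config: SiftConfig | None = None,
              fs: float | None = None) -> IMFSet:
    """Full EMD: sift off IMFs until the residue is monotonic.

    A residue with fewer than two maxima or two minima terminates the
    decomposition; a constant or monotonic input yields zero IMFs with the
    residue equal to the input.
    """
    config = config or SiftConfig()
    if isinstance(x, TimeSeries):
        values, fs = x.values, x.fs
    else:
        values = np.asarray(x, dtype=float)
        if fs is None:
            raise ValueError("fs required when input is a bare array")
    if not np.all(np.isfinite(values)):
        raise ValueError("input must be finite")

    residue = values.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < config.max_imfs:
        try:
            maxima, minima = find_extrema(residue)
        except ValueError:
            break
        if maxima.size < 2 or minima.size < 2:
            break
        imf = sift(residue, config)
        if np.allclose(imf, 0):
            break
        imfs.append(imf)
        residue = residue - imf
    return IMFSet(imfs=imfs, residue=residue, fs=fs, source=values)
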