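"""Minimal reference EMD, coded independently of the package implementation.

Used only as a cross-check oracle in tests.  Deliberately different design
choices: extrema from sign changes of first differences (no plateau
handling), envelopes anchored by clamping the signal endpoints as extra
knots (no mirroring), and a fixed SD-only stopping rule.  Agreement between
this and the package implementation on clean fixtures is evidence that
neither has a systematic envelope or stopping defect.
"""

import numpy as np
from scipy.interpolate import CubicSpline


def _extrema(x):
    d = np.diff(x)
    maxima = [i for i in range(1, len(x) - 1) if d[i - 1] > 0 and d[i] < 0]
    minima = [i for i in range(1, len(x) - 1) if d[i - 1] < 0 and d[i] > 0]
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def _envelope(idx, val, n):
    # clamp both signal endpoints as knots
    knots_i = np.concatenate(([0], idx, [n - 1]))
    knots_v = np.concatenate(([val[0]], val, [val[-1]]))
    knots_i, keep = np.unique(knots_i, return_index=True)
    return CubicSpline(knots_i, knots_v[keep])(np.arange(n))


def reference_sift(x, sd_stop=0.2, max_iter=50):
    h = np.asarray(x, dtype=float).copy()
    for _ in range(max_iter):
        maxima, minima = _extrema(h)
        if maxima.size < 2 or minima.size < 2:
            break
        e_up = _envelope(maxima, h[maxima], h.size)
        e_lo = _envelope(minima, h[minima], h.size)
        m = (e_up + e_lo) / 2
        h_new = h - m
        sd = np.sum((h - h_new) ** 2) / max(np.sum(h ** 2), 1e-300)
        h = h_new
        if sd < sd_stop:
            break
    return h


def reference_emd(x, max_imfs=12):
    residue = np.asarray(x, dtype=float).copy()
    imfs = []
    while len(imfs) < max_imfs:
        maxima, minima = _extrema(residue)
        if maxima.size < 2 or minima.size < 2:
            break
        imf = reference_sift(residue)
        imfs.append(imf)
        residue = residue - imf
    return imfs, residue
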