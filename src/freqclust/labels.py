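"""Cluster label alignment: label-sorting and label-matching.

k-means labels are arbitrary: the same partition can come back with any
permutation of cluster numbers from run to run, and labels carry no
correspondence across datasets.  Two procedures fix this.

Label-sorting canonicalizes labels within one run by scanning ROIs in a
fixed order (the atlas order) and renumbering clusters by first appearance,
using a hash table from raw label to new label.  Two runs that produce the
same partition then produce identical label vectors.

Label-matching aligns a target clustering to a reference clustering (for
instance across datasets or conditions): target clusters are assigned the
label of the reference cluster they overlap most, greedily in descending
overlap, each reference label used at most once; leftover target clusters
get fresh labels above the reference maximum.  An exact maximum-total-
overlap assignment (Hungarian algorithm) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["LabelTable", "sort_labels", "overlap_matrix", "match_labels"]


@dataclass
class LabelTable:
    """Raw (unordered) labels, sorted labels, and the first-seen hash map."""

    ult: np.ndarray
    slt: np.ndarray
    hash_map: dict[int, int]
    roi_order: np.ndarray


def _check_labels(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=int)
    if v.ndim != 1:
        raise ValueError(f"{name} must be a 1-D label vector")
    if v.size and v.min() < 1:
        raise ValueError(f"{name} labels must be positive integers")
    return v


def sort_labels(ult) -> LabelTable:
    """Renumber clusters by order of first appearance along the scan order.

    The first unseen raw label becomes 1, the next unseen becomes 2, and so
    on; repeated labels reuse their recorded replacement.  The partition is
    unchanged.
    """
    ult = _check_labels(ult, "ult")
    hash_map: dict[int, int] = {}
    slt = np.empty_like(ult)
    next_lab = 1
    for i, raw in enumerate(ult):
        raw = int(raw)
        if raw not in hash_map:
            hash_map[raw] = next_lab
            next_lab += 1
        slt[i] = hash_map[raw]
    return LabelTable(ult=ult, slt=slt, hash_map=hash_map,
                      roi_order=np.arange(ult.size))


def overlap_matrix(target, reference) -> pd.DataFrame:
    """Contingency counts: entry (a, b) = ROIs labelled a in target and b in
    reference.  Rows are target labels, columns reference labels; entries
    sum to the number of ROIs."""
    target = _check_labels(target, "target")
    reference = _check_labels(reference, "reference")
    if target.size != reference.size:
        raise ValueError(
            f"length mismatch: target {target.size} vs reference {reference.size}")
    t_labs = np.unique(target)
    r_labs = np.unique(reference)
    mat = np.zeros((t_labs.size, r_labs.size), dtype=int)
    t_idx = {lab: i for i, lab in enumerate(t_labs)}
    r_idx = {lab: j for j, lab in enumerate(r_labs)}
    for a, b in zip(target, reference):
        mat[t_idx[a], r_idx[b]] += 1
    return pd.DataFrame(mat, index=t_labs, columns=r_labs)


def match_labels(target, reference, method: str = "greedy",
                 use_jaccard: bool = False) -> np.ndarray:
    """Relabel target clusters with the reference labels they best overlap.

    ``method='greedy'`` assigns in descending overlap with ties broken by
    smaller reference label then smaller target label; ``method='exact'``
    maximizes total overlap with the Hungarian algorithm.  Each reference
    label is used at most once; unmatched target clusters receive fresh
    labels above the reference maximum, allocated in ascending target-label
    order.  The target partition is never changed.
    """
    target = _check_labels(target, "target")
    reference = _check_labels(reference, "reference")
    ov = overlap_matrix(target, reference)
    t_labs = list(ov.index)
    r_labs = list(ov.columns)
    scores = ov.to_numpy(dtype=float)
    if use_jaccard:
        t_sizes = ov.sum(axis=1).to_numpy()
        r_sizes = ov.sum(axis=0).to_numpy()
        union = t_sizes[:, None] + r_sizes[None, :] - scores
        scores = np.where(union > 0, scores / union, 0.0)

    mapping: dict[int, int] = {}
    if method == "greedy":
        cells = [(scores[i, j], r_labs[j], t_labs[i], i, j)
                 for i in range(len(t_labs)) for j in range(len(r_labs))
                 if scores[i, j] > 0]
        # descending overlap; ties -> smaller reference label, then target
        cells.sort(key=lambda c: (-c[0], c[1], c[2]))
        used_t: set[int] = set()
        used_r: set[int] = set()
        for _score, r_lab, t_lab, _i, _j in cells:
            if t_lab in used_t or r_lab in used_r:
                continue
            mapping[t_lab] = r_lab
            used_t.add(t_lab)
            used_r.add(r_lab)
    elif method == "exact":
        cost = -scores
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if scores[i, j] > 0:
                mapping[t_labs[i]] = r_labs[j]
    else:
        raise ValueError(f"unknown method {method!r}")

    next_fresh = int(reference.max()) + 1
    for t_lab in t_labs:  # ascending target-label order
        if t_lab not in mapping:
            mapping[t_lab] = next_fresh
            next_fresh += 1
    return np.array([mapping[int(a)] for a in target])
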