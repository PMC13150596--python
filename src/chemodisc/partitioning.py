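"""Kennard-Stone sample-set partitioning, stratified by class.

Kennard-Stone picks a representative training subset deterministically: the
first two selections are the farthest pair, and each later selection
maximizes its minimum Euclidean distance to the rows already chosen.  Ties
are broken toward the lexicographically smallest original index (pair), so
the selection order is reproducible and permutation-consistent.

The stratified split runs Kennard-Stone inside each class with a per-class
training quota of ``floor(train_fraction * n_class + 0.5)``; with the
standard 2/3 fraction on 15 + 18 samples this reproduces the 10 + 12 = 22
training / 11 test division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import SpectralDataset

__all__ = ["SplitResult", "kennard_stone", "stratified_split"]


@dataclass
class SplitResult:
    """Disjoint, exhaustive train/test row indices plus per-class quotas."""

    train_indices: list[int]
    test_indices: list[int]
    per_class_train_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "train_indices": list(self.train_indices),
            "test_indices": list(self.test_indices),
            "per_class_train_counts": dict(self.per_class_train_counts),
        }


def kennard_stone(matrix: np.ndarray, n_select: int) -> list[int]:
    """Max-min-distance selection order of ``n_select`` row indices."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = X.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select={n_select} out of range [2, {n}]")
    D = squareform(pdist(X, metric="euclidean"))

    # farthest pair; ties -> lexicographically smallest (i, j)
    best = (-1.0, n, n)
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] > best[0]:
                best = (D[i, j], i, j)
    selected = [best[1], best[2]]
    min_dist = np.minimum(D[best[1]], D[best[2]])

    while len(selected) < n_select:
        min_dist[selected] = -1.0  # never re-pick
        nxt = int(np.argmax(min_dist))  # argmax returns the smallest tied index
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
    return selected


def stratified_split(ds: SpectralDataset, train_fraction: float = 2.0 / 3.0) -> SplitResult:
    """Per-class Kennard-Stone division into training and test rows.

    Expects replicate-averaged, preprocessed spectra (one row per sample).
    The quota rounding is round-half-up, and a quota of 0 or the whole class
    is rejected as a degenerate split.
    """
    ds.require_two_classes()
    classes = ds.class_vector()
    train: list[int] = []
    counts: dict[str, int] = {}
    for label in ds.class_labels:
        rows = np.flatnonzero(classes == label)
        n_class = rows.size
        if n_class < 3:
            raise ValueError(f"class {label!r} has {n_class} samples; need >= 3")
        quota = int(np.floor(train_fraction * n_class + 0.5))
        if quota <= 0 or quota >= n_class:
            raise ValueError(
                f"degenerate split for class {label!r}: quota {quota} of {n_class}"
            )
        order = kennard_stone(ds.intensities[rows], quota)
        train.extend(int(rows[i]) for i in order)
        counts[label] = quota
    train_sorted = sorted(train)
    test = [i for i in range(ds.n_rows) if i not in set(train_sorted)]
    return SplitResult(
        train_indices=train_sorted,
        test_indices=test,
        per_class_train_counts=counts,
    )
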