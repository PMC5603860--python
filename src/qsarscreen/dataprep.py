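"""Descriptor-matrix reduction and Kennard-Stone train/test splitting.

The reduction mirrors the usual pre-modelling pass over a raw descriptor
matrix: drop constant and near-constant columns, then resolve collinear
descriptor pairs (|r| above a threshold) by keeping, from each pair, the
member more correlated with the activity.

The Kennard-Stone splitter picks a maximally spread training subset:
seed with the two most distant compounds in autoscaled descriptor space,
then repeatedly add the compound whose minimum distance to the already
selected set is largest.  All tie-breaks are deterministic (lexicographic
on the standardized coordinates, then original row index) so the split is
reproducible and invariant to row order for distinct rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ProcessingError
from .table import DescriptorTable

__all__ = [
    "SplitAssignment",
    "remove_constant",
    "collinearity_filter",
    "kennard_stone_split",
]


@dataclass
class SplitAssignment:
    """Disjoint train/test row indices covering the whole table."""

    train_indices: list[int]
    test_indices: list[int]

    def __post_init__(self) -> None:
        if not self.train_indices:
            raise ConfigurationError("training set must be nonempty")
        if set(self.train_indices) & set(self.test_indices):
            raise ConfigurationError("train and test indices overlap")

    def to_csv(self, table: DescriptorTable, path: str | Path) -> None:
        rows = [(table.compound_ids[i], "train") for i in self.train_indices]
        rows += [(table.compound_ids[i], "test") for i in self.test_indices]
        pd.DataFrame(rows, columns=["compound_id", "set"]).to_csv(path, index=False)


def remove_constant(
    table: DescriptorTable, near_constant_fraction: float = 0.95
) -> tuple[DescriptorTable, list[str]]:
    """Drop zero-variance columns and near-constant columns.

    A column is near-constant when its most frequent value occupies at
    least ``near_constant_fraction`` of the rows.  Returns the surviving
    table and the names removed, in original column order.
    """
    if table.n_compounds == 0 or table.n_descriptors == 0:
        raise ProcessingError("cannot filter an empty table")
    if not 0 < near_constant_fraction <= 1:
        raise ConfigurationError("near_constant_fraction must be in (0, 1]")
    n = table.n_compounds
    removed = []
    for j, name in enumerate(table.descriptor_names):
        col = table.values[:, j]
        if np.ptp(col) == 0.0:
            removed.append(name)
            continue
        _, counts = np.unique(col, return_counts=True)
        if counts.max() / n >= near_constant_fraction:
            removed.append(name)
    if len(removed) == table.n_descriptors:
        raise ProcessingError(
            "all descriptor columns are (near-)constant; inspect the input matrix"
        )
    return table.drop_columns(removed), removed


def collinearity_filter(
    table: DescriptorTable, threshold: float = 0.9
) -> tuple[DescriptorTable, list[str]]:
    """Resolve collinear descriptor pairs against the activity.

    For every pair with |Pearson r| > ``threshold`` the member with the
    lower |correlation to activity| is dropped.  Pairs are processed
    greedily by descending |r|, skipping columns already removed, so the
    worst redundancy is resolved first; the result contains no surviving
    pair above the threshold.
    """
    if table.activity is None:
        raise ConfigurationError("collinearity filter requires an activity column")
    if not 0 < threshold < 1:
        raise ConfigurationError("threshold must be in (0, 1)")
    p = table.n_descriptors
    if p < 2:
        return table, []

    X = table.values
    y = table.activity
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
        y_corr = np.array(
            [_safe_corr(X[:, j], y) for j in range(p)]
        )
    corr = np.nan_to_num(corr, nan=0.0)

    iu, ju = np.triu_indices(p, k=1)
    above = np.abs(corr[iu, ju]) > threshold
    pairs = sorted(
        zip(np.abs(corr[iu, ju])[above], iu[above], ju[above]),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    removed_idx: set[int] = set()
    for _, i, j in pairs:
        if i in removed_idx or j in removed_idx:
            continue
        # keep the member more correlated with activity; ties keep the first
        loser = j if abs(y_corr[j]) <= abs(y_corr[i]) else i
        removed_idx.add(loser)
    removed = [table.descriptor_names[j] for j in sorted(removed_idx)]
    return table.drop_columns(removed), removed


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def autoscale(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance scaling per column; constant columns map to 0."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def kennard_stone_split(table: DescriptorTable, n_train: int) -> SplitAssignment:
    """Kennard-Stone max-min-distance training-set selection.

    Distances are Euclidean in autoscaled descriptor space.  The first
    two training compounds realize the maximum pairwise distance; each
    subsequent pick maximizes the minimum distance to the selected set.
    Remaining rows form the prediction (test) set.
    """
    n = table.n_compounds
    if n_train > n:
        raise ConfigurationError(f"n_train={n_train} exceeds {n} compounds")
    if n_train < 2:
        raise ConfigurationError("n_train must be >= 2")

    Z = autoscale(table.values)
    diff = Z[:, None, :] - Z[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))

    def _preferred(candidates: np.ndarray) -> int:
        """Deterministic tie-break: lexicographically smallest standardized
        row, then smallest original index."""
        best = candidates[0]
        for c in candidates[1:]:
            for a, b in zip(Z[c], Z[best]):
                if a != b:
                    if a < b:
                        best = c
                    break
            else:
                if c < best:
                    best = c
        return int(best)

    # seed pair: true maximum pairwise distance
    dmax = dist.max()
    ii, jj = np.where(np.isclose(dist, dmax, rtol=0, atol=1e-12 * max(dmax, 1.0)))
    mask = ii < jj
    first = _preferred(np.unique(ii[mask]))
    second = _preferred(jj[mask][ii[mask] == first])
    selected = [first, second]

    remaining = [i for i in range(n) if i not in selected]
    min_dist = np.minimum(dist[:, first], dist[:, second])
    while len(selected) < n_train:
        cand = np.array(remaining)
        best_d = min_dist[cand].max()
        ties = cand[np.isclose(min_dist[cand], best_d, rtol=0, atol=1e-12 * max(best_d, 1.0))]
        pick = _preferred(ties)
        selected.append(pick)
        remaining.remove(pick)
        min_dist = np.minimum(min_dist, dist[:, pick])
    test = [i for i in range(n) if i not in set(selected)]
    return SplitAssignment(train_indices=selected, test_indices=test)
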