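"""Kennard-Stone division of samples into training and test sets.

The canonical max-min algorithm: seed the training set with the two
mutually farthest samples (Euclidean distance), then repeatedly add the
sample whose minimum distance to the current training set is largest,
until the requested training size is reached.  The remainder is the test
set.  Deterministic: ties break toward the lowest sample index.

Distances are computed on the Pareto-scaled matrix by default (pass
``scaling=None`` for raw intensities), since a space-filling design on raw
counts would be dominated by the few most intense features.

An ``alternating`` variant that assigns successive farthest-apart pairs
alternately to training and test is provided for completeness; it yields
an approximately 50/50 split and ignores ``n_train``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from oliveauth.feature_table import FeatureTable
from oliveauth.preprocessing import apply_scaling_matrix, fit_scaling

__all__ = ["Split", "kennard_stone", "kennard_stone_indices"]


@dataclass
class Split:
    """Disjoint ordered train/test sample-id lists covering all samples."""

    train_ids: list[str]
    test_ids: list[str]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def kennard_stone_indices(
    x: np.ndarray, n_train: int, variant: str = "maxmin"
) -> tuple[list[int], list[int]]:
    """Max-min Kennard-Stone on a raw coordinate matrix; returns row indices."""
    n = x.shape[0]
    if variant == "alternating":
        return _alternating(x)
    if not 2 <= n_train <= n:
        raise ValueError(f"n_train must be in [2, {n}], got {n_train}")
    d = squareform(pdist(np.asarray(x, dtype=float)))
    # seed: the two mutually farthest points, lowest indices on ties
    i, j = np.unravel_index(np.argmax(d), d.shape)
    train = [int(min(i, j)), int(max(i, j))]
    in_train = np.zeros(n, dtype=bool)
    in_train[train] = True
    min_d = d[:, train].min(axis=1)
    while len(train) < n_train:
        min_d[in_train] = -np.inf
        nxt = int(np.argmax(min_d))  # argmax takes the first (lowest) index
        train.append(nxt)
        in_train[nxt] = True
        min_d = np.minimum(min_d, d[:, nxt])
    test = [k for k in range(n) if not in_train[k]]
    return train, test


def _alternating(x: np.ndarray) -> tuple[list[int], list[int]]:
    """Assign successive farthest-apart remaining pairs alternately to the
    training and test sets (train first); a final odd sample goes to train."""
    d = squareform(pdist(np.asarray(x, dtype=float)))
    np.fill_diagonal(d, -np.inf)
    remaining = list(range(x.shape[0]))
    train: list[int] = []
    test: list[int] = []
    to_train = True
    while len(remaining) >= 2:
        sub = d[np.ix_(remaining, remaining)]
        a, b = np.unravel_index(np.argmax(sub), sub.shape)
        pair = sorted((remaining[a], remaining[b]))
        (train if to_train else test).extend(pair)
        to_train = not to_train
        remaining = [r for r in remaining if r not in pair]
    train.extend(remaining)
    return train, test


def kennard_stone(
    table: FeatureTable,
    n_train: int,
    scaling: str | None = "pareto",
    variant: str = "maxmin",
) -> Split:
    """Kennard-Stone split of the table's ``sample`` rows.

    ``scaling`` names the pretreatment used for the distance computation
    only (fitted on all sample rows); the downstream model refits its own
    scaling on the training rows.
    """
    sub = table.subset_samples(table.sample_ids)
    x = sub.sample_matrix
    if scaling is not None:
        params = fit_scaling(sub, scaling)
        x = apply_scaling_matrix(x, params)
    train_idx, test_idx = kennard_stone_indices(x, n_train, variant=variant)
    ids = sub.sample_ids
    return Split([ids[i] for i in train_idx], [ids[i] for i in test_idx])
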