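"""Seeded k-fold index construction, plain and group-exclusive.

One master seed spawns one child per repetition / sub-sample via
``numpy.random.SeedSequence`` (counter-based), so every repetition is
independently reproducible and the whole schedule is bit-stable.
"""

from __future__ import annotations

import numpy as np


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """n independent generators derived from one master seed by counter."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled k-fold split of range(n); fold sizes differ by at most one."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def group_kfold_indices(
    groups: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """k-fold split where all rows of a group land in the same fold.

    Groups are shuffled and dealt into k folds whose group counts differ by
    at most one; returns row-index arrays.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if k > len(uniq):
        raise ValueError(
            f"k={k} exceeds the number of groups ({len(uniq)})"
        )
    perm = rng.permutation(uniq)
    folds = []
    for chunk in np.array_split(perm, k):
        mask = np.isin(groups, chunk)
        folds.append(np.flatnonzero(mask))
    return folds


def train_test_split_indices(
    n: int, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test split; errors if either side would be empty."""
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n_train = int(round(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_fraction={train_fraction} leaves an empty split for n={n}"
        )
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
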