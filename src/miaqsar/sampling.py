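"""Representative splitting and resampling: Kennard-Stone, y-randomization,
and random test-set (bootstrap) cycles.

Kennard-Stone is fully deterministic; the random procedures draw from one
explicit seed so every report is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "SplitPlan",
    "kennard_stone_split",
    "y_randomize",
    "bootstrap_cycles",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class SplitPlan:
    """Train/test partition of row indices."""

    train: tuple[int, ...]
    test: tuple[int, ...]
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        overlap = set(self.train) & set(self.test)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)}")


def kennard_stone_split(X: np.ndarray, train_fraction: float) -> SplitPlan:
    """Classic maximin Kennard-Stone selection of the training set.

    Seeds with the most distant pair of rows (Euclidean distance), then
    repeatedly adds the row maximizing its minimum distance to the already
    selected set.  Ties break toward the lowest row index.  The remainder is
    the test set; its size is round-half-up of n * (1 - train_fraction).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    D = cdist(X, X)
    if D.max() == 0:
        raise ValueError("all rows identical; Kennard-Stone is undefined")

    n_test = round_half_up(n * (1.0 - train_fraction))
    n_train = n - n_test
    if n_train < 2 or n_test < 1:
        raise ValueError(f"degenerate split: {n_train} train / {n_test} test")

    # farthest pair, lowest indices on ties
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in selected]
    while len(selected) < n_train:
        dmin = D[np.ix_(remaining, selected)].min(axis=1)
        selected.append(remaining.pop(int(np.argmax(dmin))))
    return SplitPlan(
        train=tuple(sorted(selected)),
        test=tuple(k for k in range(n) if k not in set(selected)),
        method="kennard-stone",
    )


def y_randomize(y: np.ndarray, n_cycles: int, seed: int) -> list[np.ndarray]:
    """Uniform random permutations of the response (descriptors untouched)."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    return [rng.permutation(y) for _ in range(n_cycles)]


def bootstrap_cycles(
    n: int, test_fraction: float, n_cycles: int, seed: int
) -> list[SplitPlan]:
    """Random test-set re-selection cycles (without replacement).

    Each cycle draws round-half-up(n * test_fraction) distinct test rows
    uniformly; the remainder trains.  Used to check model stability on small
    datasets.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = round_half_up(n * test_fraction)
    if not 1 <= n_test <= n - 2:
        raise ValueError(f"degenerate test size {n_test} for n={n}")
    rng = np.random.default_rng(seed)
    plans = []
    for _ in range(n_cycles):
        test = np.sort(rng.choice(n, size=n_test, replace=False))
        train = np.setdiff1d(np.arange(n), test)
        plans.append(
            SplitPlan(tuple(train), tuple(test), method="random-test", seed=seed)
        )
    return plans
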