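"""Sample-set partitioning: random testing holdout + SPXY calibration selection.

The testing set is drawn uniformly at random in advance.  The remaining
(modeling) samples are divided into calibration and validation parts by SPXY
(sample-set partitioning based on joint x-y distance): a Kennard-Stone-style
greedy max-min selection on the normalized joint distance

    d(i, j) = d_x(i, j) / max d_x  +  d_y(i, j) / max d_y,

where d_x is Euclidean distance between (preprocessed) spectra and d_y the
absolute difference of reference values.  SPXY is deterministic; ties in the
max-min step are broken toward the lowest sample index for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .spectra import SpectralDataset, snv_transform

__all__ = ["SplitIndices", "random_holdout", "spxy_select", "split_dataset"]


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint 0-based row index arrays covering all samples."""

    calibration: np.ndarray
    validation: np.ndarray
    testing: np.ndarray

    def __post_init__(self) -> None:
        parts = [np.asarray(p, dtype=int) for p in
                 (self.calibration, self.validation, self.testing)]
        object.__setattr__(self, "calibration", parts[0])
        object.__setattr__(self, "validation", parts[1])
        object.__setattr__(self, "testing", parts[2])
        allidx = np.concatenate(parts)
        if len(np.unique(allidx)) != allidx.size:
            raise ValueError("split parts overlap")

    @property
    def n_samples(self) -> int:
        return self.calibration.size + self.validation.size + self.testing.size


def random_holdout(dataset: SpectralDataset, n_test: int, seed: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random testing holdout; returns (modeling, testing) indices.

    Deterministic for a fixed seed; both index arrays are sorted ascending.
    """
    n = dataset.n_samples
    if not 0 < n_test < n:
        raise ValueError(f"n_test must be in 1..{n - 1}, got {n_test}")
    rng = np.random.default_rng(seed)
    testing = np.sort(rng.choice(n, size=n_test, replace=False))
    modeling = np.setdiff1d(np.arange(n), testing)
    return modeling, testing


def spxy_select(X: np.ndarray, y: np.ndarray, n_select: int) -> np.ndarray:
    """Greedy SPXY selection; returns indices in order of selection.

    The first two picks are the pair with maximal joint distance; each later
    pick maximizes its minimum joint distance to the already-selected set.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select must be in 2..{n}, got {n_select}")

    dx = cdist(X, X)
    dy = np.abs(y[:, None] - y[None, :])
    d = np.zeros((n, n))
    if dx.max() > 0:
        d += dx / dx.max()
    if dy.max() > 0:
        d += dy / dy.max()

    # initial pair: maximal joint distance, ties -> lexicographically smallest (i, j)
    flat = np.argmax(d)  # argmax returns the first (row-major) maximum
    i, j = divmod(int(flat), n)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in selected]

    mind = d[:, selected].min(axis=1)
    while len(selected) < n_select:
        cand = remaining[int(np.argmax(mind[remaining]))]  # first max -> lowest index
        selected.append(cand)
        remaining.remove(cand)
        mind = np.minimum(mind, d[:, cand])
    return np.array(selected, dtype=int)


def split_dataset(dataset: SpectralDataset, n_cal: int, n_val: int,
                  n_test: int, seed: int) -> SplitIndices:
    """Testing via random holdout, then SPXY calibration over the modeling pool.

    SPXY distances are computed on SNV-pretreated spectra, matching the
    pipeline in which scatter correction precedes every modeling stage.
    Validation is the modeling remainder.
    """
    n = dataset.n_samples
    if n_cal + n_val + n_test != n:
        raise ValueError(f"n_cal + n_val + n_test = {n_cal + n_val + n_test} != {n}")
    if n_val < 1:
        raise ValueError("validation part must be nonempty")
    if n_cal < 2:
        raise ValueError("calibration part needs >= 2 samples")
    modeling, testing = random_holdout(dataset, n_test, seed)
    pool = snv_transform(dataset.subset(modeling))
    order = spxy_select(pool.absorbance, pool.y, n_cal)
    calibration = modeling[order]
    validation = np.setdiff1d(modeling, calibration)
    return SplitIndices(calibration=calibration, validation=validation, testing=testing)
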