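"""Latent principal components (LPCs) of a selected waveband.

The channels inside a chosen waveband are compressed to principal components
of the calibration spectra, sorted by descending explained variance; every
component above numerical rank tolerance is kept (no truncation by default,
so a 36-channel waveband with 90 calibration samples yields 36 LPCs).  The
basis is fitted on calibration samples only; validation and testing spectra
are projected with the calibration means and loadings, never refitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .window_search import Window

__all__ = ["LPCBasis", "fit_lpc", "project"]

#: singular values below this fraction of the largest are treated as rank-deficient
_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class LPCBasis:
    """PCA basis of one waveband: calibration means, loadings, variances."""

    window: Window | None
    column_means: np.ndarray       # (N,)
    loadings: np.ndarray           # (N, m), orthonormal columns
    explained_variance: np.ndarray  # (m,), descending, ddof=1

    @property
    def m(self) -> int:
        """Number of retained latent principal components."""
        return self.loadings.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Serializable audit table: one row per channel, one column per LPC."""
        df = pd.DataFrame(self.loadings,
                          columns=[f"LPC{i + 1}" for i in range(self.m)])
        df.insert(0, "column_mean", self.column_means)
        return df


def fit_lpc(cal_window_matrix: np.ndarray, window: Window | None = None,
            max_components: int | None = None) -> LPCBasis:
    """Principal components of the mean-centered calibration window matrix.

    Components come from the singular-value decomposition; each loading's
    sign is fixed so its largest-magnitude entry is positive, making the
    basis reproducible across SVD implementations.  ``max_components``
    optionally truncates to the leading components.
    """
    X = np.atleast_2d(np.asarray(cal_window_matrix, dtype=float))
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 calibration rows to fit LPCs")
    means = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - means, full_matrices=False)
    keep = s > _RANK_RTOL * (s[0] if s.size else 0.0)
    s, vt = s[keep], vt[keep]
    if max_components is not None:
        s, vt = s[:max_components], vt[:max_components]
    loadings = vt.T
    flip = loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])] < 0
    loadings[:, flip] *= -1
    return LPCBasis(window=window, column_means=means, loadings=loadings,
                    explained_variance=s ** 2 / (n - 1))


def project(basis: LPCBasis, X_window: np.ndarray) -> np.ndarray:
    """Scores of new spectra in the calibration-fitted basis."""
    X = np.atleast_2d(np.asarray(X_window, dtype=float))
    if X.shape[1] != basis.column_means.size:
        raise ValueError(
            f"X has {X.shape[1]} columns, basis expects {basis.column_means.size}")
    return (X - basis.column_means) @ basis.loadings
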