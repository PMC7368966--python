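"""PLS1 regression via NIPALS, prediction, and RMSE / correlation metrics.

The model regresses a single response on mean-centered spectra by extracting
latent variables one at a time: each component's weight vector is the
(normalized) covariance direction ``X' y``, the score is the projection of X
on it, and X is deflated by the score's loading before the next component
(X-only deflation; for a univariate y each component is exact, no inner
iteration is needed).  Only mean-centering is applied — per-spectrum SNV
upstream already removes scatter, and column autoscaling is off by default.

RMSE uses denominator n.  The correlation R is the Pearson product-moment
coefficient between reference and predicted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PLSModel", "EvaluationReport", "fit_pls", "predict", "evaluate",
           "max_components"]


def max_components(n_vars: int, n_cal: int, cap: int = 15) -> int:
    """Latent-variable ceiling for a window model: min(cap, N, n_cal - 1)."""
    return max(0, min(cap, n_vars, n_cal - 1))


@dataclass(frozen=True)
class PLSModel:
    """Fitted PLS1 model.

    ``coefs`` holds one regression vector per truncation level: ``coefs[a]``
    predicts centered y from centered X using the first ``a`` latent
    variables (``coefs[0]`` is all-zero, the intercept-only model), which
    makes scanning the latent-variable count cheap after a single fit.
    """

    n_components: int
    x_mean: np.ndarray          # (P_w,)
    y_mean: float
    weights: np.ndarray         # (P_w, A) NIPALS weight vectors
    x_loadings: np.ndarray      # (P_w, A)
    y_loadings: np.ndarray      # (A,)
    coefs: np.ndarray           # (A + 1, P_w); row a = coefficients using a LVs

    @property
    def coef(self) -> np.ndarray:
        """Regression vector at the model's full component count."""
        return self.coefs[self.n_components]


@dataclass(frozen=True)
class EvaluationReport:
    """RMSE and Pearson correlation for one prediction set."""

    rmse: float
    r: float | None
    n: int
    which_set: str = ""
    r_defined: bool = True


def fit_pls(X_cal: np.ndarray, y_cal: np.ndarray, n_components: int) -> PLSModel:
    """Fit a PLS1 model with ``n_components`` latent variables (NIPALS)."""
    X = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y = np.asarray(y_cal, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X_cal and y_cal disagree on sample count")
    if n < 2:
        raise ValueError("need at least 2 calibration samples")
    if np.ptp(y) == 0:
        raise ValueError("y_cal has zero variance")
    a_max = min(p, n - 1)
    if not 0 <= n_components <= a_max:
        raise ValueError(
            f"n_components must be in 0..{a_max} for this data, got {n_components}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean

    A = n_components
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    for a in range(A):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-14:  # X residual carries no covariance with y
            W, P, q = W[:, :a], P[:, :a], q[:a]
            A = a
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-28:
            W, P, q = W[:, :a], P[:, :a], q[:a]
            A = a
            break
        W[:, a] = w
        P[:, a] = Xd.T @ t / tt
        q[a] = yd @ t / tt
        Xd = Xd - np.outer(t, P[:, a])

    # coefficients per truncation level: B_a = W_a (P_a' W_a)^{-1} q_a
    coefs = np.zeros((A + 1, p))
    if A:
        PtW = P.T @ W  # upper-triangular with unit-ish structure, small (A x A)
        for a in range(1, A + 1):
            ba = np.linalg.solve(PtW[:a, :a], q[:a])
            coefs[a] = W[:, :a] @ ba
    return PLSModel(n_components=A, x_mean=x_mean, y_mean=y_mean,
                    weights=W, x_loadings=P, y_loadings=q, coefs=coefs)


def predict(model: PLSModel, X_new: np.ndarray, n_components: int | None = None
            ) -> np.ndarray:
    """Predict y for new spectra, optionally truncating the component count."""
    X = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X_new has {X.shape[1]} columns, model expects {model.x_mean.size}")
    a = model.n_components if n_components is None else n_components
    if not 0 <= a <= model.n_components:
        raise ValueError(f"n_components must be in 0..{model.n_components}")
    return (X - model.x_mean) @ model.coefs[a] + model.y_mean


def evaluate(y_true: np.ndarray, y_pred: np.ndarray, which_set: str = ""
             ) -> EvaluationReport:
    """RMSE (denominator n) and Pearson R between reference and prediction."""
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yt.size == 0 or yt.size != yp.size:
        raise ValueError("y_true and y_pred must be equal-length and nonempty")
    n = yt.size
    rmse = float(np.sqrt(np.mean((yt - yp) ** 2)))
    st = yt - yt.mean()
    sp = yp - yp.mean()
    denom = np.sqrt((st @ st) * (sp @ sp))
    if denom == 0:
        return EvaluationReport(rmse=rmse, r=None, n=n, which_set=which_set,
                                r_defined=False)
    r = float(np.clip((st @ sp) / denom, -1.0, 1.0))
    return EvaluationReport(rmse=rmse, r=r, n=n, which_set=which_set)
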