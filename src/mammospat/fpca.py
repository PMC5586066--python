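"""Functional PCA of forces-histogram curves.

Each forces histogram is a curve over the angle grid; across images each of
the six FH families forms a functional sample.  The sample is compressed by
functional principal component analysis: the mean curve is subtracted, the
sample covariance over the grid is eigendecomposed (uniform quadrature
weights; the FH grid is dense and regular, for which sparse-data functional
estimators reduce to plain discretised PCA), and the leading K components
are retained by an 85% cumulative-variance rule.  Per-image scores are the
grid inner products of the centred curve with each eigenfunction, and are
standardised to zero mean and unit variance over the training images before
entering any regression model.

The modes-of-variation curves ``V(theta) = mu(theta) + alpha sqrt(lambda_k)
phi_k(theta)`` visualise what component k changes about the mean histogram,
and the dominant angles of ``|phi_k|`` locate where that variability lives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateDataError,
    IncompatibleGridError,
    InsufficientDataError,
)

DEFAULT_VARIANCE_THRESHOLD = 0.85


@dataclass
class FPCModel:
    """Fitted functional PCA of one FH family."""

    grid: np.ndarray  # angles (degrees)
    mean_fn: np.ndarray  # mu(theta)
    eigenfunctions: np.ndarray  # (n_components, grid) orthonormal rows
    eigenvalues: np.ndarray  # non-increasing, >= 0 (all nonzero components)
    K: int  # retained count by the variance rule
    variance_threshold: float
    scores: np.ndarray  # (n_images, K) standardised training scores
    score_mean: np.ndarray  # (K,) raw-score mean over training images
    score_sd: np.ndarray  # (K,) raw-score sd (ddof=1) over training images

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "mean_fn": self.mean_fn.tolist(),
            "eigenfunctions": self.eigenfunctions[: self.K].tolist(),
            "eigenvalues": self.eigenvalues[: self.K].tolist(),
            "K": self.K,
            "variance_threshold": self.variance_threshold,
            "score_mean": self.score_mean.tolist(),
            "score_sd": self.score_sd.tolist(),
        }


@dataclass
class ModeOfVariation:
    """Curves ``mu +/- alpha sqrt(lambda_k) phi_k`` for one component."""

    k: int
    alpha: float
    grid: np.ndarray
    plus: np.ndarray
    minus: np.ndarray


def fit_fpca(
    curves: np.ndarray,
    grid: np.ndarray | None = None,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> FPCModel:
    """Discretised functional PCA of curves on a common regular grid.

    The covariance uses divisor ``n - 1``.  Eigenfunction signs are fixed so
    each has positive inner product with the first grid basis vector (first
    grid value positive; exact zero falls back to a positive sum).  K is the
    smallest count whose eigenvalues reach ``variance_threshold`` of the
    total variance.
    """
    X = np.asarray(curves, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InsufficientDataError("need at least 2 curves on a common grid")
    n, g = X.shape
    grid = np.arange(g) * (360.0 / g) if grid is None else np.asarray(grid, dtype=float)
    if grid.size != g:
        raise IncompatibleGridError("grid length does not match curves")
    mu = X.mean(axis=0)
    C = X - mu
    cov = C.T @ C / (n - 1)
    total_var = float(np.trace(cov))
    if total_var <= 0:
        raise DegenerateDataError("curves have zero total variance")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order].T  # rows are eigenfunctions
    nonzero = evals > max(1e-12 * evals[0], 1e-300)
    evals, evecs = evals[nonzero], evecs[nonzero]
    for k in range(evecs.shape[0]):
        ref = evecs[k, 0]
        if ref == 0.0:
            ref = evecs[k].sum()
        if ref < 0:
            evecs[k] = -evecs[k]
    cum = np.cumsum(evals) / evals.sum()
    K = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    K = min(K, evals.size)
    raw = C @ evecs[:K].T
    score_mean = raw.mean(axis=0)
    score_sd = raw.std(axis=0, ddof=1)
    if np.any(score_sd <= 0):
        raise DegenerateDataError("a retained component has zero score variance")
    return FPCModel(
        grid=grid,
        mean_fn=mu,
        eigenfunctions=evecs,
        eigenvalues=evals,
        K=K,
        variance_threshold=variance_threshold,
        scores=(raw - score_mean) / score_sd,
        score_mean=score_mean,
        score_sd=score_sd,
    )


def project(
    model: FPCModel, new_curves: np.ndarray, grid: np.ndarray | None = None,
    standardise: bool = True,
) -> np.ndarray:
    """Score new curves with a fitted model.

    Curves are centred with the model mean and projected on the retained
    eigenfunctions; by default the scores are standardised with the model's
    stored training mean and sd (mirroring scoring a validation study with a
    training-study model).
    """
    X = np.atleast_2d(np.asarray(new_curves, dtype=float))
    if X.shape[1] != model.grid.size:
        raise IncompatibleGridError("new curves are not on the model grid")
    if grid is not None and not np.allclose(np.asarray(grid, float), model.grid):
        raise IncompatibleGridError("new curves are not on the model grid")
    raw = (X - model.mean_fn) @ model.eigenfunctions[: model.K].T
    if not standardise:
        return raw
    return (raw - model.score_mean) / model.score_sd


def mode_of_variation(model: FPCModel, k: int, alpha: float) -> ModeOfVariation:
    """``V = mu +/- alpha sqrt(lambda_k) phi_k`` on the model grid (k is 1-based)."""
    if not 1 <= k <= model.K:
        raise IndexError(f"component k={k} out of range 1..{model.K}")
    dev = alpha * np.sqrt(model.eigenvalues[k - 1]) * model.eigenfunctions[k - 1]
    return ModeOfVariation(
        k=k, alpha=alpha, grid=model.grid, plus=model.mean_fn + dev, minus=model.mean_fn - dev
    )


def dominant_angles(model: FPCModel, k: int, top_m: int = 3) -> list[tuple[float, int]]:
    """Angles of the largest circular local maxima of ``|phi_k|``.

    Returns up to ``top_m`` pairs (angle in degrees, sign of phi_k there),
    ordered by decreasing ``|phi_k|``.  Used to interpret what directions a
    component captures.
    """
    if not 1 <= k <= model.K:
        raise IndexError(f"component k={k} out of range 1..{model.K}")
    phi = model.eigenfunctions[k - 1]
    mag = np.abs(phi)
    left = np.roll(mag, 1)
    right = np.roll(mag, -1)
    is_max = (mag >= left) & (mag >= right) & (mag > 0)
    # plateau de-duplication: keep the first grid point of each run
    is_max &= ~((mag == left) & np.roll(is_max, 1))
    peaks = np.nonzero(is_max)[0]
    peaks = peaks[np.argsort(mag[peaks])[::-1]][:top_m]
    return [(float(model.grid[p]), int(np.sign(phi[p]))) for p in peaks]
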