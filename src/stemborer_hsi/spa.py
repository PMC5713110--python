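"""Successive projections algorithm (SPA) for characteristic wavelengths.

SPA is a forward variable-selection scheme built to fight collinearity in
spectral matrices.  Phase 1 grows, from every possible starting column of
the N x K calibration matrix X, a chain of variables in which each new
variable maximizes the norm of its projection onto the orthogonal
complement of the span of the variables already in the chain (so each
addition carries the most non-redundant information).  Phase 2 scores every
chain prefix by fitting a multiple linear regression (MLR) on the
calibration set and measuring RMSE on a validation set, and keeps the
subset with the minimum RMSE.

Here the regression response is the ordinal infestation degree 0..5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["MLRModel", "SPAResult", "spa_chain", "spa_all_chains", "mlr_fit", "rmse", "spa_phase2"]

logger = logging.getLogger(__name__)

# Residual columns with norm below this fraction of the largest original
# column norm are considered inside the span of the chain.
_SPAN_RTOL = 1e-10


def spa_chain(X: np.ndarray, start: int, M: int | None = None, center: bool = False) -> list[int]:
    """Grow one SPA chain of up to M variables starting at column ``start``.

    Each step deflates every column by its projection onto the most recently
    chosen residual (classic Gram-Schmidt accumulation, equivalent to
    projecting onto the orthogonal complement of all chosen columns) and
    picks the column with the largest residual norm.  Ties break toward the
    lowest column index.  The chain truncates early if all remaining
    residuals are numerically inside the chain's span.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if not 0 <= start < k:
        raise ValueError(f"start index {start} outside [0, {k})")
    if M is None:
        M = max(min(n - 1, k), 1)
    M = min(M, n, k)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    R = X.copy()
    scale = np.linalg.norm(X, axis=0).max()
    tol = _SPAN_RTOL * (scale if scale > 0 else 1.0)
    chain = [start]
    chosen = np.zeros(k, dtype=bool)
    chosen[start] = True
    z = R[:, start].copy()
    while len(chain) < M:
        zz = z @ z
        if zz <= tol * tol:
            logger.warning("spa_chain: chain from %d truncated at length %d (zero pivot)", start, len(chain))
            break
        R -= np.outer(z, (z @ R) / zz)
        norms = np.linalg.norm(R, axis=0)
        norms[chosen] = -1.0
        j_max = int(np.argmax(norms))  # argmax takes the first max -> lowest index on ties
        if norms[j_max] <= tol:
            logger.warning(
                "spa_chain: chain from %d truncated at length %d (remaining columns in span)",
                start,
                len(chain),
            )
            break
        chain.append(j_max)
        chosen[j_max] = True
        z = R[:, j_max].copy()
    return chain


def spa_all_chains(X: np.ndarray, M: int | None = None, center: bool = False) -> list[list[int]]:
    """Phase 1: one chain per possible starting variable (K chains)."""
    X = np.asarray(X, dtype=float)
    return [spa_chain(X, start, M=M, center=center) for start in range(X.shape[1])]


@dataclass
class MLRModel:
    """Ordinary least-squares fit y ~ intercept + X @ coef."""

    coef: np.ndarray
    intercept: float
    rank: int
    rank_deficient: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


def mlr_fit(Xsub: np.ndarray, y: np.ndarray) -> MLRModel:
    """Fit multiple linear regression with an intercept via least squares.

    Rank-deficient designs fall back to the minimum-norm solution and are
    flagged on the returned model.
    """
    Xsub = np.atleast_2d(np.asarray(Xsub, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if Xsub.shape[0] != y.size:
        raise ValueError("X and y must have the same number of rows")
    if not (np.all(np.isfinite(Xsub)) and np.all(np.isfinite(y))):
        raise ValueError("mlr_fit requires finite values")
    A = np.column_stack([np.ones(Xsub.shape[0]), Xsub])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    deficient = rank < A.shape[1]
    if deficient:
        logger.warning("mlr_fit: rank-deficient design (rank %d < %d), minimum-norm solution", rank, A.shape[1])
    return MLRModel(coef=beta[1:], intercept=float(beta[0]), rank=int(rank), rank_deficient=deficient)


def rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    """Root mean square error between predictions and observations."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size != obs.size or pred.size == 0:
        raise ValueError("pred and obs must have equal, non-zero length")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


@dataclass
class SPAResult:
    """Outcome of the Phase-2 subset search."""

    selected_indices: list[int]
    selected_wavelengths: np.ndarray | None
    rmse_by_size: dict[int, float]
    best_size: int
    best_rmse: float


def spa_phase2(
    chains: Sequence[Sequence[int]],
    Xcal: np.ndarray,
    ycal: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    size_range: Iterable[int] = range(1, 31),
    wavelengths: np.ndarray | None = None,
) -> SPAResult:
    """Phase 2: pick the chain prefix with minimum validation RMSE.

    Every prefix of every chain whose size falls in ``size_range`` is fitted
    by MLR on the calibration set and scored on the validation set.
    Identical index sets are evaluated once.  ``rmse_by_size`` records the
    best RMSE observed at each size (the content of an RMSE-vs-size scree
    plot).  Ties break toward the smaller subset, then chain order.
    """
    sizes = sorted(set(int(s) for s in size_range))
    if not sizes:
        raise ValueError("size_range is empty")
    if sizes[0] < 1:
        raise ValueError("subset sizes must be >= 1")
    Xcal = np.asarray(Xcal, dtype=float)
    Xval = np.asarray(Xval, dtype=float)
    rmse_by_size: dict[int, float] = {}
    best: tuple[float, int, int] | None = None  # (rmse, size, order)
    best_subset: list[int] = []
    seen: set[tuple[int, ...]] = set()
    order = 0
    for chain in chains:
        for size in sizes:
            if size > len(chain):
                continue
            subset = tuple(chain[:size])
            key = tuple(sorted(subset))
            if key in seen:
                continue
            seen.add(key)
            model = mlr_fit(Xcal[:, list(subset)], ycal)
            err = rmse(model.predict(Xval[:, list(subset)]), yval)
            if size not in rmse_by_size or err < rmse_by_size[size]:
                rmse_by_size[size] = err
            cand = (err, size, order)
            if best is None or cand < best:
                best = cand
                best_subset = list(subset)
            order += 1
    if best is None:
        raise ValueError("no chain prefix matches the requested size_range")
    return SPAResult(
        selected_indices=best_subset,
        selected_wavelengths=None if wavelengths is None else np.asarray(wavelengths)[best_subset],
        rmse_by_size=rmse_by_size,
        best_size=len(best_subset),
        best_rmse=best[0],
    )
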