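"""Sample-set partitioning and feature preparation for the classifiers.

Kennard-Stone picks a representative calibration set by max-min Euclidean
distance; features are min-max normalized on calibration-set extrema; the
spectral and textural blocks are fused by column concatenation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SplitResult", "FeatureTable", "kennard_stone", "ks_split_ratio", "minmax_normalize", "fuse"]

logger = logging.getLogger(__name__)


@dataclass
class SplitResult:
    """Calibration/prediction partition (ids are row indices, pick order kept)."""

    calibration_ids: np.ndarray
    prediction_ids: np.ndarray
    ratio: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.calibration_ids = np.asarray(self.calibration_ids, dtype=int)
        self.prediction_ids = np.asarray(self.prediction_ids, dtype=int)
        if np.intersect1d(self.calibration_ids, self.prediction_ids).size:
            raise ValueError("calibration and prediction sets must be disjoint")


def kennard_stone(X: np.ndarray, n_cal: int) -> SplitResult:
    """Kennard-Stone max-min-distance selection of ``n_cal`` calibration samples.

    The first two picks are the most distant pair; every later pick
    maximizes its minimum Euclidean distance to the already-picked set.
    Ties break toward the lowest sample index, so the split is
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be an N x F matrix")
    n = X.shape[0]
    if not 2 <= n_cal <= n:
        raise ValueError(f"n_cal must be in [2, {n}]")
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    # first pair: maximum pairwise distance, first (lowest-index) occurrence
    flat = int(np.argmax(d2))
    a, b = divmod(flat, n)
    if a > b:
        a, b = b, a
    selected = [a, b]
    in_cal = np.zeros(n, dtype=bool)
    in_cal[[a, b]] = True
    min_d2 = np.minimum(d2[a], d2[b])
    while len(selected) < n_cal:
        min_d2[in_cal] = -1.0
        pick = int(np.argmax(min_d2))
        selected.append(pick)
        in_cal[pick] = True
        np.minimum(min_d2, d2[pick], out=min_d2)
    prediction = np.flatnonzero(~in_cal)
    return SplitResult(np.array(selected), prediction)


def ks_split_ratio(X: np.ndarray, ratio: tuple[int, int] = (2, 1)) -> SplitResult:
    """Kennard-Stone split at a calibration:prediction ratio (default 2:1).

    n_cal = floor(N * cal / (cal + pred)); e.g. 365 samples at 2:1 give 243
    calibration and 122 prediction samples.
    """
    n = np.asarray(X).shape[0]
    n_cal = int(n * ratio[0] // (ratio[0] + ratio[1]))
    result = kennard_stone(X, n_cal)
    result.ratio = ratio
    return result


@dataclass
class FeatureTable:
    """N x F feature matrix with names, DI labels and normalization state."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    sample_ids: list[str]
    normalization: tuple[np.ndarray, np.ndarray] | None = None  # (min, max) per feature

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, f = self.values.shape
        if len(self.feature_names) != f:
            raise ValueError("feature_names must match the number of columns")
        if self.labels.size != n or len(self.sample_ids) != n:
            raise ValueError("labels and sample_ids must match the number of rows")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def minmax_normalize(table: FeatureTable, reference_ids: np.ndarray) -> FeatureTable:
    """Scale every feature to [0, 1] using calibration-set extrema.

    The (min, max) pairs are computed on ``reference_ids`` rows only and
    applied to all rows, so prediction samples outside the calibration range
    legitimately fall outside [0, 1] (logged, not clipped).  Constant
    features map to 0 and are flagged.
    """
    reference_ids = np.asarray(reference_ids, dtype=int)
    if reference_ids.size == 0:
        raise ValueError("reference set is empty")
    ref = table.values[reference_ids]
    lo = ref.min(axis=0)
    hi = ref.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        logger.warning("minmax_normalize: %d constant feature(s) mapped to 0", int(constant.sum()))
    scaled = (table.values - lo) / np.where(constant, 1.0, span)
    scaled[:, constant] = 0.0
    outside = (scaled < 0) | (scaled > 1)
    outside[reference_ids] = False
    if outside.any():
        logger.info("minmax_normalize: %d value(s) outside [0, 1] on non-reference rows", int(outside.sum()))
    return replace(
        table,
        values=scaled,
        feature_names=list(table.feature_names),
        labels=table.labels.copy(),
        sample_ids=list(table.sample_ids),
        normalization=(lo, hi),
    )


def fuse(spectral: FeatureTable, texture: FeatureTable) -> FeatureTable:
    """Feature-level fusion: spectral block then texture block, columns concatenated."""
    if spectral.values.shape[0] != texture.values.shape[0]:
        raise ValueError("tables must have the same number of rows")
    if spectral.sample_ids != texture.sample_ids or not np.array_equal(spectral.labels, texture.labels):
        raise ValueError("tables must describe the same samples in the same order")
    if texture.n_features == 0:
        return replace(
            spectral,
            values=spectral.values.copy(),
            feature_names=list(spectral.feature_names),
            labels=spectral.labels.copy(),
            sample_ids=list(spectral.sample_ids),
        )
    return FeatureTable(
        values=np.hstack([spectral.values, texture.values]),
        feature_names=list(spectral.feature_names) + list(texture.feature_names),
        labels=spectral.labels.copy(),
        sample_ids=list(spectral.sample_ids),
    )
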