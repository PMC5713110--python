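"""PC score images and gray-level co-occurrence texture descriptors.

A hyperspectral cube is hundreds of gray-scale band images; PCA over the
ROI pixel spectra compresses them into a few principal-component score
images, and Haralick-style texture statistics are then read off the
gray-level co-occurrence matrix (GLCM) of the first two PC images.  The
GLCM p(i, j) is the relative frequency with which gray level i co-occurs
with gray level j at a fixed pixel offset (distance D, direction theta).

Eight descriptors per image (mean, variance, homogeneity, contrast,
dissimilarity, entropy, second moment, correlation) over two PC images
give the 16-value texture vector of a sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .hypercube import Hypercube
from .spa import mlr_fit

__all__ = [
    "PCAModel",
    "GLCMConfig",
    "GLCMMatrix",
    "TextureVector",
    "DESCRIPTOR_NAMES",
    "pca_fit",
    "pc_score_images",
    "quantize",
    "glcm",
    "glcm_descriptors",
    "texture_vector",
    "texture_di_regression",
]

DESCRIPTOR_NAMES = (
    "mean",
    "variance",
    "homogeneity",
    "contrast",
    "dissimilarity",
    "entropy",
    "second_moment",
    "correlation",
)

#: (row, col) step per unit distance for each supported direction
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class PCAModel:
    """Mean-centered principal components: loadings are K x C orthonormal."""

    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    center: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) @ self.loadings


def pca_fit(X: np.ndarray, n_components: int) -> PCAModel:
    """Fit PCA on an N x K matrix of spectra (or pixel spectra).

    Components are ordered by decreasing eigenvalue; each loading's sign is
    fixed so its largest-magnitude element is positive.  Variance ratios
    beyond the data rank (e.g. constant data) are reported as 0.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("pca_fit requires an N x K matrix with N >= 2")
    if not 1 <= n_components <= min(X.shape):
        raise ValueError(f"n_components must be in [1, {min(X.shape)}]")
    # covariance_eigh is deterministic and fast for the band counts used here;
    # the auto solver may fall back to randomized SVD, which is not reproducible
    solver = "covariance_eigh" if X.shape[1] <= 2048 else "full"
    p = PCA(n_components=n_components, svd_solver=solver)
    with np.errstate(divide="ignore", invalid="ignore"):
        p.fit(X)
    loadings = p.components_.T.copy()
    for c in range(loadings.shape[1]):
        col = loadings[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, c] = -col
    ratios = np.nan_to_num(p.explained_variance_ratio_, nan=0.0)
    return PCAModel(loadings=loadings, explained_variance_ratio=ratios, center=p.mean_.copy())


def pc_score_images(
    cube: Hypercube, mask: np.ndarray, model: PCAModel, n: int = 2
) -> list[np.ndarray]:
    """Project each ROI pixel spectrum onto the first ``n`` loadings.

    Returns one gray-scale score image per component; off-mask pixels are
    set to the image minimum so they read as background.
    """
    if model.loadings.shape[0] != cube.n_bands:
        raise ValueError(
            f"model fitted on {model.loadings.shape[0]} bands, cube has {cube.n_bands}"
        )
    if not 1 <= n <= model.n_components:
        raise ValueError(f"n must be in [1, {model.n_components}]")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.spatial_shape:
        raise ValueError("mask must match the cube's spatial plane")
    scores = model.transform(cube.data[mask])[:, :n]
    images = []
    for c in range(n):
        img = np.full(cube.spatial_shape, scores[:, c].min(), dtype=float)
        img[mask] = scores[:, c]
        images.append(img)
    return images


def quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Linear min-max binning of an image into ``levels`` equal-width gray levels."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("quantize requires finite pixel values")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.intp)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


@dataclass(frozen=True)
class GLCMConfig:
    """Co-occurrence offset and counting options for one (D, theta) pair."""

    distance: int = 1
    angle: int = 0
    levels: int = 64
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.angle not in _ANGLE_OFFSETS:
            raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


@dataclass
class GLCMMatrix:
    """Co-occurrence counts (or frequencies) for one offset."""

    p: np.ndarray
    config: GLCMConfig
    pair_count: int

    def __post_init__(self) -> None:
        if self.config.normalize and self.pair_count > 0:
            total = self.p.sum()
            if abs(total - 1.0) > 1e-12:
                raise ValueError("normalized GLCM must sum to 1")


def glcm(img: np.ndarray, cfg: GLCMConfig, mask: np.ndarray | None = None) -> GLCMMatrix:
    """Count gray-level pairs at offset (distance, angle).

    Ordered pairs (reference pixel, pixel at the offset) are counted; in
    symmetric mode the transpose is added so the matrix is direction-blind.
    With a mask, only pairs whose both pixels lie inside it contribute
    (background excluded).  Normalized output sums to 1.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("glcm expects a 2-D integer image")
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError("glcm expects an integer (quantized) image")
    if img.min() < 0 or img.max() >= cfg.levels:
        raise ValueError(f"gray levels must lie in [0, {cfg.levels})")
    dr, dc = (cfg.distance * o for o in _ANGLE_OFFSETS[cfg.angle])
    h, w = img.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"image {img.shape} smaller than offset ({dr}, {dc})")

    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    i = img[r0, c0].ravel()
    j = img[r1, c1].ravel()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.shape:
            raise ValueError("mask must match the image shape")
        valid = (mask[r0, c0] & mask[r1, c1]).ravel()
        i, j = i[valid], j[valid]
    counts = np.zeros((cfg.levels, cfg.levels), dtype=float)
    np.add.at(counts, (i, j), 1.0)
    n_pairs = i.size
    if cfg.symmetric:
        counts = counts + counts.T
        n_pairs *= 2
    if cfg.normalize:
        total = counts.sum()
        if total > 0:
            counts = counts / total
    return GLCMMatrix(p=counts, config=cfg, pair_count=int(n_pairs))


def glcm_descriptors(P: GLCMMatrix) -> dict[str, float]:
    """Eight Haralick-style scalars of a normalized GLCM.

    With mu_i, mu_j, sigma_i, sigma_j the marginal means/SDs of p(i, j):
    mean = sum i*p; variance = sum (i-mu_i)^2 p; homogeneity =
    sum p/(1+(i-j)^2); contrast = sum (i-j)^2 p; dissimilarity =
    sum |i-j| p; entropy = -sum p ln p (p > 0); second moment = sum p^2;
    correlation = sum (i-mu_i)(j-mu_j) p / (sigma_i sigma_j), defined as 1
    when either marginal SD is 0 (perfectly predictable pairs).
    """
    if not P.config.normalize:
        raise ValueError("glcm_descriptors requires a normalized GLCM")
    p = P.p
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("GLCM entries must sum to 1")
    L = p.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    nz = p[p > 0]
    sigma = math.sqrt(var_i * var_j)
    if sigma == 0:
        correlation = 1.0
    else:
        correlation = float(((i - mu_i) * (j - mu_j) * p).sum() / sigma)
    return {
        "mean": mu_i,
        "variance": var_i,
        "homogeneity": float((p / (1.0 + (i - j) ** 2)).sum()),
        "contrast": float(((i - j) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(i - j) * p).sum()),
        "entropy": float(-(nz * np.log(nz)).sum()),
        "second_moment": float((p**2).sum()),
        "correlation": correlation,
    }


@dataclass
class TextureVector:
    """16 named texture values: 8 descriptors for PC1 then 8 for PC2."""

    values: np.ndarray
    names: tuple[str, ...]

    @classmethod
    def feature_names(cls) -> tuple[str, ...]:
        return tuple(f"pc{c}_{d}" for c in (1, 2) for d in DESCRIPTOR_NAMES)


def texture_vector(
    cube: Hypercube,
    mask: np.ndarray,
    pca_model: PCAModel | None = None,
    distance: int = 1,
    angles: Sequence[int] = (0, 45, 90, 135),
    levels: int = 64,
    symmetric: bool = True,
) -> TextureVector:
    """Full texture pipeline for one sample.

    Fits PCA on the cube's own ROI pixels (unless a model is supplied),
    builds PC1/PC2 score images, quantizes them, and averages the eight
    GLCM descriptors over the requested directions.  GLCMs are computed on
    the ROI bounding box with off-mask pairs excluded.
    """
    mask = np.asarray(mask, dtype=bool)
    if pca_model is None:
        pca_model = pca_fit(cube.data[mask], n_components=2)
    images = pc_score_images(cube, mask, pca_model, n=2)
    rows, cols = np.nonzero(mask)
    box = (slice(rows.min(), rows.max() + 1), slice(cols.min(), cols.max() + 1))
    values: list[float] = []
    for img in images:
        sub = quantize(img[box], levels)
        sub_mask = mask[box]
        acc = np.zeros(len(DESCRIPTOR_NAMES))
        for angle in angles:
            cfg = GLCMConfig(distance=distance, angle=angle, levels=levels, symmetric=symmetric)
            desc = glcm_descriptors(glcm(sub, cfg, mask=sub_mask))
            acc += np.array([desc[name] for name in DESCRIPTOR_NAMES])
        values.extend(acc / len(angles))
    return TextureVector(values=np.array(values), names=TextureVector.feature_names())


def texture_di_regression(features: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Multiple correlation of infestation degree with the 16 texture features.

    Fits an MLR of DI on the feature matrix and returns (R, R^2), where
    R^2 = 1 - SS_res / SS_tot on the fitted data.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float).ravel()
    if features.shape[0] <= features.shape[1] + 1:
        raise ValueError("need more samples than features + 1")
    model = mlr_fit(features, labels)
    resid = labels - model.predict(features)
    ss_tot = float(((labels - labels.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0, 1.0
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return math.sqrt(max(r2, 0.0)), r2
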