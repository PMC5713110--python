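"""Reflectance calibration, band trimming, smoothing and ROI spectra.

The raw pushbroom cube is flat-field calibrated against white (~99.9%
reflectance panel) and dark (shuttered) reference frames,

    R = (I_raw - I_dark) / (I_white - I_dark),

the noisy head/tail bands are trimmed (default 82 head + 22 tail of 512,
leaving 408 bands over roughly 480-1000 nm), spectra are Savitzky-Golay
smoothed, and each sample is represented by the mean spectrum of its stalk
ROI pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .hypercube import Hypercube

__all__ = [
    "SpectraMatrix",
    "calibrate",
    "trim_bands",
    "sg_smooth",
    "roi_mean_spectrum",
    "DEFAULT_TRIM",
]

logger = logging.getLogger(__name__)

#: head/tail band counts removed by default (512 -> 408 bands, ~480-1000 nm)
DEFAULT_TRIM = (82, 22)

#: specular pixels may exceed the white panel; reflectance is capped here
REFLECTANCE_CAP = 1.5


@dataclass
class SpectraMatrix:
    """ROI-mean reflectance spectra: N samples by K bands, with DI labels."""

    values: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, k = self.values.shape
        if len(self.sample_ids) != n or self.labels.size != n:
            raise ValueError("sample_ids and labels must match the number of rows")
        if self.wavelengths.size != k:
            raise ValueError("wavelength axis must match the number of columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=[f"{w:.2f}" for w in self.wavelengths])
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraMatrix":
        df = pd.read_csv(path)
        wl = np.array([float(c) for c in df.columns[2:]])
        return cls(
            values=df.iloc[:, 2:].to_numpy(float),
            wavelengths=wl,
            sample_ids=df["sample_id"].astype(str).tolist(),
            labels=df["label"].to_numpy(int),
        )


def calibrate(raw: Hypercube, white: np.ndarray, dark: np.ndarray) -> Hypercube:
    """Flat-field calibrate a raw cube to reflectance.

    ``white``/``dark`` may be full cubes or single ``(samples, bands)``
    frames, which are broadcast along the scan axis.  Cells where
    ``white == dark`` (dead pixels) are set to 0 and logged; the result is
    clipped to [0, 1.5] to tolerate specular highlights.
    """
    if raw.calibrated:
        raise ValueError("cube is already calibrated")
    # keep single precision if the cube came in single precision
    work_dtype = raw.data.dtype if raw.data.dtype in (np.float32, np.float64) else np.float64
    white = np.asarray(white, dtype=work_dtype)
    dark = np.asarray(dark, dtype=work_dtype)
    for name, frame in (("white", white), ("dark", dark)):
        if frame.shape[-1] != raw.n_bands:
            raise ValueError(f"{name} frame band count {frame.shape[-1]} != cube bands {raw.n_bands}")
        if frame.ndim == 3 and frame.shape != raw.data.shape:
            raise ValueError(f"{name} cube shape {frame.shape} != raw shape {raw.data.shape}")
        if frame.ndim == 2 and frame.shape[0] != raw.data.shape[1]:
            raise ValueError(f"{name} frame width {frame.shape[0]} != cube samples {raw.data.shape[1]}")
        if frame.ndim not in (2, 3):
            raise ValueError(f"{name} frame must be 2-D or 3-D")
    if white.ndim == 2:
        white = white[None, :, :]
    if dark.ndim == 2:
        dark = dark[None, :, :]
    denom = white - dark
    dead = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data.astype(work_dtype, copy=False) - dark) / np.where(dead, 1.0, denom)
    dead = np.broadcast_to(dead, refl.shape)
    n_dead = int(dead.sum())
    if n_dead:
        logger.warning("calibrate: %d dead (white==dark) cells set to 0", n_dead)
        refl = np.where(dead, 0.0, refl)
    refl = np.clip(refl, 0.0, REFLECTANCE_CAP)
    return Hypercube(refl, raw.wavelengths.copy(), calibrated=True)


def trim_bands(obj: Hypercube | SpectraMatrix, n_head: int, n_tail: int):
    """Drop ``n_head`` leading and ``n_tail`` trailing bands (cube or spectra)."""
    if n_head < 0 or n_tail < 0:
        raise ValueError("trim counts must be non-negative")
    if isinstance(obj, Hypercube):
        k = obj.n_bands
    elif isinstance(obj, SpectraMatrix):
        k = obj.n_bands
    else:
        raise TypeError("trim_bands expects a Hypercube or SpectraMatrix")
    if n_head + n_tail >= k:
        raise ValueError(f"cannot trim {n_head}+{n_tail} bands from {k}")
    stop = k - n_tail
    if isinstance(obj, Hypercube):
        return Hypercube(obj.data[:, :, n_head:stop], obj.wavelengths[n_head:stop], calibrated=obj.calibrated)
    return replace(
        obj,
        values=obj.values[:, n_head:stop],
        wavelengths=obj.wavelengths[n_head:stop],
        sample_ids=list(obj.sample_ids),
        labels=obj.labels.copy(),
    )


def sg_smooth(spectra: SpectraMatrix | np.ndarray, window: int = 9, polyorder: int = 3):
    """Savitzky-Golay smooth each spectrum along the band axis.

    Edges are handled by fitting the polynomial on the truncated window
    (no reflection padding).  Accepts a SpectraMatrix or a plain 1-D/2-D
    array and returns the same kind.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if isinstance(spectra, SpectraMatrix):
        smoothed = savgol_filter(spectra.values, window, polyorder, axis=1, mode="interp")
        return replace(
            spectra,
            values=smoothed,
            wavelengths=spectra.wavelengths.copy(),
            sample_ids=list(spectra.sample_ids),
            labels=spectra.labels.copy(),
        )
    arr = np.asarray(spectra, dtype=float)
    return savgol_filter(arr, window, polyorder, axis=-1, mode="interp")


def roi_mean_spectrum(cube: Hypercube, mask: np.ndarray) -> np.ndarray:
    """Average the spectra of all ROI pixels into one representative spectrum."""
    if not cube.calibrated:
        raise ValueError("roi_mean_spectrum requires a calibrated cube")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.spatial_shape:
        raise ValueError(f"mask shape {mask.shape} != cube spatial plane {cube.spatial_shape}")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return cube.data[mask].mean(axis=0)
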