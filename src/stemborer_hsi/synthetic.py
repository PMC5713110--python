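"""Synthetic hyperspectral scenes of rice stalks under stem-borer attack.

Generates labeled raw-count hypercubes (with white/dark reference frames and
stalk ROI masks) for six infestation degrees, DI0 (healthy) through DI5
(infested 10 days).  The class structure mirrors what visible/NIR imaging of
borer-damaged stalks shows:

* chlorophyll breakdown raises visible (570-700 nm) reflectance as damage
  progresses (DI3-DI5), while the early compensation response of the plant
  pushes DI1/DI2 slightly *below* the healthy curve;
* structural collapse of the stem lowers NIR (750-1000 nm) reflectance with
  severity, with DI1/DI2 again on the opposite side of healthy;
* feeding lesions add spatial texture whose density and contrast grow with
  severity (darker patches in the NIR, brighter in the red).

Raw counts are synthesized so that flat-field calibration
``(raw - dark) / (white - dark)`` recovers the underlying reflectance; the
calibration step downstream is therefore genuinely exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .hypercube import Hypercube, write_envi

__all__ = [
    "SceneConfig",
    "LabeledCube",
    "class_mean_spectrum",
    "generate_scene",
    "iter_dataset",
    "generate_dataset",
    "save_dataset",
]

N_CLASSES = 6

# Visible and NIR windows (nm) over which the class effects act.
_VIS_WINDOW = (570.0, 700.0)
_NIR_WINDOW = (750.0, 1000.0)
_RED_WINDOW = (600.0, 700.0)  # lesion brightening band


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for the synthetic dataset.

    Defaults reproduce the laboratory design this pipeline targets: 365
    stalk samples across six infestation degrees (45, 69, 69, 69, 69, 44),
    imaged in 512 bands over 380-1030 nm.

    ``vis_effect``/``nir_effect`` are per-class reflectance offsets applied
    over the 570-700 nm and 750-1000 nm windows.  They must encode the
    compensation effect: DI1/DI2 below healthy in the visible and above it
    in the NIR, with the severe degrees trending monotonically the other
    way.  ``texture_scale`` controls lesion density/contrast per class.

    Per-sample biological variation (multiplicative gain, severity jitter,
    smooth baseline wiggle) keeps same-class samples from being identical;
    set ``gain_sd``/``effect_jitter_sd``/``baseline_sd`` to 0 along with
    ``noise_sd`` for exact, noise-free scenes.
    """

    n_bands: int = 512
    wavelength_range: tuple[float, float] = (380.0, 1030.0)
    image_shape: tuple[int, int] = (64, 64)
    class_counts: tuple[int, ...] = (45, 69, 69, 69, 69, 44)
    vis_effect: tuple[float, ...] = (0.0, -0.020, -0.010, 0.020, 0.045, 0.070)
    nir_effect: tuple[float, ...] = (0.0, 0.030, 0.015, -0.030, -0.065, -0.100)
    texture_scale: tuple[float, ...] = (0.05, 0.20, 0.35, 0.50, 0.70, 0.90)
    noise_sd: float = 0.01
    gain_sd: float = 0.01
    effect_jitter_sd: float = 0.10
    baseline_sd: float = 0.003
    texture_jitter_sd: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ValueError("n_bands must be at least 2")
        lo, hi = self.wavelength_range
        if not lo < hi:
            raise ValueError("wavelength_range must be increasing")
        if len(self.class_counts) != N_CLASSES:
            raise ValueError("class_counts must have exactly 6 entries")
        if any(c < 0 for c in self.class_counts) or sum(self.class_counts) <= 0:
            raise ValueError("class_counts must be non-negative with positive sum")
        for name in ("vis_effect", "nir_effect", "texture_scale"):
            if len(getattr(self, name)) != N_CLASSES:
                raise ValueError(f"{name} must have exactly 6 entries")
        v, n = self.vis_effect, self.nir_effect
        if not (v[1] < v[0] and v[2] < v[0]):
            raise ValueError("vis_effect must place DI1 and DI2 below DI0 (compensation effect)")
        if any(v[i + 1] < v[i] for i in range(2, N_CLASSES - 1)):
            raise ValueError("vis_effect must be non-decreasing over DI2..DI5")
        if not (n[1] > n[0] and n[2] > n[0]):
            raise ValueError("nir_effect must place DI1 and DI2 above DI0 (compensation effect)")
        if any(n[i + 1] > n[i] for i in range(2, N_CLASSES - 1)):
            raise ValueError("nir_effect must be non-increasing over DI2..DI5")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise ValueError("image_shape must be positive")

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi = self.wavelength_range
        return np.linspace(lo, hi, self.n_bands)

    @property
    def n_samples(self) -> int:
        return int(sum(self.class_counts))


@dataclass
class LabeledCube:
    """One synthetic sample: raw cube, reference frames, ROI mask, DI label."""

    cube: Hypercube
    white: np.ndarray  # (samples, bands), broadcast along the scan axis
    dark: np.ndarray
    roi_mask: np.ndarray
    label: int

    def __post_init__(self) -> None:
        bands = self.cube.n_bands
        if self.white.shape[-1] != bands or self.dark.shape[-1] != bands:
            raise ValueError("white/dark frames must share the cube's band dimension")
        if self.roi_mask.shape != self.cube.spatial_shape:
            raise ValueError("roi_mask must match the cube's spatial plane")
        if not self.roi_mask.any():
            raise ValueError("roi_mask must contain at least one true pixel")
        if not 0 <= self.label < N_CLASSES:
            raise ValueError("label must be a DI class in 0..5")


def _smooth_window(wl: np.ndarray, lo: float, hi: float, width: float = 5.0) -> np.ndarray:
    """Raised-logistic bandpass weight: ~1 inside [lo, hi], smooth 0 outside."""
    return 1.0 / (1.0 + np.exp(-(wl - lo) / width)) / (1.0 + np.exp((wl - hi) / width))


def base_spectrum(wl: np.ndarray) -> np.ndarray:
    """Analytic healthy-stalk reflectance curve.

    Green peak near 550 nm, chlorophyll absorption well near 670 nm, red edge
    near 715 nm rising to an NIR plateau, water absorption dip near 970 nm.
    """
    wl = np.asarray(wl, dtype=float)
    r = (
        0.06
        + 0.10 * np.exp(-(((wl - 550.0) / 40.0) ** 2))
        - 0.02 * np.exp(-(((wl - 670.0) / 22.0) ** 2))
        + 0.48 / (1.0 + np.exp(-(wl - 715.0) / 16.0))
        - 0.05 * np.exp(-(((wl - 970.0) / 28.0) ** 2))
    )
    return np.clip(r, 0.0, 1.0)


def class_mean_spectrum(di: int, cfg: SceneConfig) -> np.ndarray:
    """Mean stalk reflectance of infestation degree ``di`` on cfg's wavelength axis."""
    if not 0 <= di < N_CLASSES:
        raise ValueError(f"di must be in 0..5, got {di}")
    wl = cfg.wavelengths
    r = (
        base_spectrum(wl)
        + cfg.vis_effect[di] * _smooth_window(wl, *_VIS_WINDOW)
        + cfg.nir_effect[di] * _smooth_window(wl, *_NIR_WINDOW)
    )
    return np.clip(r, 0.0, 1.0)


def _stalk_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Elongated wavy vertical stalk covering ~20% of the image."""
    h, w = shape
    rows = np.arange(h)
    freq = rng.uniform(0.5, 1.5)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    center = w / 2.0 + (w / 8.0) * np.sin(2.0 * math.pi * freq * rows / max(h, 1) + phase)
    halfwidth = max(w * 0.10, 1.0) * (1.0 + 0.15 * np.sin(4.0 * math.pi * rows / max(h, 1) + phase))
    cols = np.arange(w)
    mask = np.abs(cols[None, :] - center[:, None]) <= halfwidth[:, None]
    if not mask.any():  # degenerate tiny images: keep the centre pixel
        mask[h // 2, w // 2] = True
    return mask


def _lamp_counts(wl: np.ndarray) -> np.ndarray:
    """Halogen-lamp-like signal level (arbitrary counts) over the band axis."""
    return 3500.0 * (0.25 + 0.75 * np.exp(-(((wl - 760.0) / 260.0) ** 2)))


def generate_scene(di: int, cfg: SceneConfig, rng: np.random.Generator) -> LabeledCube:
    """Generate one raw-count scene of class ``di``.

    ROI pixels carry the class mean spectrum (with per-sample gain/severity/
    baseline variation) modulated by a multiplicative lesion field and
    additive pixel noise; the background is a flat conveyor-belt spectrum.
    Counts are synthesized from the white/dark frames so that flat-field
    calibration recovers reflectance.
    """
    if not 0 <= di < N_CLASSES:
        raise ValueError(f"di must be in 0..5, got {di}")
    h, w = cfg.image_shape
    wl = cfg.wavelengths
    k = cfg.n_bands

    mask = _stalk_mask((h, w), rng)

    # Per-sample biological variation.
    gain = 1.0 + cfg.gain_sd * rng.standard_normal()
    jitter = 1.0 + cfg.effect_jitter_sd * rng.standard_normal()
    t = (wl - wl[0]) / (wl[-1] - wl[0]) * 2.0 - 1.0
    a0, a1, a2 = rng.standard_normal(3)
    baseline = cfg.baseline_sd * (a0 + a1 * t + a2 * (2.0 * t**2 - 1.0))
    spectrum = (
        base_spectrum(wl)
        + jitter
        * (
            cfg.vis_effect[di] * _smooth_window(wl, *_VIS_WINDOW)
            + cfg.nir_effect[di] * _smooth_window(wl, *_NIR_WINDOW)
        )
    ) * gain + baseline
    spectrum = np.clip(spectrum, 0.0, 1.0)

    # Lesion texture: soft-thresholded smoothed noise, density and contrast
    # growing with the class texture scale; brighter in the red, darker in NIR.
    ts = cfg.texture_scale[di]
    if ts > 0:
        ts = max(ts * (1.0 + cfg.texture_jitter_sd * rng.standard_normal()), 0.0)
    # lesion patches grow with severity: small scattered spots early, large
    # coalescing blotches late
    field = rng.standard_normal((h, w))
    field = gaussian_filter(field, sigma=1.0 + 3.0 * min(ts, 1.5))
    sd = field.std()
    if sd > 0:
        field = (field - field.mean()) / sd
    background = (0.22 + 0.01 * np.sin(wl / 60.0)).astype(np.float32)
    refl = np.broadcast_to(background, (h, w, k)).copy()
    plant = spectrum.astype(np.float32)
    if ts > 0:
        density = 0.04 + 0.28 * ts
        depth = 0.06 + 0.40 * ts
        thr = np.quantile(field, 1.0 - density)
        lesion = (1.0 / (1.0 + np.exp(-(field - thr) / 0.25))).astype(np.float32)
        signature = (
            0.6 * depth * _smooth_window(wl, *_RED_WINDOW) - depth * _smooth_window(wl, *_NIR_WINDOW)
        ).astype(np.float32)
        refl[mask] = plant[None, :] * (1.0 + lesion[mask][:, None] * signature[None, :])
    else:
        refl[mask] = plant[None, :]
    if cfg.noise_sd > 0:
        refl += np.float32(cfg.noise_sd) * rng.standard_normal((h, w, k), dtype=np.float32)
    refl = np.clip(refl, 0.0, 1.3)

    # Reference frames: one cross-track line each, broadcast along the scan axis.
    lamp = _lamp_counts(wl)
    col_gain = 1.0 + 0.02 * np.sin(np.linspace(0.0, 2.0 * math.pi, w))
    dark = (np.full((w, k), 100.0) + 2.0 * np.sin(wl / 45.0)[None, :]).astype(np.float32)
    white = (dark + (lamp[None, :] * col_gain[:, None]).astype(np.float32)).astype(np.float32)
    raw = dark[None, :, :] + refl * (white - dark)[None, :, :]

    cube = Hypercube(raw, wl, calibrated=False)
    return LabeledCube(cube=cube, white=white.astype(np.float32), dark=dark.astype(np.float32), roi_mask=mask, label=di)


def _shuffled_labels(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    labels = np.repeat(np.arange(N_CLASSES), cfg.class_counts)
    rng.shuffle(labels)
    return labels


def iter_dataset(cfg: SceneConfig) -> Iterator[LabeledCube]:
    """Yield the full labeled dataset one cube at a time (memory-friendly).

    Sample order is label-blocked then shuffled by the config seed; each cube
    draws from an independent child stream so the sequence is reproducible.
    """
    ss = np.random.SeedSequence(cfg.seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    labels = _shuffled_labels(cfg, order_rng)
    children = ss.spawn(len(labels) + 1)[1:]
    for label, child in zip(labels, children):
        yield generate_scene(int(label), cfg, np.random.default_rng(child))


def generate_dataset(cfg: SceneConfig) -> list[LabeledCube]:
    """Materialize the whole dataset as a list (use iter_dataset for large configs)."""
    return list(iter_dataset(cfg))


def save_dataset(cfg: SceneConfig, out_dir: str | Path) -> Path:
    """Write the dataset as ENVI cube files plus a label sheet and config file.

    Layout: ``sample_XXX.img``/``.img.hdr`` per cube (with ``_white``/``_dark``
    reference frames and a ``_mask`` raster), ``labels.csv`` (sample_id, DI)
    and ``scene_config.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, sample in enumerate(iter_dataset(cfg)):
        stem = f"sample_{idx:03d}"
        write_envi(sample.cube, out_dir / f"{stem}.img")
        np.savetxt(out_dir / f"{stem}_white.csv", sample.white, delimiter=",")
        np.savetxt(out_dir / f"{stem}_dark.csv", sample.dark, delimiter=",")
        np.savetxt(out_dir / f"{stem}_mask.csv", sample.roi_mask.astype(np.uint8), fmt="%d", delimiter=",")
        rows.append(f"{stem},{sample.label}")
    (out_dir / "labels.csv").write_text("sample_id,DI\n" + "\n".join(rows) + "\n")
    cfg_dict = {
        "n_bands": cfg.n_bands,
        "wavelength_range": list(cfg.wavelength_range),
        "image_shape": list(cfg.image_shape),
        "class_counts": list(cfg.class_counts),
        "vis_effect": list(cfg.vis_effect),
        "nir_effect": list(cfg.nir_effect),
        "texture_scale": list(cfg.texture_scale),
        "noise_sd": cfg.noise_sd,
        "gain_sd": cfg.gain_sd,
        "effect_jitter_sd": cfg.effect_jitter_sd,
        "baseline_sd": cfg.baseline_sd,
        "texture_jitter_sd": cfg.texture_jitter_sd,
        "seed": cfg.seed,
    }
    (out_dir / "scene_config.yaml").write_text(yaml.safe_dump(cfg_dict, sort_keys=False))
    return out_dir
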