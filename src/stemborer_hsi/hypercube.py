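"""Hyperspectral cube container and ENVI-style flat-binary I/O.

A hypercube stores a pushbroom scan as a ``(lines, samples, bands)`` array
together with its wavelength axis in nanometres.  Raw cubes hold detector
counts; calibrated cubes hold reflectance (see
:func:`stemborer_hsi.preprocess.calibrate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Hypercube", "read_envi", "write_envi"]


@dataclass
class Hypercube:
    """A ``(lines, samples, bands)`` image stack with a wavelength axis.

    Parameters
    ----------
    data:
        3-D array, spatial plane first, spectral axis last.  Raw counts or
        reflectance depending on ``calibrated``.
    wavelengths:
        Band centres in nm, strictly increasing, one per band.
    calibrated:
        True once the cube has been converted to reflectance.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D (lines, samples, bands), got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.data.shape[2]:
            raise ValueError(
                f"wavelength axis length {self.wavelengths.size} does not match "
                f"band count {self.data.shape[2]}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.calibrated:
            if not np.all(np.isfinite(self.data)):
                raise ValueError("calibrated cube contains non-finite values")
            if np.min(self.data) < 0:
                raise ValueError("calibrated reflectance must be non-negative")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def copy(self) -> "Hypercube":
        return replace(self, data=self.data.copy(), wavelengths=self.wavelengths.copy())


# ENVI data-type codes for the dtypes we emit/accept.
_ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16, 2: np.int16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def write_envi(cube: Hypercube, path: str | Path) -> Path:
    """Write a cube as ENVI flat binary (BSQ interleave) plus a text header.

    ``path`` names the binary file; the header is written alongside as
    ``<path>.hdr``.  Returns the header path.
    """
    path = Path(path)
    data = cube.data
    if data.dtype not in _DTYPE_CODES:
        data = data.astype(np.float32)
    lines, samples, bands = data.shape
    # BSQ: band-sequential, i.e. (bands, lines, samples) on disk.
    np.ascontiguousarray(np.moveaxis(data, 2, 0)).tofile(path)
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr = path.with_suffix(path.suffix + ".hdr")
    hdr.write_text(
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[data.dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"calibrated = {int(cube.calibrated)}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return hdr


def _parse_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf: list[str] = []
    in_braces = False
    for line in text.splitlines():
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and "}" not in value:
            buf = [value]
            in_braces = True
        else:
            fields[key] = value
    return fields


def read_envi(header_path: str | Path) -> Hypercube:
    """Read an ENVI header + BSQ/BIL/BIP flat binary pair written by this package."""
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    dtype = _ENVI_DTYPES[int(fields.get("data type", "4"))]
    interleave = fields.get("interleave", "bsq").lower()
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array([float(w) for w in wl_text.replace(",", " ").split()])
    binary = header_path.with_suffix("") if header_path.suffix == ".hdr" else header_path
    raw = np.fromfile(binary, dtype=dtype, count=lines * samples * bands)
    if interleave == "bsq":
        data = np.moveaxis(raw.reshape(bands, lines, samples), 0, 2)
    elif interleave == "bil":
        data = np.moveaxis(raw.reshape(lines, bands, samples), 1, 2)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    calibrated = bool(int(fields.get("calibrated", "0")))
    return Hypercube(np.ascontiguousarray(data), wavelengths, calibrated=calibrated)
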