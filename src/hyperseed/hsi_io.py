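"""ENVI-style hyperspectral cube I/O and band/wavelength calibration.

A hyperspectral cube is a ``lines x samples x bands`` reflectance array
stored on disk as a raw binary payload plus a plain-text ``.hdr`` header.
Three interleaves are supported:

* ``bsq`` (band sequential): on-disk axis order (bands, lines, samples)
* ``bil`` (band interleaved by line): (lines, bands, samples)
* ``bip`` (band interleaved by pixel): (lines, samples, bands)

Band indices are 1-based throughout the public API, matching the
numbering used by benchtop imagers (band 23 is the lower edge of the
blue window, band 292 the upper edge of the red window).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "HyperCube",
    "WavelengthCalibration",
    "default_calibration",
    "read_envi_cube",
    "write_envi_cube",
    "EnviFormatError",
    "EnviCorruptionError",
]

# ENVI numeric data-type codes <-> numpy dtypes (little-endian default).
_DTYPE_CODES: dict[int, str] = {
    1: "u1",
    2: "i2",
    3: "i4",
    4: "f4",
    5: "f8",
    12: "u2",
    13: "u4",
    14: "i8",
    15: "u8",
}
_CODE_FOR_DTYPE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}

_INTERLEAVES = ("bil", "bip", "bsq")

# Printed calibration anchors for the Pika-class imager driving the
# default band->wavelength model: the six window endpoints
# (band index, wavelength nm) of the red / green / blue display ranges.
CALIBRATION_ANCHORS: tuple[tuple[int, float], ...] = (
    (23, 421.29),
    (44, 448.94),
    (76, 491.19),
    (127, 558.79),
    (173, 620.05),
    (292, 779.75),
)

DEFAULT_BAND_COUNT = 462


class EnviFormatError(ValueError):
    """Header is missing required keys or declares unsupported values."""


class EnviCorruptionError(IOError):
    """Binary payload length disagrees with the header declaration."""


@dataclass(frozen=True)
class WavelengthCalibration:
    """Band-index -> wavelength mapping, explicit per-band or linear.

    Parameters
    ----------
    mode:
        ``"explicit"`` (tabulated per-band wavelengths) or ``"linear"``
        (``wavelength = offset_nm + step_nm * band`` with 1-based band).
    wavelengths_nm:
        Strictly increasing per-band list (explicit mode only).
    offset_nm, step_nm:
        Line parameters (linear mode only); ``step_nm > 0``.
    n_bands:
        Number of calibrated bands.
    """

    mode: str
    n_bands: int
    wavelengths_nm: tuple[float, ...] | None = None
    offset_nm: float | None = None
    step_nm: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("explicit", "linear"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if self.mode == "explicit":
            if self.wavelengths_nm is None or len(self.wavelengths_nm) != self.n_bands:
                raise ValueError("explicit mode needs one wavelength per band")
            w = np.asarray(self.wavelengths_nm)
            if self.n_bands > 1 and not np.all(np.diff(w) > 0):
                raise ValueError("wavelengths must be strictly increasing")
        else:
            if self.offset_nm is None or self.step_nm is None:
                raise ValueError("linear mode needs offset_nm and step_nm")
            if self.step_nm <= 0:
                raise ValueError("step_nm must be > 0")

    def wavelength_of_band(self, band: int) -> float:
        """Wavelength in nm of a 1-based band index."""
        if not 1 <= band <= self.n_bands:
            raise ValueError(f"band {band} outside calibrated range 1..{self.n_bands}")
        if self.mode == "explicit":
            return float(self.wavelengths_nm[band - 1])
        return float(self.offset_nm + self.step_nm * band)

    def band_of_wavelength(self, wavelength_nm: float) -> int:
        """Nearest 1-based band index for a wavelength (clamped to range)."""
        if self.mode == "linear":
            b = round((wavelength_nm - self.offset_nm) / self.step_nm)
            return int(min(max(b, 1), self.n_bands))
        w = np.asarray(self.wavelengths_nm)
        return int(np.argmin(np.abs(w - wavelength_nm))) + 1

    def wavelengths(self) -> np.ndarray:
        """All calibrated wavelengths as a float array of length n_bands."""
        if self.mode == "explicit":
            return np.asarray(self.wavelengths_nm, dtype=float)
        bands = np.arange(1, self.n_bands + 1)
        return self.offset_nm + self.step_nm * bands


def default_calibration(n_bands: int = DEFAULT_BAND_COUNT) -> WavelengthCalibration:
    """Linear calibration fitted to the six printed window endpoints.

    Least-squares line through ``CALIBRATION_ANCHORS``; residuals are all
    below one band step (~1.33 nm), so printed band/wavelength pairs are
    reproduced to within the imager's own quantization.
    """
    b = np.array([p[0] for p in CALIBRATION_ANCHORS], dtype=float)
    lam = np.array([p[1] for p in CALIBRATION_ANCHORS], dtype=float)
    A = np.vstack([b, np.ones_like(b)]).T
    (step, offset), *_ = np.linalg.lstsq(A, lam, rcond=None)
    return WavelengthCalibration(
        mode="linear", n_bands=n_bands, offset_nm=float(offset), step_nm=float(step)
    )


@dataclass
class HyperCube:
    """In-memory hyperspectral cube.

    ``data`` is always held as ``(lines, samples, bands)`` regardless of
    the on-disk interleave, which is kept only as serialization metadata.
    """

    data: np.ndarray
    interleave: str = "bil"
    calibration: WavelengthCalibration | None = None
    extra_header: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (lines, samples, bands)")
        if min(self.data.shape) < 1:
            raise ValueError("all cube dimensions must be >= 1")
        if self.interleave not in _INTERLEAVES:
            raise ValueError(f"interleave must be one of {_INTERLEAVES}")
        if self.calibration is not None and self.calibration.n_bands != self.n_bands:
            raise ValueError("calibration band count does not match cube")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_image(self, band: int) -> np.ndarray:
        """One spectral slice as a (lines, samples) array; 1-based band."""
        if not 1 <= band <= self.n_bands:
            raise ValueError(f"band {band} outside 1..{self.n_bands}")
        return self.data[:, :, band - 1]

    def wavelength_of_band(self, band: int) -> float:
        if self.calibration is None:
            raise ValueError("cube has no wavelength calibration")
        return self.calibration.wavelength_of_band(band)


def _to_disk_order(data: np.ndarray, interleave: str) -> np.ndarray:
    if interleave == "bsq":
        return np.transpose(data, (2, 0, 1))
    if interleave == "bil":
        return np.transpose(data, (0, 2, 1))
    return data  # bip


def _from_disk_order(raw: np.ndarray, interleave: str) -> np.ndarray:
    if interleave == "bsq":
        return np.transpose(raw, (1, 2, 0))
    if interleave == "bil":
        return np.transpose(raw, (0, 2, 1))
    return raw


_REQUIRED_KEYS = ("samples", "lines", "bands", "interleave", "data type")


def _parse_header(text: str) -> dict[str, str]:
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("missing ENVI magic line")
    body = text.lstrip()[4:]
    # Collapse { ... } blocks (possibly multi-line) before splitting lines.
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([^={}\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1].strip()
        fields[key] = val
    return fields


def read_envi_cube(header_path: str | Path) -> HyperCube:
    """Read an ENVI header + binary payload pair into a :class:`HyperCube`.

    The payload path is taken from the header's ``data file`` key if
    present, else the header path with its suffix replaced by the
    interleave name (``.bil``/``.bip``/``.bsq``), else ``.img``.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    fields = _parse_header(header_path.read_text())

    missing = [k for k in _REQUIRED_KEYS if k not in fields]
    if missing:
        raise EnviFormatError(f"header missing required keys: {missing}")

    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    code = int(fields["data type"])
    if code not in _DTYPE_CODES:
        raise EnviFormatError(f"unsupported ENVI data type code {code}")
    byte_order = int(fields.get("byte order", "0"))
    dtype = np.dtype(("<" if byte_order == 0 else ">") + _DTYPE_CODES[code])

    if "data file" in fields:
        data_path = header_path.parent / fields["data file"]
    else:
        data_path = None
        for ext in (f".{interleave}", ".img", ".raw", ".dat"):
            cand = header_path.with_suffix(ext)
            if cand.exists():
                data_path = cand
                break
        if data_path is None:
            raise FileNotFoundError(f"no binary payload found next to {header_path}")

    payload = np.fromfile(data_path, dtype=dtype)
    expected = samples * lines * bands
    if payload.size != expected:
        raise EnviCorruptionError(
            f"payload has {payload.size} elements, header declares {expected}"
        )

    shapes = {
        "bsq": (bands, lines, samples),
        "bil": (lines, bands, samples),
        "bip": (lines, samples, bands),
    }
    data = _from_disk_order(payload.reshape(shapes[interleave]), interleave)

    calibration = None
    if "wavelength" in fields:
        wl = tuple(float(v) for v in fields["wavelength"].replace("\n", " ").split(",") if v.strip())
        if len(wl) != bands:
            raise EnviFormatError("wavelength list length does not match band count")
        calibration = WavelengthCalibration(mode="explicit", n_bands=bands, wavelengths_nm=wl)

    known = set(_REQUIRED_KEYS) | {"byte order", "wavelength", "data file", "header offset"}
    extra = {k: v for k, v in fields.items() if k not in known}
    return HyperCube(data=data, interleave=interleave, calibration=calibration, extra_header=extra)


def write_envi_cube(cube: HyperCube, path: str | Path) -> Path:
    """Write a cube as ``<path>.hdr`` + raw payload; returns the header path.

    ``path`` may carry the interleave suffix already or be a bare stem.
    Round-trips bit-exactly through :func:`read_envi_cube` for all three
    interleaves; explicit wavelength lists and unknown header keys are
    preserved verbatim.
    """
    path = Path(path)
    if path.suffix.lower() in {".bil", ".bip", ".bsq", ".img", ".hdr"}:
        stem = path.with_suffix("")
    else:
        stem = path
    data_path = stem.with_suffix(f".{cube.interleave}")
    header_path = stem.with_suffix(".hdr")

    dtype = cube.data.dtype.newbyteorder("<")
    if np.dtype(dtype.str.lstrip("<>=|")) not in _CODE_FOR_DTYPE and dtype not in _CODE_FOR_DTYPE:
        raise EnviFormatError(f"dtype {cube.data.dtype} has no ENVI type code")
    code = _CODE_FOR_DTYPE[np.dtype(dtype.str.lstrip("<>=|"))]

    disk = np.ascontiguousarray(_to_disk_order(cube.data, cube.interleave), dtype=dtype)
    disk.tofile(data_path)

    lines = [
        "ENVI",
        f"samples = {cube.samples}",
        f"lines = {cube.lines}",
        f"bands = {cube.n_bands}",
        "header offset = 0",
        f"data type = {code}",
        f"interleave = {cube.interleave}",
        "byte order = 0",
        f"data file = {data_path.name}",
    ]
    cal = cube.calibration
    if cal is not None:
        wl = ", ".join(repr(float(w)) for w in cal.wavelengths())
        lines.append("wavelength = {" + wl + "}")
    for k, v in cube.extra_header.items():
        lines.append(f"{k} = {v}")
    header_path.write_text("\n".join(lines) + "\n")
    return header_path
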