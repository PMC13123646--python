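"""Hyperspectral cube I/O and reflectance calibration.

Cubes live on disk as a flat little-endian binary file next to a plain-text
ENVI-style header (``key = value`` lines, ``wavelength = { ... }`` list).
In memory the canonical layout is ``(rows, cols, bands)`` float/uint arrays
with a strictly increasing wavelength axis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CalibrationError, DimensionError, FormatError, HsisasError

__all__ = [
    "SpectralAxis",
    "RawCube",
    "ReflectanceCube",
    "default_axis",
    "read_cube",
    "write_cube",
    "calibrate",
    "nearest_band",
]

# ENVI numeric codes for the two supported on-disk dtypes.
_DTYPE_TO_ENVI = {np.dtype("<u2"): 12, np.dtype("<f4"): 4}
_ENVI_TO_DTYPE = {12: np.dtype("<u2"), 4: np.dtype("<f4")}

DEFAULT_L = 512
DEFAULT_RANGE_NM = (900.0, 1700.0)
DEFAULT_CLIP_MAX = 2.0


@dataclass(frozen=True)
class SpectralAxis:
    """Ordered band-center wavelengths in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise FormatError("wavelength axis must be a non-empty 1-D sequence")
        if not np.all(np.diff(wl) > 0):
            raise FormatError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", wl)

    @property
    def L(self) -> int:
        return int(self.wavelengths_nm.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.L == other.L and np.allclose(
            self.wavelengths_nm, other.wavelengths_nm
        )


def default_axis(L: int = DEFAULT_L) -> SpectralAxis:
    """The instrument axis: ``L`` bands linearly spaced over 900-1700 nm."""
    return SpectralAxis(np.linspace(*DEFAULT_RANGE_NM, L))


@dataclass
class RawCube:
    """Detector counts, shape (rows, cols, L)."""

    data: np.ndarray
    axis: SpectralAxis

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionError(f"cube must be 3-D, got shape {self.data.shape}")
        if self.data.shape[2] != self.axis.L:
            raise DimensionError(
                f"band dimension {self.data.shape[2]} != axis length {self.axis.L}"
            )
        if np.any(self.data < 0):
            raise FormatError("raw counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ReflectanceCube:
    """Calibrated unitless reflectance, shape (rows, cols, L).

    ``qc_mask`` flags pixels where the calibration denominator was degenerate
    and the value was imputed to 0.
    """

    data: np.ndarray
    axis: SpectralAxis
    provenance: dict = field(default_factory=dict)
    qc_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionError(f"cube must be 3-D, got shape {self.data.shape}")
        if self.data.shape[2] != self.axis.L:
            raise DimensionError(
                f"band dimension {self.data.shape[2]} != axis length {self.axis.L}"
            )
        if not np.all(np.isfinite(self.data)):
            raise HsisasError("reflectance cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# ENVI-style header + flat binary I/O
# ---------------------------------------------------------------------------

def _parse_header(text: str) -> dict:
    # collapse { ... } blocks onto one line before splitting key = value
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_cube(path: str | Path, header_path: str | Path | None = None) -> RawCube:
    """Read a cube from a flat binary + ENVI-style text header.

    ``header_path`` defaults to ``path`` with a ``.hdr`` suffix appended.
    The on-disk interleave (``bsq`` or ``bil``) is normalised to the
    canonical ``(rows, cols, bands)`` order.
    """
    path = Path(path)
    header_path = Path(header_path) if header_path else path.with_suffix(
        path.suffix + ".hdr"
    )
    if not header_path.exists():
        raise FormatError(f"missing header file: {header_path}")
    fields = _parse_header(header_path.read_text())

    for required in ("samples", "lines", "bands", "interleave", "data type"):
        if required not in fields:
            raise FormatError(f"header missing required field '{required}'")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    if interleave not in ("bsq", "bil"):
        raise FormatError(f"unsupported interleave '{interleave}'")
    code = int(fields["data type"])
    if code not in _ENVI_TO_DTYPE:
        raise FormatError(f"unsupported ENVI data type code {code}")
    dtype = _ENVI_TO_DTYPE[code]

    if "wavelength" not in fields:
        raise FormatError("header missing wavelength list")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array(
        [float(tok) for tok in re.split(r"[,\s]+", wl_text.strip()) if tok],
        dtype=float,
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"wavelength count {wavelengths.size} != bands {bands}"
        )

    raw = np.fromfile(path, dtype=dtype)
    expected = rows * cols * bands
    if raw.size != expected:
        raise FormatError(
            f"binary size {raw.size} elements, expected {expected}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:  # bil: line-major, then band, then sample
        cube = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    return RawCube(np.ascontiguousarray(cube), SpectralAxis(wavelengths))


def write_cube(
    cube: RawCube | ReflectanceCube,
    path: str | Path,
    interleave: str = "bsq",
    dtype: str = "float32",
) -> Path:
    """Write a cube as flat binary + ENVI-style header; returns header path."""
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil"):
        raise FormatError(f"unsupported interleave '{interleave}'")
    np_dtype = np.dtype("<u2") if dtype in ("uint16", "u2") else np.dtype("<f4")

    data = np.asarray(cube.data)
    rows, cols, bands = data.shape
    if interleave == "bsq":
        flat = data.transpose(2, 0, 1)
    else:
        flat = data.transpose(0, 2, 1)
    np.ascontiguousarray(flat, dtype=np_dtype).tofile(path)

    wl = ", ".join(f"{w:.6f}" for w in cube.axis.wavelengths_nm)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        f"interleave = {interleave}\n"
        f"data type = {_DTYPE_TO_ENVI[np_dtype]}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path = path.with_suffix(path.suffix + ".hdr")
    header_path.write_text(header)
    return header_path


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate(
    raw: RawCube,
    white: RawCube,
    dark: RawCube,
    clip_max: float = DEFAULT_CLIP_MAX,
    column_average_white: bool = False,
) -> ReflectanceCube:
    """Flat-field calibration: ``(raw - dark) / (white - dark)``.

    Pixels whose denominator is below ``eps = 1e-9 * max(white)`` are
    imputed to reflectance 0 and flagged in the QC mask. Output is clipped
    to ``[0, clip_max]``.

    ``column_average_white=True`` replaces the white frame by its per-column
    (across-track) average before subtraction, for push-broom setups where
    the white board does not fill the frame.
    """
    if raw.shape != white.shape or raw.shape != dark.shape:
        raise DimensionError(
            f"shape mismatch: raw {raw.shape}, white {white.shape}, dark {dark.shape}"
        )
    if raw.axis != white.axis or raw.axis != dark.axis:
        raise DimensionError("spectral axes differ between raw/white/dark")

    raw_f = raw.data.astype(np.float64)
    dark_f = dark.data.astype(np.float64)
    white_f = white.data.astype(np.float64)
    if column_average_white:
        white_f = np.broadcast_to(
            white_f.mean(axis=0, keepdims=True), white_f.shape
        ).copy()

    denom = white_f - dark_f
    eps = 1e-9 * float(np.max(white_f))
    bad = denom <= eps
    if bad.all():
        raise CalibrationError("white reference does not exceed dark anywhere")

    refl = np.zeros_like(raw_f)
    np.divide(raw_f - dark_f, denom, out=refl, where=~bad)
    refl[bad] = 0.0
    np.clip(refl, 0.0, clip_max, out=refl)
    return ReflectanceCube(
        data=refl,
        axis=raw.axis,
        provenance={"clip_max": clip_max, "column_average_white": column_average_white},
        qc_mask=bad,
    )


def nearest_band(axis: SpectralAxis, wavelength_nm: float) -> int:
    """Index of the band centre closest to ``wavelength_nm``.

    Ties break toward the lower index. Raises for queries outside the axis.
    """
    wl = axis.wavelengths_nm
    if wavelength_nm < wl[0] or wavelength_nm > wl[-1]:
        raise HsisasError(
            f"wavelength {wavelength_nm} nm outside axis range "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    return int(np.argmin(np.abs(wl - wavelength_nm)))
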