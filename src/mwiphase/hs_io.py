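"""Hyperspectral cube, mask and raster I/O.

Cubes are exchanged in the ENVI dialect: a small text header (``.hdr``)
next to a raw binary raster in band-interleaved-by-line (bil), by-pixel
(bip) or band-sequential (bsq) layout.  In memory a cube is always
row × col × band regardless of the on-disk interleave.

Ground-truth masks are 8-bit single-channel PNGs, 255 = tumor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "SpectralCube",
    "read_envi_cube",
    "write_envi_cube",
    "select_band",
    "read_mask",
    "write_mask",
]

# ENVI numeric data-type codes supported here.
_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_INTERLEAVES = ("bil", "bip", "bsq")


@dataclass
class SpectralCube:
    """A hyperspectral scene: intensities on a row × col × band grid.

    ``wavelengths_nm`` is strictly increasing with one entry per band;
    ``meta`` carries free-form header fields.  Spatial extent must be at
    least 8 × 8 so downstream phase extraction has a usable line length.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        rows, cols, bands = self.data.shape
        if rows < 8 or cols < 8:
            raise ValueError("cube spatial extent must be at least 8 x 8")
        if self.wavelengths_nm.shape != (bands,):
            raise ValueError(
                f"wavelength list length {self.wavelengths_nm.size} "
                f"does not match band count {bands}"
            )
        if self.wavelengths_nm.size > 1 and not np.all(
            np.diff(self.wavelengths_nm) > 0
        ):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube intensities must be finite")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


def _parse_header(text: str) -> dict:
    """Parse ENVI header text into a {lower-case key: value} dict."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing magic line)")
    body = text.lstrip()[4:]
    # Collapse brace-enclosed (possibly multi-line) values first.
    fields: dict[str, str] = {}
    pattern = re.compile(
        r"^\s*([^={}\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.MULTILINE | re.DOTALL
    )
    pos = 0
    while True:
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
        pos = m.end()
    return fields


def _parse_list(value: str) -> list[float]:
    inner = value.strip().lstrip("{").rstrip("}")
    return [float(tok) for tok in inner.replace("\n", " ").split(",") if tok.strip()]


def read_envi_cube(data_path, header_path=None) -> SpectralCube:
    """Read an ENVI raster + header into a :class:`SpectralCube`.

    The header must declare ``samples``, ``lines``, ``bands``, a supported
    ``data type``, an ``interleave`` in {bil, bip, bsq} and a wavelength
    list (taken to be nanometres).
    """
    data_path = Path(data_path)
    header_path = (
        Path(header_path)
        if header_path is not None
        else data_path.with_suffix(data_path.suffix + ".hdr")
    )
    fields = _parse_header(header_path.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"header missing required field: {exc}") from exc
    dtype_code = int(fields.get("data type", 4))
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    dtype = _ENVI_DTYPES[dtype_code]
    interleave = fields.get("interleave", "bil").strip().lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    if "wavelength" not in fields:
        raise ValueError("header has no wavelength list")
    wavelengths = _parse_list(fields["wavelength"])
    if len(wavelengths) != bands:
        raise ValueError(
            f"wavelength list length {len(wavelengths)} != bands {bands}"
        )

    offset = int(fields.get("header offset", 0))
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"file holds {raw.size} values, header implies {expected} "
            "(band count / shape mismatch)"
        )
    if interleave == "bil":  # (lines, bands, samples)
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":  # (lines, samples, bands)
        data = raw.reshape(lines, samples, bands)
    else:  # bsq: (bands, lines, samples)
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)

    meta = {
        k: v
        for k, v in fields.items()
        if k not in {"samples", "lines", "bands", "wavelength"}
    }
    return SpectralCube(data=np.ascontiguousarray(data), wavelengths_nm=wavelengths, meta=meta)


def write_envi_cube(
    cube: SpectralCube,
    data_path,
    header_path=None,
    interleave: str = "bil",
    dtype=np.float32,
) -> tuple[Path, Path]:
    """Write a cube as an ENVI raster; returns (data_path, header_path)."""
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"unsupported output dtype {dtype}")
    data_path = Path(data_path)
    header_path = (
        Path(header_path)
        if header_path is not None
        else data_path.with_suffix(data_path.suffix + ".hdr")
    )

    arr = cube.data.astype(dtype)
    if interleave == "bil":
        on_disk = arr.transpose(0, 2, 1)
    elif interleave == "bip":
        on_disk = arr
    else:
        on_disk = arr.transpose(2, 0, 1)
    np.ascontiguousarray(on_disk).tofile(data_path)

    wl = ", ".join(f"{w:g}" for w in cube.wavelengths_nm)
    header = (
        "ENVI\n"
        f"samples = {cube.cols}\n"
        f"lines = {cube.rows}\n"
        f"bands = {cube.bands}\n"
        "header offset = 0\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    return data_path, header_path


def select_band(cube: SpectralCube, target_nm: float) -> tuple[np.ndarray, float]:
    """Return the band image nearest ``target_nm`` and its actual wavelength.

    Ties between two equally distant bands resolve toward the lower
    wavelength.  The target must lie inside the cube's spectral range
    extended by half the mean band spacing.
    """
    wl = cube.wavelengths_nm
    half_step = 0.5 * float(np.mean(np.diff(wl))) if wl.size > 1 else 0.0
    if not (wl[0] - half_step <= target_nm <= wl[-1] + half_step):
        raise ValueError(
            f"target {target_nm} nm outside spectral range "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    idx = int(np.argmin(np.abs(wl - target_nm)))  # argmin is tie-stable low
    return cube.data[:, :, idx], float(wl[idx])


def read_mask(path) -> np.ndarray:
    """Read an 8-bit mask image; values > 127 map to label 1 (tumor)."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # tolerate grayscale saved with redundant channels
        img = img[..., 0]
    return (img > 127).astype(np.uint8)


def write_mask(mask: np.ndarray, path) -> Path:
    """Write a {0,1} mask as an 8-bit PNG with 255 = tumor."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be 0 or 1")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))
    return Path(path)
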