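"""Hyperspectral cube and label-map I/O.

Cubes are held in memory as row-major ``(rows, cols, bands)`` arrays with the
band axis last, because pixel-spectrum extraction is the dominant access
pattern.  On disk two formats are supported:

* ENVI: a plain-text ``.hdr`` header next to a raw little-endian binary
  (BIL/BIP/BSQ interleaves), the de-facto standard for pushbroom VNIR
  instruments.
* A portable single-file ``.npz`` archive holding the array, the wavelength
  vector and optional palette metadata, for environments without ENVI
  tooling.

Gold-standard label maps are palette-coded PNGs: green/red/blue/black for
normal, tumor, hypervascularized and background tissue; white marks
unlabeled pixels.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

__all__ = [
    "RawCube",
    "ReferencePair",
    "GoldStandardMap",
    "CLASS_UNLABELED",
    "CLASS_NORMAL",
    "CLASS_TUMOR",
    "CLASS_HYPERVASCULAR",
    "CLASS_BACKGROUND",
    "PALETTE",
    "EnviFormatError",
    "read_envi",
    "write_envi",
    "read_portable",
    "write_portable",
    "read_label_map",
    "write_label_map",
    "write_class_map",
]

# Label encoding shared across the package.
CLASS_UNLABELED = 0
CLASS_NORMAL = 1
CLASS_TUMOR = 2
CLASS_HYPERVASCULAR = 3
CLASS_BACKGROUND = 4

#: class code -> RGB color of the palette-coded maps
PALETTE: dict[int, tuple[int, int, int]] = {
    CLASS_UNLABELED: (255, 255, 255),
    CLASS_NORMAL: (0, 255, 0),
    CLASS_TUMOR: (255, 0, 0),
    CLASS_HYPERVASCULAR: (0, 0, 255),
    CLASS_BACKGROUND: (0, 0, 0),
}


class EnviFormatError(ValueError):
    """Malformed or inconsistent ENVI header/binary pair."""


@dataclass
class RawCube:
    """Raw sensor cube: ``(rows, cols, bands)`` counts plus band centers in nm."""

    data: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D (rows, cols, bands), got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all cube dimensions must be >= 1, got {self.data.shape}")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.data.shape[2]:
            raise ValueError(
                f"band count {self.data.shape[2]} does not match "
                f"wavelength count {self.wavelengths.size}"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ReferencePair:
    """White and dark reference captures used for per-pixel calibration."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white)
        self.dark = np.asarray(self.dark)
        if self.white.shape != self.dark.shape:
            raise ValueError(
                f"white shape {self.white.shape} != dark shape {self.dark.shape}"
            )


@dataclass
class GoldStandardMap:
    """Sparse per-pixel tissue labels (0=unlabeled, 1=normal, 2=tumor,
    3=hypervascularized, 4=background)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int64)
        bad = np.setdiff1d(np.unique(self.labels), np.arange(5))
        if bad.size:
            raise ValueError(f"label values outside 0..4: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# ENVI header + raw binary
# ---------------------------------------------------------------------------

# ENVI "data type" codes <-> numpy dtypes (little-endian on disk).
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_INTERLEAVES = ("bil", "bip", "bsq")


def _parse_envi_header(text: str) -> dict:
    """Parse the ``key = value`` / ``key = { ... }`` ENVI header grammar."""
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("missing ENVI magic line")
    fields: dict[str, str] = {}
    # Collapse brace blocks (which may span lines) before splitting on '='.
    for m in re.finditer(
        r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n{]*)\s*$",
        text,
        flags=re.MULTILINE | re.DOTALL,
    ):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def read_envi(header_path: str | os.PathLike) -> RawCube:
    """Read an ENVI header + companion binary into a :class:`RawCube`.

    Raises :class:`EnviFormatError` on missing wavelength metadata or when
    the binary size disagrees with the advertised shape.
    """
    header_path = os.fspath(header_path)
    with open(header_path) as fh:
        fields = _parse_envi_header(fh.read())

    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise EnviFormatError(f"header missing required field: {exc}") from exc
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported data type code {dtype_code}")
    if int(fields.get("byte order", "0")) != 0:
        raise EnviFormatError("only little-endian (byte order = 0) is supported")

    if "wavelength" not in fields:
        raise EnviFormatError("header has no wavelength block")
    wl_text = fields["wavelength"].strip()
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise EnviFormatError("wavelength block must be brace-delimited")
    wavelengths = np.array(
        [float(tok) for tok in wl_text[1:-1].replace("\n", " ").split(",") if tok.strip()]
    )
    if wavelengths.size != bands:
        raise EnviFormatError(
            f"header advertises {bands} bands but lists {wavelengths.size} wavelengths"
        )

    bin_path = os.path.splitext(header_path)[0] + ".raw"
    if not os.path.exists(bin_path):
        raise EnviFormatError(f"companion binary not found: {bin_path}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code]).newbyteorder("<")
    payload = np.fromfile(bin_path, dtype=dtype)
    if payload.size != lines * samples * bands:
        raise EnviFormatError(
            f"binary holds {payload.size} values, header implies {lines * samples * bands}"
        )

    if interleave == "bip":  # (lines, samples, bands)
        data = payload.reshape(lines, samples, bands)
    elif interleave == "bil":  # (lines, bands, samples)
        data = payload.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bsq: (bands, lines, samples)
        data = payload.reshape(bands, lines, samples).transpose(1, 2, 0)
    return RawCube(np.ascontiguousarray(data), wavelengths)


def write_envi(cube: RawCube, header_path: str | os.PathLike, interleave: str = "bip") -> None:
    """Write a cube as ENVI header + raw binary (little-endian)."""
    header_path = os.fspath(header_path)
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_CODES:
        raise EnviFormatError(f"unsupported dtype {dtype} for ENVI output")
    lines, samples, bands = cube.shape

    if interleave == "bip":
        payload = cube.data
    elif interleave == "bil":
        payload = cube.data.transpose(0, 2, 1)
    else:
        payload = cube.data.transpose(2, 0, 1)

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(header_path, "w") as fh:
        fh.write(header)
    bin_path = os.path.splitext(header_path)[0] + ".raw"
    np.ascontiguousarray(payload).astype(dtype.newbyteorder("<")).tofile(bin_path)


# ---------------------------------------------------------------------------
# Portable single-file container
# ---------------------------------------------------------------------------


def write_portable(cube: RawCube, path: str | os.PathLike) -> None:
    """Write cube + wavelengths + class palette into one ``.npz`` archive."""
    palette = np.array([PALETTE[c] for c in sorted(PALETTE)], dtype=np.uint8)
    np.savez(path, data=cube.data, wavelengths=cube.wavelengths, palette=palette)


def read_portable(path: str | os.PathLike) -> RawCube:
    with np.load(path) as archive:
        return RawCube(archive["data"], archive["wavelengths"])


# ---------------------------------------------------------------------------
# Palette-coded label / classification maps
# ---------------------------------------------------------------------------


def read_label_map(
    image_path: str | os.PathLike, palette: dict[int, tuple[int, int, int]] = PALETTE
) -> GoldStandardMap:
    """Read a palette-coded PNG into a :class:`GoldStandardMap`.

    Every pixel must exactly match a palette color; an off-palette pixel
    raises ``ValueError`` naming the offending RGB triple.
    """
    img = np.asarray(iio.imread(image_path))
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("label image must be RGB")
    labels = np.full(img.shape[:2], -1, dtype=np.int64)
    for code, rgb in palette.items():
        labels[np.all(img == np.array(rgb, dtype=img.dtype), axis=2)] = code
    if (labels < 0).any():
        r, c = np.argwhere(labels < 0)[0]
        raise ValueError(f"off-palette pixel color {tuple(int(v) for v in img[r, c])} at ({r}, {c})")
    return GoldStandardMap(labels)


def write_label_map(
    map_: GoldStandardMap | np.ndarray,
    path: str | os.PathLike,
    palette: dict[int, tuple[int, int, int]] = PALETTE,
) -> None:
    """Write any 0..4-valued label map as a palette-coded PNG (lossless)."""
    labels = map_.labels if isinstance(map_, GoldStandardMap) else np.asarray(map_)
    lut = np.zeros((5, 3), dtype=np.uint8)
    for code, rgb in palette.items():
        lut[code] = rgb
    iio.imwrite(os.fspath(path), lut[labels])


def write_class_map(
    map_: np.ndarray,
    path: str | os.PathLike,
    palette: dict[int, tuple[int, int, int]] = PALETTE,
) -> None:
    """Write a final classification map (values 1..4 only) as a palette PNG.

    Final maps are fully assigned, so an unlabeled (0) pixel is an error.
    """
    labels = map_.labels if isinstance(map_, GoldStandardMap) else np.asarray(map_)
    if (labels == CLASS_UNLABELED).any():
        raise ValueError("classification map contains unlabeled (0) pixels")
    write_label_map(GoldStandardMap(labels), path, palette)
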