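"""Three-step pre-processing chain: calibration, denoising, normalization.

1. **Calibration** converts raw counts to percent reflectance with per-pixel
   white and dark reference captures: ``C = 100 * (R - D) / (W - D)``.
2. **Denoising** smooths each pixel spectrum along the band axis (centered
   moving average, reflective ends), discards the noisy extreme bands
   outside the 450-900 nm operating bandwidth, and band-averages the
   retained bands down to 128 channels (contiguous near-equal groups).
3. **Normalization** min-max scales every pixel spectrum to [0, 1], so the
   classifiers see spectral shape rather than amplitude (illumination on a
   curved brain surface is strongly non-uniform).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from hsibrain.hsio import RawCube, ReferencePair

__all__ = [
    "CalibrationError",
    "CalibratedCube",
    "ProcessedCube",
    "PreprocessParams",
    "calibrate",
    "denoise",
    "normalize",
    "preprocess_chain",
]


class CalibrationError(ValueError):
    """White/dark reference pair unusable for division."""


@dataclass
class CalibratedCube:
    """Per-pixel-per-band calibrated reflectance in percent."""

    data: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("calibrated cube contains non-finite values")


@dataclass
class ProcessedCube:
    """Band-averaged, per-pixel min-max normalized cube.

    ``data`` is ``(rows, cols, n_bands)`` in [0, 1]; ``band_wavelengths``
    are the group-mean band centers in nm.  ``degenerate_mask`` flags
    pixels whose spectrum was constant before normalization (e.g.
    saturated glare); those spectra are all-zero.
    """

    data: np.ndarray
    band_wavelengths: np.ndarray
    degenerate_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.band_wavelengths = np.asarray(self.band_wavelengths, dtype=float)
        if self.band_wavelengths.size != self.data.shape[2]:
            raise ValueError("band count does not match wavelength count")
        if not np.all(np.diff(self.band_wavelengths) > 0):
            raise ValueError("band wavelengths must be strictly increasing")
        if self.degenerate_mask is None:
            self.degenerate_mask = np.zeros(self.data.shape[:2], dtype=bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class PreprocessParams:
    """Tunable knobs of the chain (defaults follow the instrument pipeline)."""

    smooth_window: int = 5
    band_low_nm: float = 450.0
    band_high_nm: float = 900.0
    out_bands: int = 128


def calibrate(raw: RawCube, refs: ReferencePair) -> CalibratedCube:
    """Per-pixel white/dark calibration to percent reflectance.

    ``C = 100 * (R - dark) / (white - dark)`` elementwise.  Any element
    with ``white - dark <= 0`` makes the division meaningless and raises a
    :class:`CalibrationError` naming the first offending pixel/band.
    """
    white = np.asarray(refs.white, dtype=float)
    dark = np.asarray(refs.dark, dtype=float)
    if white.shape != raw.data.shape:
        raise CalibrationError(
            f"reference shape {white.shape} does not match cube shape {raw.data.shape}"
        )
    span = white - dark
    if (span <= 0).any():
        r, c, b = np.argwhere(span <= 0)[0]
        raise CalibrationError(
            f"white - dark <= 0 at pixel ({r}, {c}), band {b}: "
            f"white={white[r, c, b]}, dark={dark[r, c, b]}"
        )
    # ratio first: (W-D)/(W-D) is exactly 1.0 elementwise, so a raw capture
    # equal to the white reference calibrates to exactly 100 everywhere
    data = (raw.data.astype(float) - dark) / span * 100.0
    return CalibratedCube(data, raw.wavelengths)


def denoise(
    cal: CalibratedCube,
    smooth_window: int = 5,
    band_low_nm: float = 450.0,
    band_high_nm: float = 900.0,
    out_bands: int = 128,
) -> CalibratedCube:
    """Spectral smoothing, extreme-band clipping, and band averaging.

    Purely spectral: every pixel is processed independently, so the
    operator commutes with spatial cropping.  The retained bands are
    partitioned into ``out_bands`` contiguous groups whose sizes differ by
    at most one; each group is averaged and the output band center is the
    group-mean wavelength.
    """
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    wl = cal.wavelengths
    if band_low_nm < wl[0] - 1e-9 or band_high_nm > wl[-1] + 1e-9:
        raise ValueError(
            f"[{band_low_nm}, {band_high_nm}] nm outside wavelength span "
            f"[{wl[0]}, {wl[-1]}] nm"
        )

    smoothed = uniform_filter1d(cal.data.astype(float), smooth_window, axis=2, mode="reflect")

    keep = (wl >= band_low_nm) & (wl <= band_high_nm)
    n_keep = int(keep.sum())
    if out_bands > n_keep:
        raise ValueError(f"out_bands={out_bands} exceeds retained band count {n_keep}")
    kept = smoothed[:, :, keep]
    kept_wl = wl[keep]

    groups = np.array_split(np.arange(n_keep), out_bands)
    data = np.stack([kept[:, :, g].mean(axis=2) for g in groups], axis=2)
    centers = np.array([kept_wl[g].mean() for g in groups])
    return CalibratedCube(data, centers)


def normalize(cube: CalibratedCube) -> ProcessedCube:
    """Per-pixel min-max scaling of each spectrum to [0, 1].

    Constant (degenerate) spectra cannot be scaled; they are mapped to
    all-zeros and flagged in ``degenerate_mask`` rather than raising, since
    saturated glare pixels are routine in real surgical scenes.
    """
    data = cube.data.astype(float)
    lo = data.min(axis=2, keepdims=True)
    hi = data.max(axis=2, keepdims=True)
    span = hi - lo
    degenerate = span[:, :, 0] == 0
    span = np.where(span == 0, 1.0, span)
    out = (data - lo) / span
    out[degenerate] = 0.0
    return ProcessedCube(out, cube.wavelengths, degenerate)


def preprocess_chain(
    raw: RawCube, refs: ReferencePair, params: PreprocessParams | None = None
) -> ProcessedCube:
    """calibrate -> denoise -> normalize; deterministic composition."""
    p = params or PreprocessParams()
    cal = calibrate(raw, refs)
    den = denoise(cal, p.smooth_window, p.band_low_nm, p.band_high_nm, p.out_bands)
    return normalize(den)
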