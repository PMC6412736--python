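"""Synthetic multi-patient hyperspectral scene generator.

Emulates the statistical and spatial structure of an intraoperative
visible/near-infrared capture of an exposed brain, so that every pipeline
stage can be exercised without real patient data:

* 826-band raw cubes on a 400-1000 nm grid with paired white/dark
  reference captures, multiplicative illumination non-uniformity,
  additive spectral noise, and optional 12-bit sensor quantization;
* per-class spectral signatures built from a smooth sigmoid-like
  reflectance baseline plus Gaussian absorption dips.  The
  hypervascularized class carries a hemoglobin-like absorption dip in the
  500-590 nm window and extra variability at long wavelengths (blood
  vessels and extravasated blood have varied spectra); the background is
  a distinct step-like family;
* spatial layout: an elliptical parenchyma (exposed brain) region inside
  a background frame, circular tumor blobs, curvilinear vessels
  (quadratic Bezier curves 2-4 px wide), an extravasated-blood blob, and
  rubber-ring markers painted as background-class annuli;
* a patient level: scenes from one patient share a signature
  perturbation; different patients differ.

What it does NOT emulate: radiometrically faithful tissue optics, light
transport, specular glare geometry, or motion artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from hsibrain.hsio import (
    CLASS_BACKGROUND,
    CLASS_HYPERVASCULAR,
    CLASS_NORMAL,
    CLASS_TUMOR,
    GoldStandardMap,
    RawCube,
    ReferencePair,
)

__all__ = [
    "LayoutError",
    "ClassLayout",
    "SignatureParams",
    "SceneConfig",
    "RawScene",
    "class_signature",
    "generate_scene",
    "generate_cohort",
]

N_RAW_BANDS = 826
WAVELENGTH_MIN_NM = 400.0
WAVELENGTH_MAX_NM = 1000.0


class LayoutError(ValueError):
    """Requested spatial layout cannot be placed in the scene."""


def default_wavelengths() -> np.ndarray:
    return np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, N_RAW_BANDS)


@dataclass
class ClassLayout:
    """Spatial layout parameters, in pixels (fractions relative to scene)."""

    parenchyma_axes_frac: tuple[float, float] = (0.42, 0.45)
    n_tumor_blobs: int = 2
    tumor_radius_frac: float = 0.10
    n_vessels: int = 2
    vessel_width_px: int = 3
    n_markers: int = 2
    marker_outer_frac: float = 0.08
    marker_ring_px: int = 2
    blood_blob_radius_frac: float = 0.07


@dataclass
class SignatureParams:
    """Per-class reflectance model: sigmoid baseline + Gaussian dips.

    Each entry is ``(low, high, center_nm, width_nm, dips)`` where dips is
    a list of ``(center_nm, sigma_nm, depth)``.  Values are reflectance in
    [0, 1].  The hypervascularized entry places its main absorption dip at
    545 nm, inside the 500-590 nm hemoglobin window.
    """

    normal: tuple = (0.15, 0.55, 600.0, 60.0, ((545.0, 20.0, 0.05),))
    tumor: tuple = (0.22, 0.68, 520.0, 45.0, ((560.0, 25.0, 0.10), (760.0, 30.0, 0.08)))
    hypervascular: tuple = (0.05, 0.60, 650.0, 45.0, ((545.0, 30.0, 0.04),))
    background_levels: tuple[float, float] = (0.75, 0.55)  # step below/above 700 nm
    background_step_nm: float = 700.0


@dataclass
class SceneConfig:
    """Full study conditions for one synthetic scene family."""

    rows: int = 64
    cols: int = 64
    noise_sd: float = 0.01  # additive spectral noise, reflectance units
    illumination_gradient: float = 0.15  # multiplicative field amplitude
    class_layout: ClassLayout = field(default_factory=ClassLayout)
    signature_params: SignatureParams = field(default_factory=SignatureParams)
    patient_shift_sd: float = 0.05  # inter-patient signature perturbation
    quantize_bits: int | None = 12  # None = keep float counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 32 or self.cols < 32:
            raise ValueError("scene must be at least 32 x 32 pixels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class RawScene:
    """One synthetic capture with full ground truth."""

    cube: RawCube
    refs: ReferencePair
    truth: GoldStandardMap
    parenchyma_truth: np.ndarray
    vessel_truth: np.ndarray
    patient_id: str
    image_id: str
    signatures: dict[int, np.ndarray]  # planted per-class reflectance spectra


# ---------------------------------------------------------------------------
# Spectral signatures
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def class_signature(
    class_id: int,
    wavelengths: np.ndarray,
    patient_rng: np.random.Generator | None = None,
    shift_sd: float = 0.0,
    params: SignatureParams | None = None,
) -> np.ndarray:
    """Reflectance spectrum of one tissue class on the given grid.

    With ``patient_rng`` and ``shift_sd > 0`` the baseline level, dip
    depths, and (for the hypervascularized class) a long-wavelength slope
    are jittered, emulating inter-patient variation.  ``shift_sd = 0``
    gives the deterministic class template (the rng is still consumed, so
    draw counts stay aligned across configurations).
    """
    p = params or SignatureParams()
    wl = np.asarray(wavelengths, dtype=float)
    rng = patient_rng or np.random.default_rng(0)

    if class_id == CLASS_BACKGROUND:
        lo_level, hi_level = p.background_levels
        sig = hi_level + (lo_level - hi_level) * _sigmoid((p.background_step_nm - wl) / 10.0)
        sig = sig + 2e-5 * (wl - wl[0])  # tilt: keep the spectrum non-constant
        sig = sig * (1.0 + shift_sd * rng.normal())
        return np.clip(sig, 0.01, 0.95)

    if class_id == CLASS_NORMAL:
        low, high, center, width, dips = p.normal
    elif class_id == CLASS_TUMOR:
        low, high, center, width, dips = p.tumor
    elif class_id == CLASS_HYPERVASCULAR:
        low, high, center, width, dips = p.hypervascular
    else:
        raise ValueError(f"unknown class id {class_id}")

    level_jitter = 1.0 + shift_sd * rng.normal()
    sig = low + (high - low) * _sigmoid((wl - center) / width)
    for c, s, depth in dips:
        sig = sig - depth * (1.0 + shift_sd * rng.normal()) * np.exp(
            -0.5 * ((wl - c) / s) ** 2
        )
    sig = sig * level_jitter
    # Blood-dominated tissue varies most beyond ~650 nm (vessels vs
    # extravasated blood); give that class a larger long-wavelength spread.
    long_ramp = _sigmoid((wl - 700.0) / 60.0)
    slope_sd = 6.0 * shift_sd if class_id == CLASS_HYPERVASCULAR else 0.5 * shift_sd
    sig = sig + slope_sd * rng.normal() * 0.3 * long_ramp
    return np.clip(sig, 0.01, 0.95)


# ---------------------------------------------------------------------------
# Spatial layout
# ---------------------------------------------------------------------------


def _disc_mask(rows: int, cols: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[:rows, :cols]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _place_discs(
    rng: np.random.Generator,
    n: int,
    radius: float,
    inside: np.ndarray,
    occupied: list[tuple[float, float, float]],
    margin: float = 2.0,
    attempts: int = 400,
) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` disc centers fully inside ``inside`` and not
    overlapping previously placed discs."""
    rows, cols = inside.shape
    if 2 * radius >= min(rows, cols):
        raise LayoutError(
            f"disc of radius {radius:.1f} cannot fit a {rows}x{cols} scene"
        )
    centers: list[tuple[float, float]] = []
    for _ in range(n):
        for _ in range(attempts):
            cy = rng.uniform(radius, rows - radius)
            cx = rng.uniform(radius, cols - radius)
            disc = _disc_mask(rows, cols, cy, cx, radius + 1)
            if not inside[disc].all():
                continue
            if any(
                np.hypot(cy - oy, cx - ox) < radius + orad + margin
                for oy, ox, orad in occupied
            ):
                continue
            centers.append((cy, cx))
            occupied.append((cy, cx, radius))
            break
        else:
            raise LayoutError(
                f"could not place disc of radius {radius:.1f} inside the parenchyma"
            )
    return centers


def _bezier_mask(
    rng: np.random.Generator,
    inside: np.ndarray,
    width_px: int,
) -> np.ndarray:
    """Rasterize one random quadratic Bezier curve clipped to ``inside``."""
    rows, cols = inside.shape
    pts = np.argwhere(inside)
    p0, p1, p2 = pts[rng.choice(len(pts), size=3, replace=False)].astype(float)
    t = np.linspace(0.0, 1.0, 6 * max(rows, cols))[:, None]
    curve = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
    mask = np.zeros((rows, cols), dtype=bool)
    half = max(width_px / 2.0, 1.0)
    yy, xx = np.mgrid[:rows, :cols]
    # distance to the sampled polyline, chunked to bound memory
    d2 = np.full((rows, cols), np.inf)
    for chunk in np.array_split(curve, 8):
        d2 = np.minimum(
            d2,
            ((yy[None] - chunk[:, 0, None, None]) ** 2
             + (xx[None] - chunk[:, 1, None, None]) ** 2).min(axis=0),
        )
    mask = d2 <= half**2
    return mask & inside


def generate_scene(
    config: SceneConfig,
    patient_rng: np.random.Generator | None = None,
    scene_seed: int | None = None,
    patient_id: str = "P01",
    image_id: str = "I01",
) -> RawScene:
    """Generate one fully-labeled synthetic capture.

    Raw counts follow the sensor model
    ``raw = dark + (white - dark) * reflectance * illumination + noise``
    so that white/dark calibration recovers ``reflectance * illumination``
    (exactly, when noise and quantization are disabled).  Separate named
    substreams drive layout, signatures, and noise, so the layout is
    reproducible independently of the noise draw.
    """
    cfg = config
    seed = cfg.seed if scene_seed is None else scene_seed
    layout_rng = np.random.default_rng([seed, 1])
    noise_rng = np.random.default_rng([seed, 2])
    sig_rng = patient_rng or np.random.default_rng([seed, 3])
    rows, cols = cfg.rows, cfg.cols
    lay = cfg.class_layout

    # --- layout ------------------------------------------------------------
    ay = lay.parenchyma_axes_frac[0] * rows
    ax = lay.parenchyma_axes_frac[1] * cols
    yy, xx = np.ogrid[:rows, :cols]
    parenchyma = ((yy - rows / 2.0) / ay) ** 2 + ((xx - cols / 2.0) / ax) ** 2 <= 1.0

    truth = np.full((rows, cols), CLASS_BACKGROUND, dtype=np.int64)
    truth[parenchyma] = CLASS_NORMAL

    vessel_mask = np.zeros((rows, cols), dtype=bool)
    for _ in range(lay.n_vessels):
        vessel_mask |= _bezier_mask(layout_rng, parenchyma, lay.vessel_width_px)
    truth[vessel_mask] = CLASS_HYPERVASCULAR

    # Discs are *placed* largest-first (tumor blobs are the hardest to fit)
    # but *painted* with the tumor on top, so blobs stay intact connected
    # components even where vessels cross them.
    occupied: list[tuple[float, float, float]] = []
    r_tumor = lay.tumor_radius_frac * min(rows, cols)
    tumor_centers = _place_discs(layout_rng, lay.n_tumor_blobs, r_tumor, parenchyma, occupied)

    r_blood = lay.blood_blob_radius_frac * min(rows, cols)
    blood_mask = np.zeros((rows, cols), dtype=bool)
    for cy, cx in _place_discs(layout_rng, 1, r_blood, parenchyma, occupied):
        blood_mask |= _disc_mask(rows, cols, cy, cx, r_blood)
    truth[blood_mask] = CLASS_HYPERVASCULAR

    r_marker = lay.marker_outer_frac * min(rows, cols)
    marker_mask = np.zeros((rows, cols), dtype=bool)
    for cy, cx in _place_discs(layout_rng, lay.n_markers, r_marker, parenchyma, occupied):
        ring = _disc_mask(rows, cols, cy, cx, r_marker) & ~_disc_mask(
            rows, cols, cy, cx, r_marker - lay.marker_ring_px
        )
        marker_mask |= ring
    truth[marker_mask] = CLASS_BACKGROUND

    tumor_mask = np.zeros((rows, cols), dtype=bool)
    for cy, cx in tumor_centers:
        tumor_mask |= _disc_mask(rows, cols, cy, cx, r_tumor)
    truth[tumor_mask] = CLASS_TUMOR

    vessel_truth = vessel_mask & (truth == CLASS_HYPERVASCULAR) & ~blood_mask

    # --- spectra -----------------------------------------------------------
    wl = default_wavelengths()
    sig_of = {
        c: class_signature(c, wl, sig_rng, cfg.patient_shift_sd, cfg.signature_params)
        for c in (CLASS_NORMAL, CLASS_TUMOR, CLASS_HYPERVASCULAR, CLASS_BACKGROUND)
    }
    refl = np.empty((rows, cols, wl.size))
    for c, sig in sig_of.items():
        refl[truth == c] = sig

    if cfg.illumination_gradient > 0:
        gx = (xx - cols / 2.0) / cols
        gy = (yy - rows / 2.0) / rows
        field2d = 1.0 + cfg.illumination_gradient * (
            0.6 * (gx + gy) - 0.8 * (gx**2 + gy**2)
        )
        signal = refl * field2d[..., None]
    else:
        signal = refl

    if cfg.noise_sd > 0:
        signal = signal + noise_rng.normal(0.0, cfg.noise_sd, size=refl.shape)

    # Lamp-shaped gain, chosen so counts stay inside the sensor range.
    gain_band = 2600.0 + 600.0 * np.exp(-0.5 * ((wl - 650.0) / 250.0) ** 2)
    dark_level = 64.0
    dark = np.full((rows, cols, wl.size), dark_level)
    white = dark + gain_band[None, None, :]
    raw = dark + (white - dark) * signal
    if cfg.quantize_bits is not None:
        top = 2**cfg.quantize_bits - 1
        raw = np.clip(np.rint(raw), 0, top).astype(np.uint16)

    return RawScene(
        cube=RawCube(raw, wl),
        refs=ReferencePair(white=white, dark=dark),
        truth=GoldStandardMap(truth),
        parenchyma_truth=parenchyma,
        vessel_truth=vessel_truth,
        patient_id=patient_id,
        image_id=image_id,
        signatures=sig_of,
    )


def generate_cohort(
    n_patients: int, images_per_patient: int, config: SceneConfig
) -> list[RawScene]:
    """Generate a multi-patient cohort.

    Scenes within a patient share one patient-level signature perturbation
    (the rng state is reset per scene so each image of a patient carries
    identical planted signatures); scenes across patients differ when
    ``patient_shift_sd > 0``.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients (leave-one-patient-out requires >= 2)")
    scenes: list[RawScene] = []
    for p in range(n_patients):
        for i in range(images_per_patient):
            patient_rng = np.random.default_rng([config.seed, 1000 + p])
            scenes.append(
                generate_scene(
                    config,
                    patient_rng=patient_rng,
                    scene_seed=config.seed + 10_000 * (p + 1) + i,
                    patient_id=f"P{p + 1:02d}",
                    image_id=f"I{i + 1:02d}",
                )
            )
    return scenes
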