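"""Full classification framework: grayscale synthesis, vessel and
parenchyma maps, spectral classification, morphology, and mask fusion.

The pipeline takes a pre-processed cube and produces a fully-assigned
four-class map:

1. a grayscale image that highlights blood vessels is synthesized from
   three channels: ``I = 0.7*b42 + 0.3*b50 + 0.8*(1 - b80)`` (1-based
   channel indices; with 128 bands over 450-900 nm these sit near the
   hemoglobin absorption at ~591 nm, ~620 nm, and a reflectance peak at
   ~729 nm);
2. the binary vessel CNN classifies the grayscale image and the raw mask
   is cleaned with close(r=1) then open(r=1);
3. the fully-convolutional segmenter yields the parenchymal (exposed
   brain) mask, cleaned with close/open at a large disk radius plus hole
   filling;
4. the per-pixel spectral DNN map is merged with the vessel mask
   (positive fill: vessel pixels forced to hypervascularized) and the
   parenchyma mask (negative fill: everything outside forced to
   background), then a final per-class binary opening with r=1 removes
   single-pixel speckle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from hsibrain.hsio import (
    CLASS_BACKGROUND,
    CLASS_HYPERVASCULAR,
)
from hsibrain.nets import (
    Cnn2DModel,
    Dnn1DModel,
    ParenchymaModel,
    predict_cnn2d,
    predict_dnn1d,
    predict_parenchyma,
)
from hsibrain.preprocess import ProcessedCube

__all__ = [
    "FrameworkConfig",
    "synthesize_grayscale",
    "morph_binary",
    "vessel_map",
    "parenchyma_map",
    "fuse_maps",
    "run_framework",
]


@dataclass
class FrameworkConfig:
    """Channel/coefficient choices and morphology radii of the pipeline."""

    gray_channels: tuple[int, int, int] = (42, 50, 80)  # 1-based
    gray_coeffs: tuple[float, float, float] = (0.7, 0.3, 0.8)
    vessel_morph_radius: int = 1
    parenchyma_morph_radius: int = 35
    final_open_radius: int = 1
    parenchyma_threshold: float = 0.5


def synthesize_grayscale(
    cube: ProcessedCube,
    channels: tuple[int, int, int] = (42, 50, 80),
    coeffs: tuple[float, float, float] = (0.7, 0.3, 0.8),
) -> np.ndarray:
    """Linear three-channel combination ``c1*bA + c2*bB + c3*(1 - bC)``.

    ``channels`` are 1-based positions in the spectral signature.
    """
    for ch in channels:
        if not (1 <= ch <= cube.n_bands):
            raise ValueError(f"channel {ch} outside 1..{cube.n_bands}")
    a, b, c = (cube.data[:, :, ch - 1] for ch in channels)
    w1, w2, w3 = coeffs
    return w1 * a + w2 * b + w3 * (1.0 - c)


def morph_binary(mask: np.ndarray, op: str, radius: int = 1) -> np.ndarray:
    """Binary morphology with a discrete disk structuring element.

    The disk is ``{(dx, dy): dx^2 + dy^2 <= r^2}``; outside the image is
    treated as background.  ``op`` is ``open``, ``close``, or
    ``fill_holes``.
    """
    mask = np.asarray(mask, dtype=bool)
    if op == "fill_holes":
        return ndimage.binary_fill_holes(mask)
    if radius < 1:
        raise ValueError("radius must be >= 1 for open/close")
    se = disk(radius)
    if op == "open":
        return ndimage.binary_opening(mask, structure=se)
    if op == "close":
        # border_value=0 throughout: outside the image is background at
        # every stage, for dilation and the erosion that follows alike.
        return ndimage.binary_closing(mask, structure=se)
    raise ValueError(f"unknown morphology op {op!r}")


def vessel_map(gray: np.ndarray, vessel_model: Cnn2DModel) -> np.ndarray:
    """Binary vessel mask: patch-CNN argmax, then close(r=1), open(r=1)."""
    probs = predict_cnn2d(vessel_model, gray)
    raw = vessel_model.classes[probs.argmax(axis=2)] == 1
    return morph_binary(morph_binary(raw, "close", 1), "open", 1)


def parenchyma_map(
    gray: np.ndarray,
    parenchyma_model: ParenchymaModel,
    radius: int = 35,
    threshold: float = 0.5,
) -> np.ndarray:
    """Parenchyma mask: net output >= threshold, close(r), open(r), fill holes.

    ``radius`` defaults to the 35-px disk used on full-resolution
    intraoperative images; scale it down for smaller scenes.
    """
    raw = predict_parenchyma(parenchyma_model, gray) >= threshold
    m = morph_binary(raw, "close", radius)
    m = morph_binary(m, "open", radius)
    return morph_binary(m, "fill_holes")


def fuse_maps(
    dnn_map: np.ndarray,
    vessel: np.ndarray,
    parenchyma: np.ndarray,
    final_open_radius: int = 1,
) -> np.ndarray:
    """Merge the spectral map with the vessel and parenchyma masks.

    Positive fill: vessel pixels become hypervascularized.  Negative
    fill (applied after, so it dominates): pixels outside the parenchyma
    become background.  Finally each class is opened as a binary mask
    with a disk of ``final_open_radius``; openings of disjoint sets stay
    disjoint, and a pixel whose class is eroded away everywhere keeps its
    pre-open label, so the output remains fully assigned.
    """
    dnn_map = np.asarray(dnn_map)
    vessel = np.asarray(vessel, dtype=bool)
    parenchyma = np.asarray(parenchyma, dtype=bool)
    if not (dnn_map.shape == vessel.shape == parenchyma.shape):
        raise ValueError("map and mask shapes differ")
    fused = dnn_map.copy()
    fused[vessel] = CLASS_HYPERVASCULAR
    fused[~parenchyma] = CLASS_BACKGROUND

    out = np.zeros_like(fused)
    for c in (1, 2, 3, 4):
        opened = morph_binary(fused == c, "open", final_open_radius)
        out[opened] = c
    out[out == 0] = fused[out == 0]
    return out


def run_framework(
    cube: ProcessedCube,
    dnn_model: Dnn1DModel,
    vessel_model: Cnn2DModel,
    parenchyma_model: ParenchymaModel,
    config: FrameworkConfig | None = None,
) -> tuple[np.ndarray, dict]:
    """Run the full pipeline on one processed cube.

    Returns ``(final_map, intermediates)`` where the final map is a fully
    assigned four-class image and ``intermediates`` exposes the grayscale
    image, the vessel/parenchyma masks, and the spectral probability cube
    for downstream visualization.
    """
    cfg = config or FrameworkConfig()
    gray = synthesize_grayscale(cube, cfg.gray_channels, cfg.gray_coeffs)
    vessels = vessel_map(gray, vessel_model)
    parenchyma = parenchyma_map(
        gray, parenchyma_model, cfg.parenchyma_morph_radius, cfg.parenchyma_threshold
    )
    pcube = predict_dnn1d(dnn_model, cube)
    fused = fuse_maps(pcube.argmax_map(), vessels, parenchyma, cfg.final_open_radius)
    return fused, {
        "grayscale": gray,
        "vessel_mask": vessels,
        "parenchyma_mask": parenchyma,
        "probability_cube": pcube,
    }
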