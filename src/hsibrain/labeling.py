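"""Semi-automatic gold-standard labeling with the spectral angle mapper.

The labeling workflow mirrors the interactive tool used by neurosurgeons:
pick a reference pixel of known tissue, compute the spectral angle of
every pixel of the pre-processed cube to that reference, threshold the
angle image to select the most similar pixels, and assign them a class.
SAM is scale-invariant, so it compares spectral *shape* — consistent with
running it after per-pixel min-max normalization.

Thresholds are radians throughout the library; the CLI accepts degrees.
"""

from __future__ import annotations

import numpy as np

from hsibrain.hsio import GoldStandardMap
from hsibrain.preprocess import ProcessedCube

__all__ = ["sam_angle", "sam_image", "select_similar", "assign_class"]


def sam_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Spectral angle between two spectra, radians.

    ``arccos(<a, b> / (|a| |b|))`` clipped to [0, pi].  Zero vectors have
    no direction and raise ``ValueError``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("spectra must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cannot compute spectral angle of a zero vector")
    return float(np.arccos(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)))


def sam_image(cube: ProcessedCube, ref_pixel: tuple[int, int]) -> np.ndarray:
    """Per-pixel spectral angle to the spectrum at ``ref_pixel``.

    Degenerate (all-zero) pixel spectra are assigned ``pi`` so no finite
    threshold selects them.
    """
    r, c = ref_pixel
    rows, cols, _ = cube.shape
    if not (0 <= r < rows and 0 <= c < cols):
        raise ValueError(f"reference pixel {ref_pixel} outside image {rows}x{cols}")
    ref = cube.data[r, c]
    ref_norm = np.linalg.norm(ref)
    if ref_norm == 0:
        raise ValueError("reference pixel has a zero (degenerate) spectrum")
    flat = cube.data.reshape(-1, cube.n_bands)
    norms = np.linalg.norm(flat, axis=1)
    cosines = np.full(flat.shape[0], -1.0)
    ok = norms > 0
    cosines[ok] = flat[ok] @ ref / (norms[ok] * ref_norm)
    return np.arccos(np.clip(cosines, -1.0, 1.0)).reshape(rows, cols)


def select_similar(
    cube: ProcessedCube, ref_pixel: tuple[int, int], threshold: float
) -> np.ndarray:
    """Binary mask of pixels within ``threshold`` radians of the reference.

    The reference pixel itself is always selected (its angle is exactly 0).
    A tiny absolute tolerance (1e-7 rad, far below any useful threshold)
    absorbs arccos round-off near zero angle, so a threshold of 0 still
    selects exact positive multiples of the reference.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    angles = sam_image(cube, ref_pixel)
    mask = angles <= threshold + 1e-7
    mask[ref_pixel] = True
    return mask


def assign_class(
    map_: GoldStandardMap, mask: np.ndarray, class_id: int
) -> tuple[GoldStandardMap, int]:
    """Assign ``class_id`` to all masked pixels; last write wins.

    Returns the updated map and the number of previously-labeled pixels
    that were overwritten, so interactive sessions stay auditable.
    """
    if class_id not in (1, 2, 3, 4):
        raise ValueError(f"class_id must be in 1..4, got {class_id}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != map_.shape:
        raise ValueError("mask shape does not match label map")
    conflicts = int(((map_.labels != 0) & (map_.labels != class_id) & mask).sum())
    labels = map_.labels.copy()
    labels[mask] = class_id
    return GoldStandardMap(labels), conflicts
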