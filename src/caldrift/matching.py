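"""Cross-session neuron matching by registration + structural similarity.

Aligns two mean-fluorescence field-of-view images by integer translation
(phase cross-correlation), extracts a 39×39 patch around every cell
body, scores all day-1 × day-2 patch pairs with the structural
similarity index (SSIM), row-normalizes each day-1 cell's scores by
their maximum, assigns each cell its best-scoring partner, and reports
percent agreement with a reference pairing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment
from skimage.metrics import structural_similarity
from skimage.registration import phase_cross_correlation

__all__ = [
    "MatchResult",
    "register_translation",
    "patch_similarity",
    "match_and_score",
]

PATCH_SIZE = 39


@dataclass(frozen=True)
class MatchResult:
    similarity: np.ndarray  # (n1, n2) SSIM values in [-1, 1]
    normalized_similarity: np.ndarray  # each row / its row max
    assignment: np.ndarray  # per day-1 cell, best day-2 index
    agreement_pct: float


def register_translation(image_a: np.ndarray, image_b: np.ndarray) -> tuple[int, int]:
    """Integer (dy, dx) such that shifting B by −(dy, dx) aligns it to A,
    found by maximizing cross-correlation. Flat images give (0, 0) with
    a warning."""
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("images must be 2-D and equal-sized")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("flat image: returning zero shift")
        return (0, 0)
    # plain (unnormalized) cross-correlation on mildly smoothed images:
    # robust to additive pixel noise, unlike the phase-whitened variant
    a = gaussian_filter(a, 1.0)
    b = gaussian_filter(b, 1.0)
    shift, _, _ = phase_cross_correlation(a, b, upsample_factor=1, normalization=None)
    # phase_cross_correlation returns the shift to apply to B to match A;
    # B = A translated by (dy, dx) gives shift = (-dy, -dx)
    return (int(-shift[0]), int(-shift[1]))


def _extract_patch(image: np.ndarray, center: tuple[float, float], size: int = PATCH_SIZE) -> tuple[np.ndarray, bool]:
    """Square patch centered on (y, x), zero-padded at borders.

    Returns (patch, padded_flag)."""
    half = size // 2
    cy, cx = int(round(center[0])), int(round(center[1]))
    y0, y1 = cy - half, cy + half + 1
    x0, x1 = cx - half, cx + half + 1
    h, w = image.shape
    patch = np.zeros((size, size), dtype=float)
    sy0, sy1 = max(y0, 0), min(y1, h)
    sx0, sx1 = max(x0, 0), min(x1, w)
    padded = (sy0, sy1, sx0, sx1) != (y0, y1, x0, x1)
    patch[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = image[sy0:sy1, sx0:sx1]
    return patch, padded


def patch_similarity(patch_a: np.ndarray, patch_b: np.ndarray) -> float:
    """Structural similarity index of two aligned cell-body patches
    (Gaussian weighting, standard stabilizing constants)."""
    a = np.asarray(patch_a, dtype=float)
    b = np.asarray(patch_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("patch size mismatch")
    data_range = max(a.max() - a.min(), b.max() - b.min())
    if data_range == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(
        structural_similarity(
            a, b, gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
            data_range=data_range,
        )
    )


def match_and_score(
    day1_image: np.ndarray,
    day2_image: np.ndarray,
    roi_centers_1: np.ndarray,
    roi_centers_2: np.ndarray,
    reference_pairing: np.ndarray,
    one_to_one: bool = False,
) -> MatchResult:
    """Full matching pipeline: register, patch, score, assign, agree.

    Both center lists are given in the day-1 reference frame (the frame
    in which cells are book-kept across days); registration estimates
    the day-2 image's translation and day-2 patches are extracted at
    ``center + shift`` in the day-2 image. ``reference_pairing[i]``
    gives the day-2 index considered the true match of day-1 cell i.
    Per-row argmax assignment by default (each neuron's matches ranked
    independently); ``one_to_one`` switches to a Hungarian globally
    optimal one-to-one assignment.
    """
    c1 = np.asarray(roi_centers_1, dtype=float)
    c2 = np.asarray(roi_centers_2, dtype=float)
    ref = np.asarray(reference_pairing, dtype=int)
    if ref.shape[0] != c1.shape[0]:
        raise ValueError("reference pairing must cover every day-1 cell")

    dy, dx = register_translation(day1_image, day2_image)
    shift = np.array([dy, dx], dtype=float)

    n1, n2 = c1.shape[0], c2.shape[0]
    day2_patches = []
    any_padded = False
    for j in range(n2):
        pb, pad_b = _extract_patch(day2_image, tuple(c2[j] + shift))
        any_padded |= pad_b
        day2_patches.append(pb)
    sim = np.empty((n1, n2))
    for i in range(n1):
        pa, pad_a = _extract_patch(day1_image, tuple(c1[i]))
        any_padded |= pad_a
        for j in range(n2):
            sim[i, j] = patch_similarity(pa, day2_patches[j])
    if any_padded:
        warnings.warn("some patches extended past image borders (zero-padded)")

    row_max = sim.max(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(row_max != 0, sim / row_max, 0.0)

    if one_to_one:
        rows, cols = linear_sum_assignment(-sim)
        assignment = np.full(n1, -1, dtype=int)
        assignment[rows] = cols
    else:
        assignment = sim.argmax(axis=1)

    agreement = 100.0 * float(np.mean(assignment == ref))
    return MatchResult(
        similarity=sim,
        normalized_similarity=norm,
        assignment=assignment,
        agreement_pct=agreement,
    )
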