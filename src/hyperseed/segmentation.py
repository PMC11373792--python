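"""Single-seed isolation from scene images.

The chain is the classical bright-object recipe for seeds on a dark
stage: luminance grayscale -> Otsu binarization -> border-connected
hole filling -> morphological opening -> 8-connected component
labelling -> per-component crops resized to the classifier input size.
Touching seeds are not split; a low-solidity component is a merge
candidate and can be filtered by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.measure import label as cc_label, regionprops
from skimage.transform import resize

__all__ = [
    "SeedMask",
    "SeedCrop",
    "to_grayscale",
    "otsu_threshold",
    "binarize",
    "fill_holes",
    "extract_seed_masks",
    "crop_seed",
    "segment_scene",
]

GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class SeedMask:
    """Boolean mask of one connected seed component.

    ``bbox`` is the tight (row, col, height, width) box; ``mask`` is the
    full-frame boolean array; ``solidity`` (area / convex area) flags
    merged seeds when low.
    """

    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    area: int
    component_id: int
    solidity: float = 1.0


@dataclass
class SeedCrop:
    """One segmented seed resized to the classifier input size."""

    pixels: np.ndarray  # (out_size, out_size, 3) uint8
    label: str | None
    scene_id: str | None = None
    band_triple: tuple[int, int, int] | None = None
    component_id: int | None = None
    transform: str = "original"


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Luminance grayscale with fixed (0.299, 0.587, 0.114) weights.

    Accepts (H, W, 3) uint8 or float; returns uint8 with round-to-nearest.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {rgb.shape}")
    gray = rgb[..., 0] * GRAY_WEIGHTS[0] + rgb[..., 1] * GRAY_WEIGHTS[1] + rgb[..., 2] * GRAY_WEIGHTS[2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's threshold by exhaustive scan of the 256-level histogram.

    Returns the level t maximizing between-class variance of the split
    ``(<= t, > t)``; ties break toward the lower level. For a constant
    image every split is degenerate and 0 is returned (all background
    under ``> t`` foreground polarity when the constant is 0... callers
    use :func:`binarize`, which special-cases constants explicitly).
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("expected single-channel image")
    hist = np.bincount(gray.ravel().astype(np.uint8), minlength=256).astype(np.float64)
    total = hist.sum()
    omega0 = np.cumsum(hist) / total          # weight of class <= t
    mu_t = np.cumsum(hist * np.arange(256)) / total
    mu_total = mu_t[-1]
    omega1 = 1.0 - omega0
    valid = (omega0 > 0) & (omega1 > 0)
    sigma_b = np.zeros(256)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b[valid] = (mu_total * omega0 - mu_t)[valid] ** 2 / (omega0 * omega1)[valid]
    if not valid.any():
        return 0
    return int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximizer


def binarize(gray: np.ndarray, invert: bool = False) -> np.ndarray:
    """Otsu binarization; foreground = above threshold (bright seeds).

    A constant image yields all background. ``invert=True`` flips the
    polarity for dark objects on a bright stage.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("expected single-channel image")
    if gray.min() == gray.max():
        return np.zeros(gray.shape, dtype=bool)
    t = otsu_threshold(gray)
    fg = gray > t
    return ~fg if invert else fg


def fill_holes(binary: np.ndarray) -> np.ndarray:
    """Set background regions not connected to the border to foreground."""
    binary = np.asarray(binary, dtype=bool)
    return ndimage.binary_fill_holes(binary)


def extract_seed_masks(
    binary: np.ndarray,
    min_area: int | None = None,
    opening_radius: int = 2,
) -> list[SeedMask]:
    """Opening + 8-connected labelling + area filter -> per-seed masks.

    ``min_area`` defaults to 0.1% of the frame pixels. Masks are
    returned in raster order of their bounding-box top-left corner.
    """
    binary = np.asarray(binary, dtype=bool)
    if min_area is None:
        min_area = max(1, int(0.001 * binary.size))
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    opened = binary
    if opening_radius > 0:
        opened = morphology.opening(binary, morphology.disk(opening_radius))
    labels = cc_label(opened, connectivity=2)
    masks: list[SeedMask] = []
    for prop in regionprops(labels):
        if prop.area < min_area:
            continue
        r0, c0, r1, c1 = prop.bbox
        masks.append(
            SeedMask(
                mask=labels == prop.label,
                bbox=(r0, c0, r1 - r0, c1 - c0),
                area=int(prop.area),
                component_id=int(prop.label),
                solidity=float(prop.solidity),
            )
        )
    masks.sort(key=lambda m: (m.bbox[0], m.bbox[1]))
    for i, m in enumerate(masks, start=1):
        m.component_id = i
    return masks


def crop_seed(
    image: np.ndarray,
    mask: SeedMask,
    pad: int = 4,
    out_size: int = 224,
    label: str | None = None,
    scene_id: str | None = None,
    band_triple: tuple[int, int, int] | None = None,
) -> SeedCrop:
    """Cut one seed out of the frame and resize to ``out_size`` square.

    The bounding box is expanded by ``pad`` (clamped to the frame),
    out-of-mask pixels are blacked out before resizing, and the result
    is bilinearly resized to ``out_size x out_size x 3`` uint8.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected (H, W, 3) image")
    if mask.area == 0 or not mask.mask.any():
        raise ValueError("empty mask")
    r, c, h, w = mask.bbox
    r0 = max(0, r - pad)
    c0 = max(0, c - pad)
    r1 = min(image.shape[0], r + h + pad)
    c1 = min(image.shape[1], c + w + pad)
    window = image[r0:r1, c0:c1].astype(np.float64).copy()
    window[~mask.mask[r0:r1, c0:c1]] = 0.0
    if window.shape[:2] != (out_size, out_size):
        window = resize(window, (out_size, out_size), order=1, mode="constant",
                        anti_aliasing=False, preserve_range=True)
    pixels = np.clip(np.rint(window), 0, 255).astype(np.uint8)
    return SeedCrop(
        pixels=pixels,
        label=label,
        scene_id=scene_id,
        band_triple=band_triple,
        component_id=mask.component_id,
    )


def segment_scene(
    rgb: np.ndarray,
    min_area: int | None = None,
    opening_radius: int = 2,
    invert: bool = False,
) -> list[SeedMask]:
    """Full chain grayscale -> Otsu -> fill holes -> opening -> masks."""
    gray = to_grayscale(rgb)
    binary = fill_holes(binarize(gray, invert=invert))
    return extract_seed_masks(binary, min_area=min_area, opening_radius=opening_radius)
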