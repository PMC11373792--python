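"""Sixfold seed-crop augmentation (sevenfold dataset with originals).

Each crop is expanded with six fixed transforms, in this order:
45-degree rotation, 90-degree rotation, color enhancement, brightness
enhancement, horizontal mirroring, contrast enhancement. Enhancement
factors default to 1.3 and are fixed (no jitter) so the expansion is
fully reproducible. Normalization is applied at training time, not
baked into the stored images, so augmented crops stay inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageEnhance

from .segmentation import SeedCrop

__all__ = ["AugmentationParams", "TRANSFORM_NAMES", "augment_seed", "expand_dataset"]

TRANSFORM_NAMES = ("rot45", "rot90", "color", "brightness", "mirror", "contrast")
EXPANSION_FACTOR = 1 + len(TRANSFORM_NAMES)  # originals retained -> 7x


@dataclass(frozen=True)
class AugmentationParams:
    brightness_factor: float = 1.3
    color_factor: float = 1.3
    contrast_factor: float = 1.3
    rotation_fill: int = 0  # black corners, matching the crop fill policy
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("brightness_factor", "color_factor", "contrast_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _apply_transform(pixels: np.ndarray, name: str, params: AugmentationParams) -> np.ndarray:
    img = Image.fromarray(pixels)
    if name == "rot45":
        # rotate on the fixed canvas; corners filled with the crop fill value
        out = img.rotate(45, resample=Image.BILINEAR,
                         fillcolor=(params.rotation_fill,) * 3)
    elif name == "rot90":
        out = img.transpose(Image.ROTATE_90)
    elif name == "color":
        out = ImageEnhance.Color(img).enhance(params.color_factor)
    elif name == "brightness":
        out = ImageEnhance.Brightness(img).enhance(params.brightness_factor)
    elif name == "mirror":
        out = img.transpose(Image.FLIP_LEFT_RIGHT)
    elif name == "contrast":
        out = ImageEnhance.Contrast(img).enhance(params.contrast_factor)
    else:
        raise ValueError(f"unknown transform {name!r}")
    return np.asarray(out)


def augment_seed(crop: SeedCrop, params: AugmentationParams = AugmentationParams()) -> list[SeedCrop]:
    """The six transformed variants of one crop, in fixed order.

    Outputs share the input's dimensions, label and provenance; each
    records its transform name. With the original retained the family
    size is 7.
    """
    out = []
    for name in TRANSFORM_NAMES:
        pixels = _apply_transform(crop.pixels, name, params)
        out.append(dc_replace(crop, pixels=pixels, transform=name))
    return out


def expand_dataset(
    manifest: pd.DataFrame,
    params: AugmentationParams = AugmentationParams(),
) -> pd.DataFrame:
    """Sevenfold manifest expansion: originals plus six variants each.

    ``manifest`` needs columns ``path`` and ``label`` (extra columns are
    carried through); rows gain ``transform`` and ``origin`` columns,
    where ``origin`` is the original row's path — the provenance handle
    the splitter's leakage guard groups on. Output paths suffix the
    transform name before the extension. Raises on path collisions.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    if not {"path", "label"} <= set(manifest.columns):
        raise ValueError("manifest must have 'path' and 'label' columns")
    rows = []
    for _, row in manifest.iterrows():
        base = dict(row)
        rows.append({**base, "transform": "original", "origin": row["path"]})
        stem, dot, ext = str(row["path"]).rpartition(".")
        for name in TRANSFORM_NAMES:
            new_path = f"{stem}_{name}.{ext}" if dot else f"{row['path']}_{name}"
            rows.append({**base, "path": new_path, "transform": name, "origin": row["path"]})
    out = pd.DataFrame(rows)
    if out["path"].duplicated().any():
        dupes = out.loc[out["path"].duplicated(), "path"].tolist()[:5]
        raise ValueError(f"augmented path collision, e.g. {dupes}")
    return out.reset_index(drop=True)


def augment_crop_array(
    crops: Sequence[SeedCrop], params: AugmentationParams = AugmentationParams()
) -> list[SeedCrop]:
    """In-memory sevenfold expansion of a crop list (originals first order
    preserved: each original followed by its six variants)."""
    out: list[SeedCrop] = []
    for crop in crops:
        out.append(crop)
        out.extend(augment_seed(crop, params))
    return out
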