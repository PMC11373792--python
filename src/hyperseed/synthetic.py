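"""Synthetic hyperspectral seed scenes with known ground truth.

Emulates the benchtop acquisition geometry this package targets: a dark
stage carrying non-overlapping, roughly ellipsoidal seeds, imaged as a
reflectance cube of a few hundred contiguous bands over 400-1000 nm.
Each seed class gets a reflectance signature = flat baseline + Gaussian
bumps at chosen wavelengths, so between-class contrast is concentrated
at known bands and the band-selection search has a planted optimum.

The generator is the test bed for the whole pipeline: the per-pixel
spectrum inside a seed is exactly ``baseline + class bumps`` when
``noise_sd == 0``, and every scene ships with an instance label mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hsi_io import HyperCube, WavelengthCalibration, default_calibration, write_envi_cube

__all__ = [
    "GaussianBump",
    "ClassSignature",
    "SyntheticSceneSpec",
    "GroundTruth",
    "PlacementError",
    "generate_scene",
    "generate_corpus",
    "default_three_class_spec",
]


class PlacementError(RuntimeError):
    """Requested seeds cannot be packed with the stated minimum gap."""


@dataclass(frozen=True)
class GaussianBump:
    """One Gaussian reflectance bump: exp(-(lambda-center)^2 / 2 width^2)."""

    center_nm: float
    width_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("bump amplitude must be >= 0")
        if self.width_nm <= 0:
            raise ValueError("bump width must be > 0")


@dataclass(frozen=True)
class ClassSignature:
    """Per-class reflectance model over a shared baseline."""

    label: str
    bumps: tuple[GaussianBump, ...]

    def reflectance(self, wavelengths_nm: np.ndarray, baseline: float) -> np.ndarray:
        spec = np.full(wavelengths_nm.shape, baseline, dtype=np.float32)
        for b in self.bumps:
            spec += b.amplitude * np.exp(
                -0.5 * ((wavelengths_nm - b.center_nm) / b.width_nm) ** 2
            ).astype(np.float32)
        return spec


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Full description of one synthetic scene family.

    Defaults model the desk-scale acquisition: 462 bands over the fitted
    400-1000 nm calibration, a dark stage (background reflectance 0.04),
    seed baseline reflectance 0.30, seeds 8-14 px in semi-axis with a
    6 px minimum gap, additive Gaussian noise of 0.01 reflectance units.
    """

    signatures: tuple[ClassSignature, ...]
    seeds_per_class: int = 4
    image_size: tuple[int, int] = (160, 220)  # (lines, samples)
    band_count: int = 462
    baseline: float = 0.30
    background: float = 0.04
    axis_range: tuple[int, int] = (8, 14)
    min_gap: int = 6
    noise_sd: float = 0.01
    rng_seed: int = 0
    calibration: WavelengthCalibration | None = None

    def __post_init__(self) -> None:
        if self.seeds_per_class < 0:
            raise ValueError("seeds_per_class must be >= 0")
        if self.band_count < 1:
            raise ValueError("band_count must be >= 1")
        if self.axis_range[0] < 1 or self.axis_range[1] < self.axis_range[0]:
            raise ValueError("invalid axis_range")

    @property
    def n_classes(self) -> int:
        return len(self.signatures)

    @property
    def class_labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.signatures)

    def get_calibration(self) -> WavelengthCalibration:
        return self.calibration or default_calibration(self.band_count)


@dataclass
class GroundTruth:
    """Instance labels for one generated scene.

    ``label_mask`` holds 0 for background and the 1-based instance id
    elsewhere; ``instances`` carries, per id (in order), the class label,
    ellipse parameters and tight bounding box.
    """

    label_mask: np.ndarray
    instances: list[dict]

    def n_instances(self) -> int:
        return len(self.instances)

    def instance_mask(self, instance_id: int) -> np.ndarray:
        return self.label_mask == instance_id


def _place_ellipses(
    spec: SyntheticSceneSpec, rng: np.random.Generator
) -> list[dict]:
    """Rejection-sample non-overlapping ellipses; bounded retries."""
    lines, samples = spec.image_size
    placed: list[dict] = []
    max_tries = 200 * max(1, spec.n_classes * spec.seeds_per_class)
    tries = 0
    for ci, sig in enumerate(spec.signatures):
        for _ in range(spec.seeds_per_class):
            while True:
                tries += 1
                if tries > max_tries:
                    raise PlacementError(
                        f"could not place {spec.n_classes * spec.seeds_per_class} "
                        f"seeds in a {lines}x{samples} frame with min_gap="
                        f"{spec.min_gap}; reduce seed count/size or gap"
                    )
                a = rng.integers(spec.axis_range[0], spec.axis_range[1] + 1)
                b = rng.integers(spec.axis_range[0], spec.axis_range[1] + 1)
                theta = rng.uniform(0, np.pi)
                r_max = max(a, b)
                cy = rng.integers(r_max + 1, lines - r_max - 1) if lines > 2 * r_max + 2 else None
                cx = rng.integers(r_max + 1, samples - r_max - 1) if samples > 2 * r_max + 2 else None
                if cy is None or cx is None:
                    raise PlacementError(
                        f"frame {lines}x{samples} too small for seeds of semi-axis {r_max}"
                    )
                ok = True
                for other in placed:
                    d = np.hypot(cy - other["cy"], cx - other["cx"])
                    if d < r_max + max(other["a"], other["b"]) + spec.min_gap:
                        ok = False
                        break
                if ok:
                    placed.append(
                        {
                            "class_index": ci,
                            "class_label": sig.label,
                            "cy": int(cy),
                            "cx": int(cx),
                            "a": int(a),
                            "b": int(b),
                            "theta": float(theta),
                        }
                    )
                    break
    return placed


def _rasterize(ellipse: dict, shape: tuple[int, int]) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = yy - ellipse["cy"]
    dx = xx - ellipse["cx"]
    c, s = np.cos(ellipse["theta"]), np.sin(ellipse["theta"])
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / ellipse["a"]) ** 2 + (v / ellipse["b"]) ** 2 <= 1.0


def generate_scene(spec: SyntheticSceneSpec) -> tuple[HyperCube, GroundTruth]:
    """Generate one seeded scene: reflectance cube plus instance mask.

    Deterministic for a fixed ``spec.rng_seed``; raises
    :class:`PlacementError` when the packing constraint is infeasible.
    """
    rng = np.random.default_rng(spec.rng_seed)
    lines, samples = spec.image_size
    cal = spec.get_calibration()
    wavelengths = cal.wavelengths().astype(np.float32)

    cube = np.full((lines, samples, spec.band_count), spec.background, dtype=np.float32)
    label_mask = np.zeros((lines, samples), dtype=np.int32)
    instances: list[dict] = []

    if spec.seeds_per_class > 0:
        ellipses = _place_ellipses(spec, rng)
        for iid, ell in enumerate(ellipses, start=1):
            mask = _rasterize(ell, (lines, samples))
            sig = spec.signatures[ell["class_index"]]
            cube[mask] = sig.reflectance(wavelengths, spec.baseline)
            label_mask[mask] = iid
            rows, cols = np.nonzero(mask)
            bbox = (int(rows.min()), int(cols.min()),
                    int(rows.max() - rows.min() + 1), int(cols.max() - cols.min() + 1))
            instances.append({**ell, "instance_id": iid, "bbox": bbox,
                              "area": int(mask.sum())})

    if spec.noise_sd > 0:
        cube += rng.normal(0.0, spec.noise_sd, size=cube.shape).astype(np.float32)
    np.clip(cube, 0.0, 1.0, out=cube)

    hyper = HyperCube(data=cube, interleave="bil", calibration=cal)
    return hyper, GroundTruth(label_mask=label_mask, instances=instances)


def generate_corpus(
    spec: SyntheticSceneSpec, n_scenes: int
) -> tuple[list[tuple[HyperCube, GroundTruth]], pd.DataFrame]:
    """Generate ``n_scenes`` scenes with per-scene seeds derived from the base seed.

    Scene ``i`` uses ``rng_seed + i``. The manifest records one row per
    instance (scene, instance id, class label, area) so class balance is
    auditable: each class appears ``n_scenes * seeds_per_class`` times.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    scenes = []
    rows = []
    for i in range(n_scenes):
        scene_spec = replace(spec, rng_seed=spec.rng_seed + i)
        cube, gt = generate_scene(scene_spec)
        scenes.append((cube, gt))
        for inst in gt.instances:
            rows.append(
                {
                    "scene": i,
                    "instance_id": inst["instance_id"],
                    "class_label": inst["class_label"],
                    "area": inst["area"],
                }
            )
    manifest = pd.DataFrame(rows, columns=["scene", "instance_id", "class_label", "area"])
    return scenes, manifest


def save_scene(
    cube: HyperCube, gt: GroundTruth, out_dir: str | Path, name: str
) -> dict[str, Path]:
    """Persist one scene: ENVI cube, paletted PNG label mask, JSON instances."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = write_envi_cube(cube, out_dir / name)

    mask_path = out_dir / f"{name}_labels.png"
    if gt.label_mask.max() > 255:
        raise ValueError("more than 255 instances cannot be stored as 8-bit PNG")
    img = Image.fromarray(gt.label_mask.astype(np.uint8), mode="P")
    palette = [0, 0, 0]
    rng = np.random.default_rng(12345)
    palette += list(rng.integers(40, 255, size=255 * 3))
    img.putpalette(palette[: 256 * 3])
    img.save(mask_path)

    json_path = out_dir / f"{name}_instances.json"
    json_path.write_text(json.dumps(gt.instances, indent=1))
    return {"header": header, "mask": mask_path, "instances": json_path}


BUMP_WIDTH_NM = 3.0  # ~2 band steps: signal is confined to the planted bands
BUMP_AMPLITUDE = 0.35


def default_three_class_spec(
    rng_seed: int = 0,
    noise_sd: float = 0.01,
    band_count: int = 462,
    planted_triple: tuple[int, int, int] = (188, 83, 41),
) -> SyntheticSceneSpec:
    """Three seed classes separable at a planted (R, G, B) band triple.

    Class A is bright at the planted red band, class B at the green
    band, class C at the blue band (narrow 3 nm bumps of amplitude
    0.35 over the common 0.30 baseline), so the planted triple carries
    all between-class contrast. The packaged end-to-end experiments
    classify this corpus.
    """
    cal = default_calibration(band_count)
    r_nm, g_nm, b_nm = (cal.wavelength_of_band(b) for b in planted_triple)
    sigs = (
        ClassSignature("A", (GaussianBump(r_nm, BUMP_WIDTH_NM, BUMP_AMPLITUDE),)),
        ClassSignature("B", (GaussianBump(g_nm, BUMP_WIDTH_NM, BUMP_AMPLITUDE),)),
        ClassSignature("C", (GaussianBump(b_nm, BUMP_WIDTH_NM, BUMP_AMPLITUDE),)),
    )
    return SyntheticSceneSpec(
        signatures=sigs,
        rng_seed=rng_seed,
        noise_sd=noise_sd,
        band_count=band_count,
    )


def band_search_spec(
    rng_seed: int = 0,
    noise_sd: float = 0.01,
    band_count: int = 462,
    planted_triple: tuple[int, int, int] = (188, 83, 41),
) -> SyntheticSceneSpec:
    """Four-class corpus on which the planted triple is uniquely optimal.

    Classes A/B/C carry one narrow bump each at the planted red, green
    and blue bands; class D is baseline-only. Dropping any planted band
    therefore collapses one (class, D) pair, so no triple that misses a
    planted band can reach the planted triple's accuracy — the property
    the band-search recovery tests rely on. Geometry is scaled down
    (smaller seeds, smaller frame) so a multi-scene corpus stays cheap.
    """
    cal = default_calibration(band_count)
    r_nm, g_nm, b_nm = (cal.wavelength_of_band(b) for b in planted_triple)
    sigs = (
        ClassSignature("A", (GaussianBump(r_nm, BUMP_WIDTH_NM, BUMP_AMPLITUDE),)),
        ClassSignature("B", (GaussianBump(g_nm, BUMP_WIDTH_NM, BUMP_AMPLITUDE),)),
        ClassSignature("C", (GaussianBump(b_nm, BUMP_WIDTH_NM, BUMP_AMPLITUDE),)),
        ClassSignature("D", ()),
    )
    return SyntheticSceneSpec(
        signatures=sigs,
        seeds_per_class=3,
        image_size=(110, 150),
        axis_range=(6, 10),
        min_gap=5,
        rng_seed=rng_seed,
        noise_sd=noise_sd,
        band_count=band_count,
    )
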