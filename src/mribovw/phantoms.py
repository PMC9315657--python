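"""Seeded MRI-like phantom images with class-dependent lesion structure.

Four phantom classes mimic the geometry of axial brain-MRI tumor
categories without any anatomical physics:

* ``glioma_like`` — a large, irregular, multi-lobed bright region with
  noisy internal texture anywhere inside the brain;
* ``meningioma_like`` — a smooth, round bright disc attached to the
  brain periphery;
* ``pituitary_like`` — a small, sharp bright blob near the brain
  centre;
* ``no_tumor`` — brain texture only.

Lesion intensity bands overlap across classes so a mean-intensity
shortcut cannot separate them: the classes differ in geometry, edge
sharpness and internal texture — exactly what bag-of-visual-words local
descriptors measure.  Every image is perturbed by seeded rotation/scale
jitter and additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .dataset_io import GrayImage, LabeledDataset, load_dataset, write_image

PHANTOM_CLASSES = (
    "glioma_like",
    "meningioma_like",
    "no_tumor",
    "pituitary_like",
)

#: Lesion intensity band shared by all tumor classes (deliberately
#: overlapping so intensity alone cannot identify the class).
TUMOR_INTENSITY_RANGE = (0.68, 0.85)

BRAIN_BASE = 0.42
BRAIN_TEXTURE_AMP = 0.07
BACKGROUND = 0.05


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters for one phantom image."""

    class_label: str
    image_size: int = 96
    noise_sigma: float = 0.02
    rotation_deg: float = 15.0       # jitter range: +/- this many degrees
    scale_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in PHANTOM_CLASSES:
            raise ValueError(
                f"class_label must be one of {PHANTOM_CLASSES}, got {self.class_label!r}"
            )
        if self.image_size < 96:
            raise ValueError(f"image_size must be >= 96, got {self.image_size}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _render(spec: PhantomSpec) -> dict:
    """Render a phantom; returns image plus the masks used to build it."""
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    # normalized coordinates in [-1, 1]
    lin = np.linspace(-1.0, 1.0, n)
    yy, xx = np.meshgrid(lin, lin, indexing="ij")

    theta = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
    s = rng.uniform(*spec.scale_range)
    # rotate and scale the evaluation frame (equivalently the shapes)
    xr = (np.cos(theta) * xx + np.sin(theta) * yy) / s
    yr = (-np.sin(theta) * xx + np.cos(theta) * yy) / s

    brain_mask = (xr / 0.72) ** 2 + (yr / 0.60) ** 2 <= 1.0

    texture = ndimage.gaussian_filter(rng.standard_normal((n, n)), 3.0)
    texture *= BRAIN_TEXTURE_AMP / max(np.abs(texture).max(), 1e-12)
    # gentle radial shading like a coil-intensity falloff
    shading = 0.04 * (1.0 - (xr**2 + yr**2))

    img = np.full((n, n), BACKGROUND)
    img[brain_mask] = BRAIN_BASE + texture[brain_mask] + shading[brain_mask]

    tumor_soft = np.zeros((n, n))
    tumor_mask = np.zeros((n, n), dtype=bool)
    level = rng.uniform(*TUMOR_INTENSITY_RANGE)

    def dist2(cx, cy, ax, ay):
        return ((xr - cx) / ax) ** 2 + ((yr - cy) / ay) ** 2

    if spec.class_label == "glioma_like":
        # several overlapping lobes around one anchor inside the brain
        cx, cy = rng.uniform(-0.28, 0.28, size=2)
        n_lobes = rng.integers(3, 6)
        for _ in range(n_lobes):
            ox, oy = rng.uniform(-0.18, 0.18, size=2)
            ax, ay = rng.uniform(0.13, 0.24, size=2)
            tumor_mask |= dist2(cx + ox, cy + oy, ax, ay) <= 1.0
        tumor_mask &= brain_mask
        tumor_soft = ndimage.gaussian_filter(tumor_mask.astype(float), 1.0)
        rough = ndimage.gaussian_filter(rng.standard_normal((n, n)), 0.7)
        rough *= 0.16 / max(np.abs(rough).max(), 1e-12)
        lesion = (level + rough) * tumor_soft
    elif spec.class_label == "meningioma_like":
        # smooth round disc attached to the periphery
        ang = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(0.42, 0.50)
        cx, cy = 0.72 * r * np.cos(ang), 0.60 * r * np.sin(ang)
        rad = rng.uniform(0.16, 0.20)
        tumor_mask = (dist2(cx, cy, rad, rad) <= 1.0) & brain_mask
        tumor_soft = ndimage.gaussian_filter(tumor_mask.astype(float), 2.0)
        lesion = level * tumor_soft
    elif spec.class_label == "pituitary_like":
        # small sharp blob near the centre
        cx, cy = rng.uniform(-0.10, 0.10, size=2)
        rad = rng.uniform(0.080, 0.110)
        tumor_mask = (dist2(cx, cy, rad, rad) <= 1.0) & brain_mask
        tumor_soft = ndimage.gaussian_filter(tumor_mask.astype(float), 0.4)
        lesion = level * tumor_soft
    else:  # no_tumor
        lesion = np.zeros((n, n))

    img = img * (1.0 - tumor_soft) + lesion
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=(n, n))
    img = np.clip(img, 0.0, 1.0)
    return {
        "image": GrayImage(img),
        "brain_mask": brain_mask,
        "tumor_mask": tumor_mask,
        "intensity_level": level,
    }


def make_phantom(spec: PhantomSpec) -> tuple[GrayImage, str]:
    """Render one seeded phantom image and return it with its label."""
    return _render(spec)["image"], spec.class_label


def _derive_seed(master_seed: int, index: int) -> int:
    # simple splittable derivation, kept below 2**31
    return int((master_seed * 1_000_003 + index * 7919 + 17) % (2**31 - 1))


def make_dataset(
    n_per_class: int,
    root_path: str | Path,
    seed: int = 0,
    image_size: int = 96,
    noise_sigma: float = 0.02,
    classes: tuple[str, ...] = PHANTOM_CLASSES,
) -> LabeledDataset:
    """Write a class-per-folder PNG phantom dataset and load it back.

    Per-image seeds derive deterministically from the master seed, so
    re-running with the same arguments reproduces identical files.
    """
    if n_per_class < 2:
        raise ValueError(f"n_per_class must be >= 2, got {n_per_class}")
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    idx = 0
    for label in classes:
        cdir = root / label
        cdir.mkdir(exist_ok=True)
        for i in range(n_per_class):
            spec = PhantomSpec(
                class_label=label,
                image_size=image_size,
                noise_sigma=noise_sigma,
                seed=_derive_seed(seed, idx),
            )
            img, _ = make_phantom(spec)
            write_image(img, cdir / f"{label}_{i:04d}.png")
            idx += 1
    return load_dataset(root)
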