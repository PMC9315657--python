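"""Image loading, grayscale conversion and stratified dataset splitting.

Datasets follow the class-per-subfolder layout common to image
classification collections::

    root/
        glioma_like/    img001.png ...
        meningioma_like/ ...

Images are converted to single-channel float intensities in [0, 1].
Colour inputs are combined with the fixed ITU-R 601 luma weights so the
conversion is reproducible across backends.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import DatasetError, FormatError, SplitError

logger = logging.getLogger(__name__)

#: ITU-R 601 luma weights for RGB -> gray.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Feature extraction needs room for at least one descriptor patch.
MIN_SIDE = 32

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class GrayImage:
    """A 2-D intensity field with values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise FormatError(f"GrayImage requires a 2-D array, got ndim={px.ndim}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise FormatError(
                f"image {px.shape} smaller than minimum {MIN_SIDE}x{MIN_SIDE}"
            )
        if not np.all(np.isfinite(px)):
            raise FormatError("image contains non-finite values")
        if px.min() < -1e-12 or px.max() > 1 + 1e-12:
            raise FormatError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def to_grayscale(raster: np.ndarray) -> GrayImage:
    """Convert a 1- or 3-channel raster to a :class:`GrayImage`.

    8-bit inputs are divided by 255.  Float inputs already inside [0, 1]
    are taken as-is; float inputs outside that range are min-max rescaled
    per image.  3-channel inputs are combined with ITU-R 601 luma weights
    (0.299, 0.587, 0.114).
    """
    arr = np.asarray(raster)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim == 3:
        if arr.shape[2] != 3:
            raise FormatError(
                f"unsupported channel count {arr.shape[2]}; expected 1 or 3"
            )
        arr = arr.astype(np.float64) @ LUMA_WEIGHTS
        if np.issubdtype(np.asarray(raster).dtype, np.integer):
            arr = arr / 255.0
    elif arr.ndim == 2:
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.float64) / 255.0
        else:
            arr = arr.astype(np.float64)
    else:
        raise FormatError(f"unsupported raster ndim {arr.ndim}")

    lo, hi = float(arr.min()), float(arr.max())
    if lo < 0.0 or hi > 1.0:
        # float input on an arbitrary scale: per-image min-max to [0, 1]
        span = hi - lo
        arr = (arr - lo) / span if span > 0 else np.zeros_like(arr)
    return GrayImage(arr)


def read_image(path: str | Path) -> GrayImage:
    """Read a PNG/JPEG file and convert it to grayscale."""
    with Image.open(path) as im:
        im = im.convert("RGB") if im.mode not in ("L", "I;16", "F") else im
        arr = np.asarray(im)
    return to_grayscale(arr)


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write a GrayImage as an 8-bit PNG (values quantized to 1/255)."""
    data = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


@dataclass
class LabeledDataset:
    """Paths and labels for a class-per-folder image collection.

    ``items`` is ordered lexicographically by class then filename so every
    downstream stage (vocabulary building in particular) is reproducible
    independent of filesystem enumeration order.
    """

    items: list[tuple[Path, str]]
    classes: tuple[str, ...]
    n_skipped: int = 0

    def __post_init__(self) -> None:
        known = set(self.classes)
        for _, label in self.items:
            if label not in known:
                raise DatasetError(f"label {label!r} not in classes {self.classes}")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> list[str]:
        return [label for _, label in self.items]

    def class_indices(self, label: str) -> list[int]:
        return [i for i, (_, lab) in enumerate(self.items) if lab == label]

    def load_image(self, index: int) -> GrayImage:
        return read_image(self.items[index][0])


def load_dataset(root_path: str | Path) -> LabeledDataset:
    """Enumerate a ``<root>/<class>/<image>`` tree into a LabeledDataset.

    Unreadable files are skipped with a warning (counted in
    ``n_skipped``); an empty class folder is an error naming the folder.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise DatasetError(f"dataset root {root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise DatasetError(f"dataset root {root} contains no class folders")

    items: list[tuple[Path, str]] = []
    n_skipped = 0
    for cdir in class_dirs:
        files = sorted(
            p for p in cdir.iterdir()
            if p.is_file() and p.suffix.lower() in IMAGE_SUFFIXES
        )
        readable = []
        for f in files:
            try:
                with Image.open(f) as im:
                    im.verify()
                readable.append(f)
            except Exception:
                n_skipped += 1
                warnings.warn(f"skipping unreadable image {f}", stacklevel=2)
        if not readable:
            raise DatasetError(f"class folder {cdir} holds no readable images")
        items.extend((f, cdir.name) for f in readable)
    classes = tuple(c.name for c in class_dirs)
    logger.info("loaded %d items in %d classes from %s", len(items), len(classes), root)
    return LabeledDataset(items=items, classes=classes, n_skipped=n_skipped)


@dataclass(frozen=True)
class SplitIndex:
    """Disjoint train/test index lists produced by a seeded stratified split."""

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_indices) & set(self.test_indices):
            raise SplitError("train and test indices overlap")


def stratified_split(
    dataset: LabeledDataset, fraction: float = 0.8, seed: int = 0
) -> SplitIndex:
    """Split per class: ``round(fraction * class_size)`` items go to train.

    The per-class train count is clamped to keep at least one item on each
    side, so the deviation from the configured fraction is at most one
    item.  The shuffle is driven only by ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise SplitError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    for label in dataset.classes:
        idx = np.array(dataset.class_indices(label))
        if idx.size < 2:
            raise SplitError(f"class {label!r} has {idx.size} item(s); need >= 2")
        n_train = int(round(fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx.size)
        train.extend(int(i) for i in idx[perm[:n_train]])
        test.extend(int(i) for i in idx[perm[n_train:]])
    return SplitIndex(
        train_indices=tuple(sorted(train)),
        test_indices=tuple(sorted(test)),
        fraction=fraction,
        seed=seed,
    )


def save_split(split: SplitIndex, path: str | Path) -> None:
    """Write a two-column text file: index, split membership."""
    lines = [f"# fraction={split.fraction} seed={split.seed}"]
    membership = {i: "train" for i in split.train_indices}
    membership.update({i: "test" for i in split.test_indices})
    for i in sorted(membership):
        lines.append(f"{i}\t{membership[i]}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_split(path: str | Path) -> SplitIndex:
    """Read a split file written by :func:`save_split`."""
    fraction, seed = 0.8, 0
    train, test = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            for tok in line[1:].split():
                key, _, val = tok.partition("=")
                if key == "fraction":
                    fraction = float(val)
                elif key == "seed":
                    seed = int(val)
            continue
        idx, _, part = line.partition("\t")
        (train if part == "train" else test).append(int(idx))
    return SplitIndex(tuple(train), tuple(test), fraction, seed)
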