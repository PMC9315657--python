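"""Shared descriptor container and 4x4 patch-pooling geometry.

Both feature families (Gaussian scale space and nonlinear scale space)
produce 64-element local descriptors: a square patch centred on a grid
point is divided into a 4x4 layout of subregions, each subregion is
sampled on a 5x5 lattice of points, and the four statistics
(sum dx, sum dy, sum |dx|, sum |dy|) of the Gaussian-weighted first-order
responses are concatenated over subregions (4 * 4 * 4 = 64).  The layout
lives here so both families share one geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

DESCRIPTOR_LENGTH = 64
SUBREGION_GRID = 4      # 4x4 subregions per patch
SAMPLES_PER_SUB = 5     # 5x5 sample lattice per subregion
FORMAT_VERSION = 1

#: Width of the Gaussian weight relative to the patch scale sigma,
#: matching the classic descriptor-weighting convention.
WEIGHT_SIGMA_FACTOR = 3.3

#: sigma for a patch of side s: the 9-pixel base filter corresponds to
#: sigma = 1.2, so sigma scales as s * 1.2 / 9.
SIGMA_PER_SCALE = 1.2 / 9.0


def scale_to_sigma(scale: int | float) -> float:
    """Nominal Gaussian sigma for a patch/filter of side ``scale`` pixels."""
    return float(scale) * SIGMA_PER_SCALE


@lru_cache(maxsize=32)
def sample_layout(scale: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampling offsets, Gaussian weights and subregion ids for one patch.

    Returns ``(offsets, weights, sub_index)`` where ``offsets`` is an
    (M, 2) float array of (drow, dcol) offsets from the patch centre,
    ``weights`` the per-sample Gaussian weight and ``sub_index`` the
    row-major subregion id in 0..15.  M = (4*5)**2 = 400.
    """
    n = SUBREGION_GRID * SAMPLES_PER_SUB  # 20 samples per axis
    # sample centres at (i + 0.5)/n of the patch, relative to the centre
    rel = (np.arange(n) + 0.5) / n * scale - scale / 2.0
    drow, dcol = np.meshgrid(rel, rel, indexing="ij")
    offsets = np.stack([drow.ravel(), dcol.ravel()], axis=1)

    sigma_w = WEIGHT_SIGMA_FACTOR * scale_to_sigma(scale)
    d2 = rel[:, None] ** 2 + rel[None, :] ** 2
    weights = np.exp(-d2 / (2.0 * sigma_w**2)).ravel()

    sub = np.arange(n) // SAMPLES_PER_SUB
    sub_r, sub_c = np.meshgrid(sub, sub, indexing="ij")
    sub_index = (sub_r * SUBREGION_GRID + sub_c).ravel()
    return offsets, weights, sub_index


def pool_responses(
    dx: np.ndarray, dy: np.ndarray, weights: np.ndarray, sub_index: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pool weighted responses into 64-element descriptors.

    ``dx``/``dy`` have shape (..., M) over the M sample points.  Returns
    ``(vectors, strengths)``: L2-normalized descriptors of shape
    (..., 64) and the element variance of the raw vector (the strength
    used for redundant-feature selection).  Constant patches yield the
    zero vector with strength 0.
    """
    wdx = dx * weights
    wdy = dy * weights
    n_sub = SUBREGION_GRID * SUBREGION_GRID
    lead = wdx.shape[:-1]
    raw = np.zeros(lead + (n_sub, 4), dtype=np.float64)
    for s in range(n_sub):
        mask = sub_index == s
        raw[..., s, 0] = wdx[..., mask].sum(axis=-1)
        raw[..., s, 1] = wdy[..., mask].sum(axis=-1)
        raw[..., s, 2] = np.abs(wdx[..., mask]).sum(axis=-1)
        raw[..., s, 3] = np.abs(wdy[..., mask]).sum(axis=-1)
    raw = raw.reshape(lead + (DESCRIPTOR_LENGTH,))
    norms = np.linalg.norm(raw, axis=-1, keepdims=True)
    # constant patches leave only float cancellation noise; snap to zero
    degenerate = norms <= 1e-9
    raw = np.where(degenerate, 0.0, raw)
    strengths = raw.var(axis=-1)
    safe = np.where(degenerate, 1.0, norms)
    return raw / safe, strengths


@dataclass
class DescriptorSet:
    """N local descriptors of one family with positions, scales, strengths.

    ``family`` is ``"gaussian"`` or ``"nonlinear"``; ``image_ids`` records
    which image each row came from so pooled training sets keep their
    provenance.
    """

    matrix: np.ndarray          # (N, 64)
    positions: np.ndarray       # (N, 2) int (row, col)
    scales: np.ndarray          # (N,) int
    strengths: np.ndarray       # (N,) float, >= 0
    family: str
    image_ids: np.ndarray = field(default=None)  # (N,) int

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        n = self.matrix.shape[0]
        if self.matrix.shape[1] != DESCRIPTOR_LENGTH and n > 0:
            raise ValueError(
                f"descriptors must have {DESCRIPTOR_LENGTH} elements, "
                f"got {self.matrix.shape[1]}"
            )
        if self.family not in ("gaussian", "nonlinear"):
            raise ValueError(f"unknown descriptor family {self.family!r}")
        self.positions = np.asarray(self.positions, dtype=np.int64).reshape(n, 2)
        self.scales = np.asarray(self.scales, dtype=np.int64).reshape(n)
        self.strengths = np.asarray(self.strengths, dtype=np.float64).reshape(n)
        if n and self.strengths.min() < 0:
            raise ValueError("strengths must be non-negative")
        if self.image_ids is None:
            self.image_ids = np.zeros(n, dtype=np.int64)
        else:
            self.image_ids = np.asarray(self.image_ids, dtype=np.int64).reshape(n)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def take(self, indices: np.ndarray) -> "DescriptorSet":
        return DescriptorSet(
            matrix=self.matrix[indices],
            positions=self.positions[indices],
            scales=self.scales[indices],
            strengths=self.strengths[indices],
            family=self.family,
            image_ids=self.image_ids[indices],
        )

    def for_image(self, image_id: int) -> "DescriptorSet":
        return self.take(np.flatnonzero(self.image_ids == image_id))

    @classmethod
    def concatenate(cls, sets: list["DescriptorSet"]) -> "DescriptorSet":
        if not sets:
            raise ValueError("cannot concatenate an empty list")
        family = sets[0].family
        if any(s.family != family for s in sets):
            raise ValueError("cannot concatenate mixed families")
        return cls(
            matrix=np.vstack([s.matrix for s in sets]),
            positions=np.vstack([s.positions for s in sets]),
            scales=np.concatenate([s.scales for s in sets]),
            strengths=np.concatenate([s.strengths for s in sets]),
            family=family,
            image_ids=np.concatenate([s.image_ids for s in sets]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Columnar view: family, image_id, row, col, scale, strength, v0..v63."""
        data = {
            "family": np.repeat(self.family, len(self)),
            "image_id": self.image_ids,
            "row": self.positions[:, 0],
            "col": self.positions[:, 1],
            "scale": self.scales,
            "strength": self.strengths,
        }
        for j in range(DESCRIPTOR_LENGTH):
            data[f"v{j}"] = self.matrix[:, j]
        return pd.DataFrame(data)

    def save(self, path: str | Path) -> None:
        """Persist as a versioned .npz archive."""
        np.savez_compressed(
            path,
            version=FORMAT_VERSION,
            family=self.family,
            matrix=self.matrix,
            positions=self.positions,
            scales=self.scales,
            strengths=self.strengths,
            image_ids=self.image_ids,
        )

    @classmethod
    def load(cls, path: str | Path) -> "DescriptorSet":
        with np.load(path, allow_pickle=False) as z:
            if int(z["version"]) != FORMAT_VERSION:
                raise ValueError(f"unsupported descriptor archive version {z['version']}")
            return cls(
                matrix=z["matrix"],
                positions=z["positions"],
                scales=z["scales"],
                strengths=z["strengths"],
                family=str(z["family"]),
                image_ids=z["image_ids"],
            )


def grid_points(height: int, width: int, step: int) -> np.ndarray:
    """Dense grid positions: (step*i + step//2, step*j + step//2)."""
    rows = np.arange(step // 2, height, step)
    cols = np.arange(step // 2, width, step)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)
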