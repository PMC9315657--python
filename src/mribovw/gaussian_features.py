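"""Gaussian scale-space features via box-filter approximations.

The linear (Gaussian) branch follows the speeded-up-robust-features
construction: an integral image gives O(1) axis-aligned box sums; second
derivatives of the Gaussian are approximated by box filters whose
determinant det(H) = Lxx*Lyy - (w*Lxy)^2 marks blob-like structure; and
local appearance is described by pooling Haar-wavelet first-derivative
responses over a 4x4 subregion layout into a 64-element vector.

Descriptors are extracted on a dense pixel grid (no interest-point
detection) and are upright by default: dense grids on axis-aligned
image slices gain nothing from orientation assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset_io import GrayImage
from .descriptors import (
    DescriptorSet,
    grid_points,
    pool_responses,
    sample_layout,
    scale_to_sigma,
)
from .errors import ExtractionError, ScaleError

logger = logging.getLogger(__name__)

#: Balancing weight for the cross term in the box-filter Hessian
#: determinant: det ~ Dxx*Dyy - (0.9*Dxy)^2.
CROSS_TERM_WEIGHT = 0.9


@dataclass(frozen=True)
class IntegralImage:
    """Cumulative-sum table: entry (i, j) = sum of pixels over [0..i]x[0..j]."""

    table: np.ndarray
    height: int
    width: int


def integral_image(img: GrayImage | np.ndarray) -> IntegralImage:
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)
    table = px.cumsum(axis=0).cumsum(axis=1)
    return IntegralImage(table=table, height=px.shape[0], width=px.shape[1])


def box_sum(ii: IntegralImage, r0, c0, r1, c1) -> np.ndarray:
    """Sum of pixels over the inclusive rectangle [r0..r1] x [c0..c1].

    Accepts scalars or equally-shaped integer arrays; rectangles are
    clamped to the image, and empty (fully outside) rectangles sum to 0.
    """
    r0 = np.clip(np.asarray(r0, dtype=np.int64), 0, ii.height)
    c0 = np.clip(np.asarray(c0, dtype=np.int64), 0, ii.width)
    r1 = np.clip(np.asarray(r1, dtype=np.int64), -1, ii.height - 1)
    c1 = np.clip(np.asarray(c1, dtype=np.int64), -1, ii.width - 1)

    # pad a zero row/column so (index - 1) lookups are branch-free
    t = ii.table
    padded = np.zeros((t.shape[0] + 1, t.shape[1] + 1), dtype=t.dtype)
    padded[1:, 1:] = t
    total = (
        padded[r1 + 1, c1 + 1]
        - padded[r0, c1 + 1]
        - padded[r1 + 1, c0]
        + padded[r0, c0]
    )
    return np.where((r1 >= r0) & (c1 >= c0), total, 0.0)


class _PaddedIntegral:
    """Integral image with a cached zero-padded table for batched queries."""

    def __init__(self, img: GrayImage | np.ndarray | IntegralImage):
        ii = img if isinstance(img, IntegralImage) else integral_image(img)
        self.height = ii.height
        self.width = ii.width
        self.padded = np.zeros((self.height + 1, self.width + 1))
        self.padded[1:, 1:] = ii.table

    def box(self, r0, c0, r1, c1):
        r0 = np.clip(r0, 0, self.height)
        c0 = np.clip(c0, 0, self.width)
        r1 = np.clip(r1, -1, self.height - 1)
        c1 = np.clip(c1, -1, self.width - 1)
        total = (
            self.padded[r1 + 1, c1 + 1]
            - self.padded[r0, c1 + 1]
            - self.padded[r1 + 1, c0]
            + self.padded[r0, c0]
        )
        return np.where((r1 >= r0) & (c1 >= c0), total, 0.0)

    def _interp(self, y, x):
        """Bilinear value of the padded integral table at real (y, x).

        The running integral of a piecewise-constant image is exactly
        bilinear inside each unit cell, so this interpolation integrates
        fractional rectangles exactly.
        """
        y = np.clip(y, 0.0, float(self.height))
        x = np.clip(x, 0.0, float(self.width))
        iy = np.clip(np.floor(y).astype(np.int64), 0, self.height - 1)
        ix = np.clip(np.floor(x).astype(np.int64), 0, self.width - 1)
        fy = y - iy
        fx = x - ix
        p = self.padded
        return (
            (1 - fy) * (1 - fx) * p[iy, ix]
            + (1 - fy) * fx * p[iy, ix + 1]
            + fy * (1 - fx) * p[iy + 1, ix]
            + fy * fx * p[iy + 1, ix + 1]
        )

    def box_frac(self, r0, c0, r1, c1):
        """Exact integral over the real rectangle [r0, r1+1) x [c0, c1+1).

        Accepts fractional bounds; clamped to the image and rescaled to
        the nominal area like :meth:`box_norm`.
        """
        r0 = np.asarray(r0, dtype=np.float64)
        c0 = np.asarray(c0, dtype=np.float64)
        r1 = np.asarray(r1, dtype=np.float64)
        c1 = np.asarray(c1, dtype=np.float64)
        nominal = (r1 - r0 + 1.0) * (c1 - c0 + 1.0)
        y0 = np.clip(r0, 0.0, float(self.height))
        y1 = np.clip(r1 + 1.0, 0.0, float(self.height))
        x0 = np.clip(c0, 0.0, float(self.width))
        x1 = np.clip(c1 + 1.0, 0.0, float(self.width))
        area = np.maximum(y1 - y0, 0.0) * np.maximum(x1 - x0, 0.0)
        total = (
            self._interp(y1, x1)
            - self._interp(y0, x1)
            - self._interp(y1, x0)
            + self._interp(y0, x0)
        )
        return np.where(area > 0, total * nominal / np.maximum(area, 1e-300), 0.0)

    def box_norm(self, r0, c0, r1, c1):
        """Clamped box sum rescaled to the nominal (unclamped) area.

        Border rectangles are clamped to the image; rescaling the
        clamped sum by nominal/clamped area keeps filters balanced
        there (a constant image yields exactly balanced responses).
        """
        r0 = np.asarray(r0, dtype=np.int64)
        c0 = np.asarray(c0, dtype=np.int64)
        r1 = np.asarray(r1, dtype=np.int64)
        c1 = np.asarray(c1, dtype=np.int64)
        nominal = (r1 - r0 + 1) * (c1 - c0 + 1)
        r0c = np.clip(r0, 0, self.height - 1)
        c0c = np.clip(c0, 0, self.width - 1)
        r1c = np.clip(r1, 0, self.height - 1)
        c1c = np.clip(c1, 0, self.width - 1)
        clamped = (r1c - r0c + 1) * (c1c - c0c + 1)
        return self.box(r0c, c0c, r1c, c1c) * (nominal / clamped)


@dataclass(frozen=True)
class HessianResponse:
    """Box-filter Hessian determinant map at one scale."""

    det_map: np.ndarray
    sigma: float
    lxx: np.ndarray
    lyy: np.ndarray
    lxy: np.ndarray


def _filter_size_for_sigma(sigma: float) -> tuple[int, int]:
    """Map sigma to an odd box-filter size L = 3*lobe with lobe odd.

    The 9-pixel base filter corresponds to sigma = 1.2.
    """
    lobe = int(round(sigma / 1.2 * 3))
    if lobe % 2 == 0:
        lobe += 1
    lobe = max(lobe, 3)
    return 3 * lobe, lobe


def hessian_det_response(img: GrayImage, sigma: float) -> HessianResponse:
    """det(H) of the box-filter Hessian at every pixel, scale ``sigma``.

    Border rectangles are clamped to the image.  Responses are
    normalized by the filter area so scales are comparable.
    """
    size, lobe = _filter_size_for_sigma(sigma)
    if size < 9:
        raise ScaleError(f"sigma {sigma} maps to filter size {size} < 9")
    if size > min(img.height, img.width):
        raise ScaleError(
            f"filter size {size} exceeds image {img.height}x{img.width}"
        )
    pad = _PaddedIntegral(img)
    rr, cc = np.meshgrid(
        np.arange(img.height), np.arange(img.width), indexing="ij"
    )
    half = (size - 1) // 2        # full-filter radius
    hl = (lobe - 1) // 2          # lobe radius
    band = 2 * lobe - 1           # height of the Dxx stripes
    hb = (band - 1) // 2

    # Dxx: full-width stripe of height 2*lobe-1; middle third weighted -2
    whole = pad.box_norm(rr - hb, cc - half, rr + hb, cc + half)
    middle = pad.box_norm(rr - hb, cc - hl, rr + hb, cc + hl)
    lxx = whole - 3.0 * middle
    # Dyy: transpose layout
    whole_t = pad.box_norm(rr - half, cc - hb, rr + half, cc + hb)
    middle_t = pad.box_norm(rr - hl, cc - hb, rr + hl, cc + hb)
    lyy = whole_t - 3.0 * middle_t
    # Dxy: four lobe x lobe quadrant blocks around the centre pixel
    tl = pad.box_norm(rr - lobe, cc - lobe, rr - 1, cc - 1)
    tr = pad.box_norm(rr - lobe, cc + 1, rr - 1, cc + lobe)
    bl = pad.box_norm(rr + 1, cc - lobe, rr + lobe, cc - 1)
    br = pad.box_norm(rr + 1, cc + 1, rr + lobe, cc + lobe)
    lxy = tl + br - tr - bl

    inv_area = 1.0 / (size * size)
    lxx, lyy, lxy = lxx * inv_area, lyy * inv_area, lxy * inv_area
    det = lxx * lyy - (CROSS_TERM_WEIGHT * lxy) ** 2
    return HessianResponse(det_map=det, sigma=float(sigma), lxx=lxx, lyy=lyy, lxy=lxy)


def _haar_filter_size(sigma: float) -> int:
    """Even Haar support side, ~3*sigma.

    A support a little wider than the classic 2*sigma averages more
    pixels per response, which stabilizes dense-grid descriptors on
    noisy inputs where no interest-point selection filters weak
    locations first.
    """
    return max(2, 2 * int(round(1.5 * sigma)))


def haar_responses(ii, center, filter_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Haar wavelet responses (dx, dy) at ``center`` = (row, col).

    ``filter_size`` must be even; the support covers rows
    ``r - f/2 .. r + f/2 - 1`` and likewise for columns.  dx is the right
    half minus the left half; dy the bottom half minus the top half
    (row axis pointing down).  ``center`` may hold arrays for batching.
    """
    if filter_size % 2 != 0:
        raise ValueError(f"Haar filter size must be even, got {filter_size}")
    pad = ii if isinstance(ii, _PaddedIntegral) else _PaddedIntegral(ii)
    r, c = center
    r = np.asarray(r, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    h = filter_size / 2.0
    dx = pad.box_frac(r - h, c, r + h - 1, c + h - 1) - pad.box_frac(
        r - h, c - h, r + h - 1, c - 1
    )
    dy = pad.box_frac(r, c - h, r + h - 1, c + h - 1) - pad.box_frac(
        r - h, c - h, r - 1, c + h - 1
    )
    return dx, dy


@dataclass(frozen=True)
class GaussianDescriptor:
    """64-element upright descriptor at one grid point and scale."""

    vector: np.ndarray
    position: tuple[int, int]
    scale: int
    strength: float
    clipped: bool = False


def _descriptors_at(
    pad: _PaddedIntegral, positions: np.ndarray, scale: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched descriptor computation at (N, 2) positions for one scale."""
    offsets, weights, sub_index = sample_layout(int(scale))
    sigma = scale_to_sigma(scale)
    f = _haar_filter_size(sigma)
    coords = positions[:, None, :].astype(np.float64) + offsets[None, :, :]
    rr = np.clip(coords[..., 0], 0.0, pad.height - 1.0)
    cc = np.clip(coords[..., 1], 0.0, pad.width - 1.0)
    dx, dy = haar_responses(pad, (rr, cc), f)
    vectors, strengths = pool_responses(dx, dy, weights, sub_index)
    half = scale // 2
    clipped = (
        (positions[:, 0] - half < 0)
        | (positions[:, 1] - half < 0)
        | (positions[:, 0] + half >= pad.height)
        | (positions[:, 1] + half >= pad.width)
    )
    return vectors, strengths, clipped


def gaussian_descriptor_at(
    img: GrayImage, position: tuple[int, int], scale: int
) -> GaussianDescriptor:
    """Descriptor of the square patch of side ``scale`` centred at ``position``.

    Patches reaching past the border use clamped sampling and are flagged
    ``clipped``; constant patches yield the zero vector with strength 0.
    """
    pad = _PaddedIntegral(img)
    pos = np.asarray([position], dtype=np.int64)
    vectors, strengths, clipped = _descriptors_at(pad, pos, scale)
    return GaussianDescriptor(
        vector=vectors[0],
        position=(int(position[0]), int(position[1])),
        scale=int(scale),
        strength=float(strengths[0]),
        clipped=bool(clipped[0]),
    )


def dense_extract_gaussian(
    img: GrayImage,
    grid_step: int = 8,
    scales: tuple[int, ...] = (17, 34, 51, 68),
    image_id: int = 0,
) -> DescriptorSet:
    """One descriptor per (grid point, scale); grid offset by step/2.

    Scales larger than the image are dropped per image (logged); an image
    smaller than every scale is an extraction error.
    """
    usable = [s for s in scales if s <= min(img.height, img.width)]
    dropped = [s for s in scales if s not in usable]
    if dropped:
        logger.info("image %d: dropping scales %s (image %dx%d)",
                    image_id, dropped, img.height, img.width)
    if not usable:
        raise ExtractionError(
            f"image {img.height}x{img.width} smaller than all scales {scales}"
        )
    pad = _PaddedIntegral(img)
    pts = grid_points(img.height, img.width, grid_step)
    mats, poss, scls, strs = [], [], [], []
    for s in usable:
        vectors, strengths, _ = _descriptors_at(pad, pts, s)
        mats.append(vectors)
        poss.append(pts)
        scls.append(np.full(len(pts), s, dtype=np.int64))
        strs.append(strengths)
    n = sum(len(p) for p in poss)
    return DescriptorSet(
        matrix=np.vstack(mats),
        positions=np.vstack(poss),
        scales=np.concatenate(scls),
        strengths=np.concatenate(strs),
        family="gaussian",
        image_ids=np.full(n, image_id, dtype=np.int64),
    )
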