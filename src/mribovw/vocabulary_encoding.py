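"""Strongest-feature selection, k-means vocabularies and BoVW encoding.

The pooled training descriptors of each family are pruned to the
strongest 80% by element variance, clustered into a k = 400 visual-word
vocabulary (k-means++ / Lloyd), and every image is then encoded as the
L1-normalized histogram of its descriptors' nearest words.  The two
family histograms concatenate into the 800-element hybrid vector.
Vocabularies are fit on training images only; test images are encoded
against the frozen centroids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances_argmin

from .descriptors import DESCRIPTOR_LENGTH, DescriptorSet
from .errors import EncodingError, SelectionError, VocabularyError

VOCAB_FORMAT_VERSION = 1


def select_strongest(pool: DescriptorSet, keep_fraction: float = 0.8) -> DescriptorSet:
    """Keep the top ``ceil(keep_fraction * N)`` descriptors by strength.

    Strength is the element variance of the raw descriptor; ties are
    broken by (image_id, row, col, scale) lexicographic order so the
    selection is deterministic.
    """
    if len(pool) == 0:
        raise SelectionError("cannot select from an empty descriptor pool")
    if not 0.0 < keep_fraction <= 1.0:
        raise SelectionError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    order = np.lexsort(
        (
            pool.scales,
            pool.positions[:, 1],
            pool.positions[:, 0],
            pool.image_ids,
            -pool.strengths,
        )
    )
    n_keep = int(np.ceil(keep_fraction * len(pool)))
    return pool.take(order[:n_keep])


@dataclass
class Vocabulary:
    """k cluster centroids for one descriptor family."""

    centroids: np.ndarray   # (k, 64)
    family: str
    seed: int
    inertia: float

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=np.float64))
        if self.centroids.shape[1] != DESCRIPTOR_LENGTH:
            raise VocabularyError(
                f"centroids must have {DESCRIPTOR_LENGTH} columns, "
                f"got {self.centroids.shape[1]}"
            )
        if not np.all(np.isfinite(self.centroids)):
            raise VocabularyError("centroids contain non-finite values")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            version=VOCAB_FORMAT_VERSION,
            centroids=self.centroids,
            family=self.family,
            seed=self.seed,
            inertia=self.inertia,
        )

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        with np.load(path, allow_pickle=False) as z:
            if int(z["version"]) != VOCAB_FORMAT_VERSION:
                raise VocabularyError(
                    f"unsupported vocabulary archive version {z['version']}"
                )
            return cls(
                centroids=z["centroids"],
                family=str(z["family"]),
                seed=int(z["seed"]),
                inertia=float(z["inertia"]),
            )


def fit_vocabulary(
    pool: DescriptorSet,
    k: int = 400,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> Vocabulary:
    """Cluster the pool into k visual words (k-means++ init, Lloyd runs).

    Iteration stops when the relative inertia change drops below ``tol``
    or after ``max_iter`` Lloyd iterations.
    """
    if len(pool) < k:
        raise VocabularyError(
            f"need at least k={k} descriptors to fit a vocabulary, "
            f"pool has {len(pool)}"
        )
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=max_iter,
        tol=tol,
        algorithm="lloyd",
        random_state=seed,
    ).fit(pool.matrix)
    return Vocabulary(
        centroids=km.cluster_centers_,
        family=pool.family,
        seed=seed,
        inertia=float(km.inertia_),
    )


def encode_histogram(
    desc: DescriptorSet, vocab: Vocabulary, normalization: str = "l1"
) -> np.ndarray:
    """Histogram of nearest-centroid assignments for one image's descriptors.

    Euclidean nearest centroid, ties resolved to the lowest centroid
    index.  ``l1`` normalization (default) makes the block sum to 1 so
    images of different sizes are comparable; ``l2`` and ``count`` modes
    are available.  An empty descriptor set yields the all-zero block.
    """
    if desc.family != vocab.family:
        raise EncodingError(
            f"descriptor family {desc.family!r} does not match "
            f"vocabulary family {vocab.family!r}"
        )
    counts = np.zeros(vocab.k, dtype=np.float64)
    if len(desc) > 0:
        assign = pairwise_distances_argmin(desc.matrix, vocab.centroids)
        np.add.at(counts, assign, 1.0)
    if normalization == "count":
        return counts
    if normalization == "l1":
        total = counts.sum()
        return counts / total if total > 0 else counts
    if normalization == "l2":
        norm = np.linalg.norm(counts)
        return counts / norm if norm > 0 else counts
    raise EncodingError(f"unknown normalization {normalization!r}")


@dataclass(frozen=True)
class HybridVector:
    """Concatenated per-family histograms: gaussian block then nonlinear."""

    values: np.ndarray
    image_id: int
    normalization: str = "l1"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64).ravel()
        )


def hybridize(
    g_block: np.ndarray,
    n_block: np.ndarray,
    image_id: int = 0,
    expected_k: int | None = None,
    normalization: str = "l1",
) -> HybridVector:
    """Concatenate the gaussian and nonlinear histogram blocks."""
    g = np.asarray(g_block, dtype=np.float64).ravel()
    n = np.asarray(n_block, dtype=np.float64).ravel()
    if expected_k is not None and (g.size != expected_k or n.size != expected_k):
        raise EncodingError(
            f"expected {expected_k}-element blocks, got {g.size} and {n.size}"
        )
    return HybridVector(
        values=np.concatenate([g, n]), image_id=image_id, normalization=normalization
    )


def feature_table(
    vectors: list[HybridVector], labels: list[str]
) -> "pd.DataFrame":
    """Delimited-table view (image_id, label, f0..fD-1) of hybrid vectors."""
    import pandas as pd

    if len(vectors) != len(labels):
        raise EncodingError("vectors and labels length mismatch")
    mat = np.vstack([v.values for v in vectors])
    df = pd.DataFrame(mat, columns=[f"f{j}" for j in range(mat.shape[1])])
    df.insert(0, "label", labels)
    df.insert(0, "image_id", [v.image_id for v in vectors])
    return df
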