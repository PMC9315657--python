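import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cluster import KMeans

from mribovw import (
    DescriptorSet,
    Vocabulary,
    encode_histogram,
    fit_vocabulary,
    hybridize,
    select_strongest,
)
from mribovw.errors import EncodingError, SelectionError, VocabularyError


def make_pool(matrix, strengths=None, family="gaussian", image_ids=None):
    n = matrix.shape[0]
    return DescriptorSet(
        matrix=matrix,
        positions=np.tile([[0, 0]], (n, 1)),
        scales=np.full(n, 17),
        strengths=np.ones(n) if strengths is None else np.asarray(strengths),
        family=family,
        image_ids=image_ids,
    )


def embed(points2d):
    """Embed 2-D points into the 64-d descriptor space (zeros elsewhere)."""
    m = np.zeros((len(points2d), 64))
    m[:, :2] = points2d
    return m


class TestSelectStrongest:
    def test_keep_all_is_identity_up_to_ranking(self, rng):
        pool = make_pool(rng.random((10, 64)), strengths=rng.random(10))
        out = select_strongest(pool, keep_fraction=1.0)
        assert len(out) == 10
        assert np.allclose(np.sort(out.strengths), np.sort(pool.strengths))

    def test_toy_ranking_keeps_top_half(self):
        pool = make_pool(np.eye(4, 64), strengths=[3.0, 1.0, 2.0, 0.0])
        out = select_strongest(pool, keep_fraction=0.5)
        assert sorted(out.strengths.tolist()) == [2.0, 3.0]

    def test_tie_break_is_lexicographic(self):
        pool = DescriptorSet(
            matrix=np.eye(4, 64),
            positions=[[8, 8], [0, 0], [8, 0], [0, 8]],
            scales=[17, 17, 17, 17],
            strengths=[1.0, 1.0, 1.0, 1.0],
            family="gaussian",
            image_ids=[0, 0, 0, 0],
        )
        out = select_strongest(pool, keep_fraction=0.5)
        # all strengths equal -> lexicographically first (row, col) survive
        assert out.positions.tolist() == [[0, 0], [0, 8]]

    def test_empty_pool_rejected(self):
        pool = make_pool(np.empty((0, 64)))
        with pytest.raises(SelectionError):
            select_strongest(pool)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        n=st.integers(min_value=1, max_value=1000),
        tenths=st.integers(min_value=1, max_value=10),
    )
    def test_output_size_is_ceil_fraction(self, n, tenths):
        frac = tenths / 10.0
        rng = np.random.default_rng(n)
        pool = make_pool(rng.random((n, 64)), strengths=rng.random(n))
        assert len(select_strongest(pool, frac)) == int(np.ceil(frac * n))


class TestFitVocabulary:
    def test_exact_cover_gives_zero_inertia(self, rng):
        m = rng.random((5, 64))
        vocab = fit_vocabulary(make_pool(m), k=5, seed=0)
        assert vocab.inertia == pytest.approx(0.0, abs=1e-12)
        # centroids are a permutation of the inputs
        dists = ((vocab.centroids[:, None, :] - m[None, :, :]) ** 2).sum(-1)
        assert np.allclose(dists.min(axis=1), 0.0, atol=1e-12)

    def test_matches_exhaustive_partition_optimum(self):
        # two tight, well-separated groups: enumerate every 2-partition
        pts = np.array(
            [[0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [0.1, 0.1],
             [5.0, 5.0], [5.1, 5.0], [5.0, 5.1], [5.1, 5.1]]
        )
        from itertools import combinations

        best = np.inf
        idx = range(8)
        for size in range(1, 8):
            for group in combinations(idx, size):
                a = pts[list(group)]
                b = pts[[i for i in idx if i not in group]]
                inertia = (
                    ((a - a.mean(0)) ** 2).sum() + ((b - b.mean(0)) ** 2).sum()
                )
                best = min(best, inertia)
        vocab = fit_vocabulary(make_pool(embed(pts)), k=2, seed=0)
        assert vocab.inertia == pytest.approx(best, abs=1e-10)

    def test_same_seed_reproduces(self, rng):
        pool = make_pool(rng.random((50, 64)))
        a = fit_vocabulary(pool, k=4, seed=3)
        b = fit_vocabulary(pool, k=4, seed=3)
        assert np.array_equal(a.centroids, b.centroids)

    def test_too_few_descriptors_rejected(self, rng):
        with pytest.raises(VocabularyError, match="3"):
            fit_vocabulary(make_pool(rng.random((3, 64))), k=5, seed=0)

    def test_inertia_nonincreasing_over_lloyd_iterations(self, rng):
        X = rng.random((200, 64))
        inertias = []
        for iters in range(1, 7):
            km = KMeans(
                n_clusters=8, init="k-means++", n_init=1, max_iter=iters,
                tol=0.0, algorithm="lloyd", random_state=0,
            ).fit(X)
            inertias.append(km.inertia_)
        assert all(b <= a + 1e-9 for a, b in zip(inertias, inertias[1:]))


class TestEncodeHistogram:
    def test_concentrated_assignment_is_one_hot(self, rng):
        centroids = np.zeros((5, 64))
        centroids[:, 0] = np.arange(5) * 10.0
        vocab = Vocabulary(centroids=centroids, family="gaussian", seed=0, inertia=0)
        desc = make_pool(np.tile(centroids[3], (7, 1)) + rng.normal(0, 0.01, (7, 64)))
        block = encode_histogram(desc, vocab)
        assert block[3] == pytest.approx(1.0)

    def test_l1_normalization(self, rng):
        vocab = Vocabulary(centroids=rng.random((5, 64)), family="gaussian", seed=0, inertia=0)
        block = encode_histogram(make_pool(rng.random((20, 64))), vocab)
        assert block.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_nearest_centroid(self, rng):
        centroids = rng.random((6, 64))
        vocab = Vocabulary(centroids=centroids, family="gaussian", seed=0, inertia=0)
        m = rng.random((50, 64))
        block = encode_histogram(make_pool(m), vocab, normalization="count")
        expected = np.zeros(6)
        for row in m:
            d = ((centroids - row) ** 2).sum(axis=1)
            expected[int(np.argmin(d))] += 1
        assert np.array_equal(block, expected)

    def test_family_mismatch_rejected(self, rng):
        vocab = Vocabulary(centroids=rng.random((4, 64)), family="nonlinear", seed=0, inertia=0)
        with pytest.raises(EncodingError):
            encode_histogram(make_pool(rng.random((4, 64))), vocab)

    def test_permutation_invariance(self, rng):
        vocab = Vocabulary(centroids=rng.random((6, 64)), family="gaussian", seed=0, inertia=0)
        m = rng.random((30, 64))
        a = encode_histogram(make_pool(m), vocab)
        b = encode_histogram(make_pool(m[rng.permutation(30)]), vocab)
        assert np.allclose(a, b)

    def test_centroids_encode_to_uniform_histogram(self, rng):
        centroids = rng.random((8, 64))
        vocab = Vocabulary(centroids=centroids, family="gaussian", seed=0, inertia=0)
        block = encode_histogram(make_pool(centroids), vocab)
        assert np.allclose(block, 1.0 / 8)

    def test_empty_descriptor_set_gives_zero_block(self, rng):
        vocab = Vocabulary(centroids=rng.random((4, 64)), family="gaussian", seed=0, inertia=0)
        block = encode_histogram(make_pool(np.empty((0, 64))), vocab)
        assert np.allclose(block, 0.0)


class TestHybridize:
    def test_concatenation_order_and_length(self, rng):
        g = rng.random(400)
        n = rng.random(400)
        h = hybridize(g, n)
        assert h.values.shape == (800,)
        assert np.array_equal(h.values[:400], g)

    def test_zero_gaussian_block_keeps_total_mass(self):
        g = np.zeros(400)
        n = np.zeros(400)
        n[7] = 1.0
        assert hybridize(g, n).values.sum() == pytest.approx(1.0)

    def test_not_commutative(self, rng):
        a, b = rng.random(400), rng.random(400)
        assert not np.array_equal(hybridize(a, b).values, hybridize(b, a).values)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(EncodingError):
            hybridize(rng.random(400), rng.random(300), expected_k=400)
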