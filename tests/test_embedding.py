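"""PCA retained-variance selection and the t-SNE contract."""

import numpy as np
import pytest

from spinechange.embedding import (
    EmbeddingConfig,
    conditional_similarities,
    pca_reduce,
    tsne_embed,
)


class TestPCAReduce:
    def test_rank_one_data_needs_one_component(self, rng):
        X = np.zeros((20, 15))
        X[:, 3] = rng.normal(size=20)
        scores, n, explained = pca_reduce(X, 0.95)
        assert n == 1
        assert explained[0] == pytest.approx(1.0)

    def test_eigenvalues_match_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(10, 15))
        _, _, explained = pca_reduce(X, 0.95)
        cov = np.cov(X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        rank = 9  # 10 centered samples span at most a 9-dim subspace
        np.testing.assert_allclose(explained[:rank], eig[:rank] / eig.sum(), atol=1e-9)

    def test_full_threshold_keeps_the_rank(self, rng):
        low_rank = rng.normal(size=(30, 4)) @ rng.normal(size=(4, 15))
        scores, n, _ = pca_reduce(low_rank, 1.0)
        assert n == 4
        assert scores.shape == (30, 4)

    def test_threshold_is_tight(self, rng):
        X = rng.normal(size=(50, 15)) * np.linspace(3, 0.1, 15)
        for thr in (0.8, 0.9, 0.95, 0.99):
            _, n, explained = pca_reduce(X, thr)
            cum = np.cumsum(explained)
            assert cum[n - 1] >= thr - 1e-12
            if n > 1:
                assert cum[n - 2] < thr

    def test_scores_are_uncorrelated(self, rng):
        X = rng.normal(size=(60, 15)) @ rng.normal(size=(15, 15))
        scores, n, _ = pca_reduce(X, 0.99)
        cov = np.cov(scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-9 * np.diag(cov).max()

    def test_too_few_samples_is_domain_error(self):
        with pytest.raises(ValueError):
            pca_reduce(np.zeros((1, 15)), 0.95)


class TestConditionalSimilarities:
    def test_perplexity_calibration(self, rng):
        X = rng.normal(size=(60, 5))
        for perp in (5.0, 15.0, 30.0):
            P = conditional_similarities(X, perp)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
            with np.errstate(divide="ignore"):
                logs = np.where(P > 0, np.log2(P, where=P > 0), 0.0)
            entropy = -np.sum(P * logs, axis=1)
            np.testing.assert_allclose(2.0**entropy, perp, atol=1e-3)

    def test_matches_reference_joint_probabilities(self, rng):
        # independent cross-check against scikit-learn's own calibration
        from scipy.spatial.distance import pdist, squareform
        from sklearn.manifold._t_sne import _joint_probabilities

        X = rng.normal(size=(40, 4))
        perp = 10.0
        P_cond = conditional_similarities(X, perp)
        joint_mine = (P_cond + P_cond.T) / (2 * X.shape[0])
        d2 = squareform(pdist(X, "sqeuclidean")).astype(np.float32)
        joint_ref = squareform(_joint_probabilities(d2, perp, verbose=0))
        np.testing.assert_allclose(joint_mine, joint_ref, atol=2e-5)


class TestTSNEEmbed:
    def test_output_shape_ids_and_provenance(self, rng):
        X = rng.normal(size=(50, 5))
        config = EmbeddingConfig(random_seed=3, perplexity=10.0)
        m = tsne_embed(X, config, pair_ids=[f"p{i}" for i in range(50)])
        assert m.coordinates.shape == (50, 2)
        assert m.pair_ids[0] == "p0"
        assert m.provenance["perplexity"] == 10.0
        assert m.provenance["random_seed"] == 3

    def test_same_seed_is_deterministic(self, rng):
        X = rng.normal(size=(50, 5))
        config = EmbeddingConfig(random_seed=11, perplexity=12.0)
        a = tsne_embed(X, config).coordinates
        b = tsne_embed(X, config).coordinates
        np.testing.assert_array_equal(a, b)

    def test_excessive_perplexity_is_domain_error(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(X, EmbeddingConfig(random_seed=0, perplexity=20.0))

    def test_small_sample_warns(self, rng):
        X = rng.normal(size=(25, 3))
        with pytest.warns(UserWarning, match="small"):
            tsne_embed(X, EmbeddingConfig(random_seed=0, perplexity=12.0))


def test_separated_blobs_stay_linearly_separable():
    """Three well-separated Gaussian blobs remain >=95% linearly separable
    in the map across 10 seeds (embedding sanity, not an exact contract)."""
    from sklearn.svm import LinearSVC

    gen = np.random.default_rng(2024)
    centers = np.array(
        [[0.0] * 15, [12.0] + [0.0] * 14, [0.0, 12.0] + [0.0] * 13]
    )
    X = np.vstack([gen.normal(c, 1.0, size=(30, 15)) for c in centers])
    y = np.repeat([0, 1, 2], 30)
    for seed in range(10):
        m = tsne_embed(X, EmbeddingConfig(random_seed=seed, perplexity=15.0))
        acc = LinearSVC().fit(m.coordinates, y).score(m.coordinates, y)
        assert acc >= 0.95
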