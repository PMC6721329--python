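"""Dimensionality reduction: PCA to a retained-variance target, then t-SNE.

The feature matrix is first rotated onto its principal components, keeping
the smallest number of components whose cumulative explained-variance
fraction reaches the configured threshold (default 95%).  The retained
scores are then embedded into a 2D map with t-SNE: per-point Gaussian
bandwidths are calibrated so every conditional input-similarity
distribution has the configured perplexity, and the map minimizes the KL
divergence to Student-t (1 d.f.) map similarities.

Features are centered but not standardized by default: the direction
components are bounded by construction and the length components are of
comparable magnitude when the segment length is 1 model unit; a flag
enables z-scoring for other regimes.  The t-SNE optimizer is delegated to
scikit-learn with its default optimization parameters, which only affect
convergence rate; the random seed is mandatory and recorded in provenance.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import sklearn
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

_RANK_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class EmbeddingConfig:
    """Settings for the PCA + t-SNE reduction.

    ``tsne_kwargs`` is an opaque pass-through to the t-SNE optimizer for
    users who need to touch convergence settings.
    """

    random_seed: int
    variance_threshold: float = 0.95
    perplexity: float = 30.0
    standardize: bool = False
    tsne_kwargs: Mapping[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.variance_threshold <= 1.0):
            raise ValueError("variance_threshold must be in (0, 1]")
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")


@dataclasses.dataclass(frozen=True)
class Map2D:
    """A 2D embedding with row-aligned pair ids and run provenance."""

    coordinates: np.ndarray  # (N, 2)
    pair_ids: tuple[str, ...]
    provenance: Mapping[str, Any]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError(f"map must be N x 2, got shape {coords.shape}")
        if len(self.pair_ids) != coords.shape[0]:
            raise ValueError("pair_ids must align with coordinate rows")
        object.__setattr__(self, "coordinates", coords)


def pca_reduce(
    features: np.ndarray,
    variance_threshold: float = 0.95,
    standardize: bool = False,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Project mean-centered features onto leading principal components.

    Returns ``(scores, n, explained)``: the N x n component scores, the
    smallest component count ``n`` whose cumulative explained-variance
    fraction reaches ``variance_threshold``, and the full per-component
    explained-variance fractions.  With ``variance_threshold = 1.0`` the
    retained count equals the rank of the centered data.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 samples")
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance_threshold must be in (0, 1]")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    pca = PCA(svd_solver="full")
    scores_full = pca.fit_transform(X)
    explained = pca.explained_variance_ratio_
    rank = max(1, int(np.sum(explained > _RANK_TOL)))
    cumulative = np.cumsum(explained)
    reached = np.nonzero(cumulative >= variance_threshold - 1e-12)[0]
    n = int(reached[0]) + 1 if reached.size else rank
    n = min(n, rank)
    return scores_full[:, :n], n, explained


def conditional_similarities(
    scores: np.ndarray, perplexity: float, tol: float = 1e-10, max_iter: int = 200
) -> np.ndarray:
    """Per-point Gaussian conditional similarities at a target perplexity.

    Each row i holds p(j|i) with the bandwidth beta_i found by binary search
    so that ``2**H(p(.|i))`` equals ``perplexity``.  Exposed for diagnostics;
    the embedding itself delegates to the optimizer's internal calibration,
    which follows the same contract.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if perplexity >= n:
        raise ValueError("perplexity must be below the sample count")
    sq = np.sum(X**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    target = np.log2(perplexity)
    P = np.zeros((n, n))
    for i in range(n):
        di = np.delete(d2[i], i)
        lo, hi = 0.0, np.inf
        beta = 1.0
        for _ in range(max_iter):
            w = np.exp(-beta * (di - di.min()))
            p = w / w.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                h = -np.sum(p[p > 0] * np.log2(p[p > 0]))
            if abs(h - target) < tol:
                break
            if h > target:  # too spread out -> narrow the kernel
                lo = beta
                beta = beta * 2 if np.isinf(hi) else 0.5 * (lo + hi)
            else:
                hi = beta
                beta = beta / 2 if lo == 0.0 else 0.5 * (lo + hi)
        P[i, np.arange(n) != i] = p
    return P


def tsne_embed(
    scores: np.ndarray,
    config: EmbeddingConfig,
    pair_ids: Sequence[str] | None = None,
) -> Map2D:
    """Embed PCA scores into a 2D map with t-SNE.

    Deterministic given ``config.random_seed``; ``perplexity >= N`` is a
    domain error and ``N <= 3 * perplexity`` only triggers a warning since
    the bandwidth calibration degrades gracefully.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if config.perplexity >= n:
        raise ValueError(f"perplexity {config.perplexity} must be < sample count {n}")
    if n <= 3 * config.perplexity:
        warnings.warn(
            f"sample count {n} is small for perplexity {config.perplexity}; "
            "the map may be unstable",
            stacklevel=2,
        )
    tsne = TSNE(
        n_components=2,
        perplexity=config.perplexity,
        random_state=config.random_seed,
        init="pca",
        **dict(config.tsne_kwargs),
    )
    coords = tsne.fit_transform(X)
    ids = tuple(pair_ids) if pair_ids is not None else tuple(str(i) for i in range(n))
    provenance = {
        "perplexity": config.perplexity,
        "random_seed": config.random_seed,
        "pca_dims": int(X.shape[1]),
        "n_samples": n,
        "sklearn_version": sklearn.__version__,
    }
    return Map2D(coordinates=coords, pair_ids=ids, provenance=provenance)


def embed_features(
    features: np.ndarray,
    config: EmbeddingConfig,
    pair_ids: Sequence[str] | None = None,
) -> tuple[Map2D, int, np.ndarray]:
    """PCA to the variance threshold, then t-SNE to 2D, in one call."""
    scores, n_components, explained = pca_reduce(
        features, config.variance_threshold, config.standardize
    )
    map2d = tsne_embed(scores, config, pair_ids)
    return map2d, n_components, explained


def map_to_frame(map2d: Map2D) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": list(map2d.pair_ids),
            "x": map2d.coordinates[:, 0],
            "y": map2d.coordinates[:, 1],
        }
    )
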