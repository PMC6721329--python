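"""End-to-end pipeline orchestration and the perplexity-stability sweep.

``run_all`` executes the full chain — load or simulate snapshots, extract
pairs, reconstruct curves, compute change features, PCA, t-SNE, MST
clustering, offset-shape bundles and angle statistics — writing every
intermediate plus a provenance manifest to the output directory.
``perplexity_sweep`` re-embeds and re-clusters across a list of perplexity
values and reports cluster sizes and pairwise adjusted Rand indices, the
stability check used to justify a single working perplexity.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import sklearn
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .embedding import EmbeddingConfig, Map2D, map_to_frame, pca_reduce, tsne_embed
from .features import PairFeature, feature_matrix, features_to_frame, pair_feature
from .io import (
    PosturePair,
    extract_pairs,
    read_snapshots,
    summarize_database,
    summary_to_frame,
    write_pairs,
    write_snapshots,
)
from .mst import Clustering, mst_cluster
from .profiles import BundleStats, bundle_stats, bundles_to_frame, flags_to_frame
from .spine import OffsetShape, offset_shape, offsets_to_frame, reconstruct_curve
from .stats import angle_report, wilcoxon_per_sensor
from .synthetic import GeneratorConfig, generate_database, write_truth

logger = logging.getLogger(__name__)

#: cluster counts per position used throughout the reference analysis
DEFAULT_K = {"standing": 4, "sitting": 4, "hinging": 6}
DEFAULT_SWEEP = (25.0, 30.0, 35.0, 40.0)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` / ``generator`` provides the snapshots.
    ``k`` overrides the per-position default cluster count; ``position``
    filters the database to one position before pairing.
    """

    input_path: str | None = None
    generator: GeneratorConfig | None = None
    position: str | None = None
    segment_length: float = 1.0
    variance_threshold: float = 0.95
    perplexity: float = 30.0
    sweep: tuple[float, ...] = DEFAULT_SWEEP
    k: int | None = None
    k_by_position: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_K)
    )
    zero_tol: float = 1e-9
    seed: int = 0
    out_dir: str = "spinechange_out"
    ari_flag_threshold: float = 0.8
    delimiter: str = ","

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("provide exactly one of input_path or generator")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")

    def resolve_k(self, position: str | None) -> int:
        if self.k is not None:
            return self.k
        if position is not None and position in self.k_by_position:
            return self.k_by_position[position]
        return 4


@dataclasses.dataclass
class RunResult:
    """In-memory artifacts of one pipeline run."""

    pairs: list[PosturePair]
    features: list[PairFeature]
    map2d: Map2D
    clustering: Clustering
    offsets: list[OffsetShape]
    bundles: list[BundleStats]
    pca_components: int
    explained: np.ndarray
    out_dir: Path


def _load_pairs(config: RunConfig, out_dir: Path) -> list[PosturePair]:
    if config.generator is not None:
        snapshots, truth = generate_database(config.generator)
        write_snapshots(snapshots, out_dir / "snapshots.csv", delimiter=config.delimiter)
        write_truth(truth, out_dir / "truth.csv")
    else:
        snapshots = read_snapshots(config.input_path, delimiter=config.delimiter)
    if config.position is not None:
        snapshots = [s for s in snapshots if s.position == config.position]
    pairs = extract_pairs(snapshots)
    logger.info("extracted %d pairs from %d snapshots", len(pairs), len(snapshots))
    return pairs


def compute_features(
    pairs: Sequence[PosturePair], segment_length: float = 1.0
) -> list[PairFeature]:
    """Reconstruct both curves of every pair and compute its change feature."""
    out = []
    for p in pairs:
        c0 = reconstruct_curve(p.t0.angles, segment_length)
        c1 = reconstruct_curve(p.t1.angles, segment_length)
        out.append(pair_feature(c0, c1, pair_id=p.pair_id))
    return out


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write all artifacts to ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pairs = _load_pairs(config, out_dir)
    if len(pairs) < 2:
        raise ValueError(f"pipeline needs at least 2 pairs, got {len(pairs)}")
    write_pairs(pairs, out_dir / "pairs.csv", delimiter=config.delimiter)
    summary_to_frame(summarize_database(pairs)).to_csv(
        out_dir / "summary.csv", sep=config.delimiter, index=False
    )

    features = compute_features(pairs, config.segment_length)
    features_to_frame(features).to_csv(
        out_dir / "features.csv", sep=config.delimiter, index=False
    )
    ids, mat = feature_matrix(features)

    emb_config = EmbeddingConfig(
        random_seed=config.seed,
        variance_threshold=config.variance_threshold,
        perplexity=config.perplexity,
    )
    scores, n_components, explained = pca_reduce(mat, config.variance_threshold)
    map2d = tsne_embed(scores, emb_config, pair_ids=ids)
    map_to_frame(map2d).to_csv(out_dir / "map.csv", sep=config.delimiter, index=False)

    position = config.position or (pairs[0].position if pairs else None)
    k = config.resolve_k(position)
    clustering = mst_cluster(map2d.coordinates, k)
    pd.DataFrame({"pair_id": ids, "cluster": clustering.labels}).to_csv(
        out_dir / "labels.csv", sep=config.delimiter, index=False
    )

    offsets = [offset_shape(p, config.segment_length, config.zero_tol) for p in pairs]
    offsets_to_frame(offsets).to_csv(
        out_dir / "offsets.csv", sep=config.delimiter, index=False
    )
    bundles = bundle_stats(offsets, clustering, config.zero_tol)
    bundles_to_frame(bundles).to_csv(
        out_dir / "bundles.csv", sep=config.delimiter, index=False
    )
    flags_to_frame(bundles).to_csv(
        out_dir / "cluster_flags.csv", sep=config.delimiter, index=False
    )

    angle_report(pairs).to_csv(out_dir / "angle_report.csv", sep=config.delimiter, index=False)
    wilcoxon_per_sensor(pairs).to_csv(
        out_dir / "wilcoxon.csv", sep=config.delimiter, index=False
    )

    # conservation: every stage must carry one row per pair
    assert len(features) == len(pairs) == map2d.coordinates.shape[0] == len(clustering.labels)

    manifest = {
        "config": _config_dict(config),
        "n_pairs": len(pairs),
        "pca_components": n_components,
        "explained_variance": [float(v) for v in explained],
        "k": k,
        "cluster_sizes": [int(s) for s in clustering.sizes()],
        "versions": {
            "spinechange": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "python": platform.python_version(),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return RunResult(
        pairs=pairs,
        features=features,
        map2d=map2d,
        clustering=clustering,
        offsets=offsets,
        bundles=bundles,
        pca_components=n_components,
        explained=explained,
        out_dir=out_dir,
    )


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    gen = d.get("generator")
    if gen is not None and "epoch" in gen:
        gen["epoch"] = gen["epoch"].isoformat()
    d["k_by_position"] = dict(d["k_by_position"])
    return d


@dataclasses.dataclass(frozen=True)
class SweepReport:
    """Cluster sizes and pairwise label agreement across a perplexity sweep."""

    perplexities: tuple[float, ...]
    cluster_sizes: Mapping[float, tuple[int, ...]]
    ari_matrix: np.ndarray  # (S, S) pairwise adjusted Rand indices
    reference: float
    flagged: tuple[float, ...]  # perplexities whose ARI to the reference is low

    def min_pairwise_ari(self) -> float:
        iu = np.triu_indices(len(self.perplexities), k=1)
        return float(self.ari_matrix[iu].min()) if iu[0].size else 1.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        ref_idx = self.perplexities.index(self.reference)
        for i, perp in enumerate(self.perplexities):
            rows.append(
                {
                    "perplexity": perp,
                    "cluster_sizes": " ".join(map(str, self.cluster_sizes[perp])),
                    "ari_to_reference": float(self.ari_matrix[i, ref_idx]),
                    "flagged": perp in self.flagged,
                }
            )
        return pd.DataFrame(rows)


def perplexity_sweep(config: RunConfig) -> SweepReport:
    """Re-embed and re-cluster across ``config.sweep`` perplexity values.

    The reference labeling is the sweep value closest to the working
    perplexity (30 by default); label sets whose ARI against it falls below
    ``config.ari_flag_threshold`` are flagged.
    """
    if len(config.sweep) < 2:
        raise ValueError("sweep needs at least 2 perplexity values")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pairs = _load_pairs(config, out_dir)
    features = compute_features(pairs, config.segment_length)
    ids, mat = feature_matrix(features)
    scores, _, _ = pca_reduce(mat, config.variance_threshold)

    position = config.position or (pairs[0].position if pairs else None)
    k = config.resolve_k(position)

    labelings: dict[float, np.ndarray] = {}
    sizes: dict[float, tuple[int, ...]] = {}
    for perp in config.sweep:
        emb = EmbeddingConfig(
            random_seed=config.seed,
            variance_threshold=config.variance_threshold,
            perplexity=perp,
        )
        map2d = tsne_embed(scores, emb, pair_ids=ids)
        clustering = mst_cluster(map2d.coordinates, k)
        labelings[perp] = clustering.labels
        sizes[perp] = tuple(int(s) for s in clustering.sizes())

    perps = tuple(config.sweep)
    S = len(perps)
    ari = np.ones((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            ari[i, j] = ari[j, i] = adjusted_rand_score(
                labelings[perps[i]], labelings[perps[j]]
            )
    reference = min(perps, key=lambda p: (abs(p - config.perplexity), p))
    ref_idx = perps.index(reference)
    flagged = tuple(
        p
        for i, p in enumerate(perps)
        if i != ref_idx and ari[i, ref_idx] < config.ari_flag_threshold
    )
    report = SweepReport(
        perplexities=perps,
        cluster_sizes=sizes,
        ari_matrix=ari,
        reference=reference,
        flagged=flagged,
    )
    report.to_frame().to_csv(out_dir / "sweep.csv", sep=config.delimiter, index=False)
    return report
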