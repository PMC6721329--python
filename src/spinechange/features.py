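"""Per-pair 15-dimensional change features.

For a posture pair's two reconstructed curves the change at spine-curve
point ``j`` is summarized by the displacement length

    l_j = || P_j|t1 - P_j|t0 ||_2

and the unit direction ``d_j = (P_j|t1 - P_j|t0) / l_j``.  The sensor pinned
at the origin (``P1``) never moves and is left out, so ``j`` ranges over
``{0, 2, 3, 4, 5}`` and the flattened feature vector has 15 entries:

    F = (d0x, d0y, d2x, d2y, ..., d5x, d5y, l0, l2, l3, l4, l5).

Below a displacement tolerance the direction is undefined; both ``l_j`` and
``d_j`` are then zeroed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .spine import SpineCurve

#: spine-curve point indices entering the feature (P1 is pinned at the origin)
FEATURE_LEVELS = (0, 2, 3, 4, 5)
FEATURE_DIM = 3 * len(FEATURE_LEVELS)

FEATURE_COLUMNS = tuple(
    f"d{j}{axis}" for j in FEATURE_LEVELS for axis in ("x", "y")
) + tuple(f"l{j}" for j in FEATURE_LEVELS)


@dataclasses.dataclass(frozen=True)
class PairFeature:
    """Directions, lengths and the flattened 15-entry vector for one pair."""

    directions: np.ndarray  # (5, 2) unit or zero vectors, levels 0,2,3,4,5
    lengths: np.ndarray  # (5,) nonnegative, model units
    vector: np.ndarray  # (15,) flattened layout per FEATURE_COLUMNS
    pair_id: str


def pair_feature(
    curve_t0: SpineCurve, curve_t1: SpineCurve, tol: float = 1e-9, pair_id: str = ""
) -> PairFeature:
    """Compute the change feature between a pair's two spine curves.

    Both curves must share the same segment length; a mismatch is a domain
    error because displacement lengths would not be comparable.
    """
    if curve_t0.segment_length != curve_t1.segment_length:
        raise ValueError(
            "curves have mismatched segment lengths: "
            f"{curve_t0.segment_length} vs {curve_t1.segment_length}"
        )
    diffs = curve_t1.points[list(FEATURE_LEVELS)] - curve_t0.points[list(FEATURE_LEVELS)]
    lengths = np.linalg.norm(diffs, axis=1)
    directions = np.zeros_like(diffs)
    moving = lengths >= tol
    directions[moving] = diffs[moving] / lengths[moving, None]
    lengths = np.where(moving, lengths, 0.0)
    vector = np.concatenate([directions.ravel(), lengths])
    return PairFeature(
        directions=directions, lengths=lengths, vector=vector, pair_id=pair_id
    )


def feature_matrix(features: Sequence[PairFeature]) -> tuple[list[str], np.ndarray]:
    """Stack features into (pair ids, N x 15 matrix), row order preserved."""
    ids = [f.pair_id for f in features]
    mat = np.vstack([f.vector for f in features]) if features else np.empty((0, FEATURE_DIM))
    return ids, mat


def features_to_frame(features: Sequence[PairFeature]) -> pd.DataFrame:
    ids, mat = feature_matrix(features)
    df = pd.DataFrame(mat, columns=list(FEATURE_COLUMNS))
    df.insert(0, "pair_id", ids)
    return df


def frame_to_matrix(df: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    return list(df["pair_id"]), df[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
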