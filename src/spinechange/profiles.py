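"""Cluster profiles: offset-spine-shape bundles with percentile bands.

Each cluster is summarized by overlaying its members' offset spine shapes.
At every point level 0..5 the horizontal (x) distribution is reduced to the
1st/25th/50th/75th/99th percentiles — the light band, dark band and median
of the bundle plot — plus tallies of the +/o/- sign annotations.

Percentiles use linear interpolation between closest order statistics so
that bundle tables are bit-reproducible.

Three per-cluster boolean/ordinal flags turn the qualitative geometric
separations seen in bundles into machine-checkable descriptors:

* ``base_sign_unanimous`` — the shared sign of the base point P0's x across
  all members, or ``None`` when members disagree;
* ``upper_slant_sign`` — the sign of the median x at the topmost level P5;
* ``crossing_level`` — the lowest level at which the median-sign sequence
  changes sign (the shape crosses the vertical line between that level and
  the next), with ``crossing_multiplicity`` counting all such changes since
  a bundle may cross more than once.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .mst import Clustering
from .spine import OffsetShape, classify_sign

PERCENTILES = (1.0, 25.0, 50.0, 75.0, 99.0)
N_LEVELS = 6


@dataclasses.dataclass(frozen=True)
class BundleStats:
    """Percentile bands and sign tallies for one cluster's offset shapes."""

    cluster_id: int
    n_members: int
    percentiles: np.ndarray  # (6 levels, 5 percentiles), x in model units
    sign_counts: np.ndarray  # (6 levels, 3) counts of +, o, -
    base_sign_unanimous: str | None
    upper_slant_sign: str
    crossing_level: int | None
    crossing_multiplicity: int


def _median_sign_path(medians: np.ndarray, zero_tol: float) -> list[str]:
    return [classify_sign(x, zero_tol) for x in medians]


def _crossings(sign_path: Sequence[str]) -> tuple[int | None, int]:
    """Lowest level where consecutive non-'o' median signs flip, and the count."""
    changes = []
    prev_sign, prev_level = None, None
    for level, s in enumerate(sign_path):
        if s == "o":
            continue
        if prev_sign is not None and s != prev_sign:
            changes.append(prev_level)
        prev_sign, prev_level = s, level
    return (changes[0] if changes else None), len(changes)


def bundle_stats(
    offsets: Sequence[OffsetShape],
    clustering: Clustering,
    zero_tol: float = 1e-9,
) -> list[BundleStats]:
    """Summarize each cluster of offset spine shapes as a percentile bundle.

    ``offsets`` must align row-for-row with ``clustering.labels``; a length
    mismatch is a domain error since the alignment is by pair id.
    """
    if len(offsets) != len(clustering.labels):
        raise ValueError(
            f"{len(offsets)} offset shapes but {len(clustering.labels)} labels"
        )
    xs = np.array([o.points[:, 0] for o in offsets])  # (N, 6)
    signs = np.array([list(o.signs) for o in offsets])  # (N, 6)

    out = []
    for cid in range(clustering.k):
        member = clustering.labels == cid
        mx = xs[member]
        msigns = signs[member]
        pct = np.percentile(mx, PERCENTILES, axis=0, method="linear").T  # (6, 5)
        counts = np.stack(
            [(msigns == s).sum(axis=0) for s in ("+", "o", "-")], axis=1
        )  # (6, 3)
        base = msigns[:, 0]
        base_unanimous = base[0] if len(set(base)) == 1 else None
        medians = pct[:, PERCENTILES.index(50.0)]
        sign_path = _median_sign_path(medians, zero_tol)
        crossing_level, multiplicity = _crossings(sign_path)
        out.append(
            BundleStats(
                cluster_id=cid,
                n_members=int(member.sum()),
                percentiles=pct,
                sign_counts=counts,
                base_sign_unanimous=base_unanimous,
                upper_slant_sign=sign_path[-1],
                crossing_level=crossing_level,
                crossing_multiplicity=multiplicity,
            )
        )
    return out


def bundles_to_frame(bundles: Sequence[BundleStats]) -> pd.DataFrame:
    rows = []
    for b in bundles:
        for level in range(N_LEVELS):
            rows.append(
                {
                    "cluster": b.cluster_id,
                    "level": level,
                    "n_members": b.n_members,
                    "p01": b.percentiles[level, 0],
                    "p25": b.percentiles[level, 1],
                    "p50": b.percentiles[level, 2],
                    "p75": b.percentiles[level, 3],
                    "p99": b.percentiles[level, 4],
                    "n_plus": int(b.sign_counts[level, 0]),
                    "n_zero": int(b.sign_counts[level, 1]),
                    "n_minus": int(b.sign_counts[level, 2]),
                }
            )
    return pd.DataFrame(rows)


def flags_to_frame(bundles: Sequence[BundleStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster": b.cluster_id,
                "n_members": b.n_members,
                "base_sign_unanimous": b.base_sign_unanimous or "",
                "upper_slant_sign": b.upper_slant_sign,
                "crossing_level": -1 if b.crossing_level is None else b.crossing_level,
                "crossing_multiplicity": b.crossing_multiplicity,
            }
            for b in bundles
        ]
    )


def plot_bundles(
    bundles: Sequence[BundleStats],
    offsets: Sequence[OffsetShape],
    clustering: Clustering,
    path: str,
) -> None:
    """Optional convenience plot of the bundles (one panel per cluster)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ys = np.array([o.points[:, 1] for o in offsets])
    fig, axes = plt.subplots(1, len(bundles), figsize=(3 * len(bundles), 4), squeeze=False)
    for ax, b in zip(axes[0], bundles):
        y = ys[clustering.labels == b.cluster_id].mean(axis=0)
        ax.fill_betweenx(y, b.percentiles[:, 0], b.percentiles[:, 4], color="0.85")
        ax.fill_betweenx(y, b.percentiles[:, 1], b.percentiles[:, 3], color="0.6")
        ax.plot(b.percentiles[:, 2], y, "o-", color="tab:orange", ms=4)
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_title(f"cluster {b.cluster_id} (n={b.n_members})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
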