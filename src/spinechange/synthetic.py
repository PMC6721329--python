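"""Synthetic snapshot databases with planted change archetypes.

The generator emulates the statistical structure the analysis pipeline
assumes in real five-sensor posture recordings: per-position baseline tilt
distributions for the unguided (t0) snapshots, and a mixture of *change
archetypes* — per-sensor mean angle-change templates — that produce the
guided (t1) snapshots.  Each simulated user draws

* t0 angles ~ Normal(baseline mean_i, baseline sd_i) per sensor,
* an archetype by mixture weight,
* t1 angles = t0 + template + Normal(0, change sd) + measurement noise,

with measurement noise added independently to both snapshots.  Baseline
defaults are the observed per-position tilt statistics of unguided standing
/ sitting / hip-hinging snapshots.  The archetype templates translate
posture-trainer vocabulary into angle space: *increased pelvic anteversion*
is a positive change on the lowest sensor, *sway reduction* a positive
change on the upper sensors (which sit at negative tilts when swayed), and
so on.  A hidden truth table records each user's archetype for
label-recovery tests; the pipeline never reads it.

An optional contamination mode replaces a small fraction of change draws
with wide-tailed ones, breaking normality the way real angle data does, so
the nonparametric test path is exercised meaningfully.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import N_SENSORS, SensorSnapshot

#: per-position unguided (t0) baseline tilt means and SDs, degrees, sensor 1 first
BASELINE_T0 = {
    "standing": {
        "means": (19.6, 10.1, -4.1, -12.3, -12.0),
        "sds": (10.3, 10.7, 10.3, 8.9, 9.5),
    },
    "sitting": {
        "means": (12.0, 6.0, -0.6, -6.8, -6.9),
        "sds": (10.0, 9.4, 8.7, 7.4, 8.2),
    },
    "hinging": {
        "means": (75.5, 77.4, 79.1, 82.1, 87.8),
        "sds": (18.1, 18.8, 20.1, 21.6, 22.6),
    },
}


@dataclasses.dataclass(frozen=True)
class ArchetypeSpec:
    """One planted change archetype: a mean angle-change template plus spread."""

    name: str
    mean_change: tuple[float, float, float, float, float]  # degrees per sensor
    change_sd: tuple[float, float, float, float, float] = (1.0,) * N_SENSORS
    weight: float = 1.0

    def __post_init__(self) -> None:
        if len(self.mean_change) != N_SENSORS:
            raise ValueError("mean_change needs one entry per sensor")
        if len(self.change_sd) != N_SENSORS:
            raise ValueError("change_sd needs one entry per sensor")
        if any(s < 0 for s in self.change_sd):
            raise ValueError("change SDs must be nonnegative")
        if self.weight < 0:
            raise ValueError("weights must be nonnegative")


def archetype(name: str, mean_change: Sequence[float], change_sd: float | Sequence[float] = 1.0,
              weight: float = 1.0) -> ArchetypeSpec:
    """Convenience constructor accepting a scalar change SD."""
    if isinstance(change_sd, (int, float)):
        change_sd = (float(change_sd),) * N_SENSORS
    return ArchetypeSpec(name, tuple(float(v) for v in mean_change), tuple(change_sd), weight)


#: default archetype mixture: three well-separated trainer-vocabulary templates.
#: every template keeps a clearly nonzero sensor-1 change: the base point's
#: displacement direction is a unit vector, so a mean change near zero there
#: would make its sign flip user-to-user and inflate the within-archetype
#: spread far beyond the nominal change SD.
DEFAULT_ARCHETYPES = (
    archetype("anteversion_loss", (-6.0, -3.0, 0.0, 2.0, 3.0)),
    archetype("sway_straightening", (-5.0, 2.0, 5.0, 8.0, 9.0)),
    archetype("anteversion_gain", (8.0, 5.0, 2.0, 4.0, 5.0)),
)


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Settings for one synthetic snapshot database.

    ``noise_sd`` is per-snapshot measurement noise (degrees); the
    between-snapshot change spread lives on each archetype.  Timestamps
    place t0 uniformly in the year starting at ``epoch`` and draw the
    unguided-to-guided gap from an exponential with 2-day median, floored
    at 30 minutes, matching the magnitudes seen in real pair databases.
    ``contaminate_fraction`` > 0 replaces that fraction of change draws
    with 5x-wider ones (a skew-contaminated mixture).
    """

    position: str = "standing"
    n_users: int = 120
    baseline_means: tuple[float, ...] | None = None  # None -> per-position default
    baseline_sds: tuple[float, ...] | None = None
    archetypes: tuple[ArchetypeSpec, ...] = DEFAULT_ARCHETYPES
    noise_sd: float = 0.5
    contaminate_fraction: float = 0.0
    epoch: dt.datetime = dt.datetime(2018, 1, 1)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.position not in BASELINE_T0:
            raise ValueError(f"unknown position {self.position!r}")
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not self.archetypes or sum(a.weight for a in self.archetypes) <= 0:
            raise ValueError("archetype weights must sum to a positive value")
        if not 0.0 <= self.contaminate_fraction < 1.0:
            raise ValueError("contaminate_fraction must be in [0, 1)")

    @property
    def means(self) -> np.ndarray:
        if self.baseline_means is not None:
            return np.asarray(self.baseline_means, dtype=float)
        return np.asarray(BASELINE_T0[self.position]["means"])

    @property
    def sds(self) -> np.ndarray:
        sds = (
            np.asarray(self.baseline_sds, dtype=float)
            if self.baseline_sds is not None
            else np.asarray(BASELINE_T0[self.position]["sds"])
        )
        if np.any(sds < 0):
            raise ValueError("baseline SDs must be nonnegative")
        return sds


_GAP_MEDIAN_S = 2 * 86400.0  # 2-day median unguided-to-guided gap
_GAP_FLOOR_S = 30 * 60.0


def generate_database(
    config: GeneratorConfig,
) -> tuple[list[SensorSnapshot], pd.DataFrame]:
    """Generate one unguided and one guided snapshot per simulated user.

    Returns the snapshot list (interleaved t0, t1 per user) and the hidden
    truth table (``user_id``, ``archetype``) for label-recovery checks.
    Byte-identical for a given config, including the seed.
    """
    rng = np.random.default_rng(config.random_seed)
    weights = np.array([a.weight for a in config.archetypes], dtype=float)
    weights = weights / weights.sum()
    means, sds = config.means, config.sds

    snapshots: list[SensorSnapshot] = []
    truth_rows = []
    for u in range(config.n_users):
        user_id = f"u{u + 1:04d}"
        aidx = int(rng.choice(len(config.archetypes), p=weights))
        arch = config.archetypes[aidx]
        true_t0 = rng.normal(means, sds)
        change_sd = np.asarray(arch.change_sd)
        if config.contaminate_fraction > 0 and rng.random() < config.contaminate_fraction:
            change_sd = 5.0 * change_sd
        delta = np.asarray(arch.mean_change) + rng.normal(0.0, change_sd)
        t0_angles = true_t0 + rng.normal(0.0, config.noise_sd, N_SENSORS)
        t1_angles = true_t0 + delta + rng.normal(0.0, config.noise_sd, N_SENSORS)
        t0_angles = np.clip(t0_angles, -180.0, 180.0)
        t1_angles = np.clip(t1_angles, -180.0, 180.0)

        t0_offset = rng.uniform(0.0, 365 * 86400.0)
        gap = max(_GAP_FLOOR_S, rng.exponential(_GAP_MEDIAN_S / math.log(2)))
        t0_ts = config.epoch + dt.timedelta(seconds=round(t0_offset))
        t1_ts = t0_ts + dt.timedelta(seconds=round(gap))

        snapshots.append(
            SensorSnapshot(user_id, config.position, "unguided", t0_ts, tuple(t0_angles))
        )
        snapshots.append(
            SensorSnapshot(user_id, config.position, "guided", t1_ts, tuple(t1_angles))
        )
        truth_rows.append({"user_id": user_id, "archetype": arch.name})
    return snapshots, pd.DataFrame(truth_rows)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Write the hidden truth sidecar (never read by the pipeline)."""
    truth.to_csv(path, index=False)
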