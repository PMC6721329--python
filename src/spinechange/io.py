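"""Data model and file I/O for timestamped five-sensor posture snapshots.

A *snapshot* is one captured frame of the five forward-tilt angles measured
along the lumbar spine, together with user, position (standing / sitting /
hinging) and guidance metadata.  Snapshots arrive as delimited text, one row
per snapshot.  From a snapshot database we extract one *posture pair* per
user and position: the earliest unguided snapshot (``t0``, the most
unlearned realization of the position) and the latest guided snapshot
(``t1``, the user's current best guided imitation).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
import math
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

POSITIONS = ("standing", "sitting", "hinging")
GUIDANCES = ("unguided", "guided")
N_SENSORS = 5

#: canonical column names of the snapshot table
SNAPSHOT_COLUMNS = (
    "user_id",
    "position",
    "guidance",
    "timestamp",
    "angle_1",
    "angle_2",
    "angle_3",
    "angle_4",
    "angle_5",
)

# common aliases accepted for the position field; the deposited database's
# schema is adapted through an explicit column map instead of guessing.
_POSITION_ALIASES = {
    "standing": "standing",
    "sitting": "sitting",
    "hinging": "hinging",
    "hip hinging": "hinging",
    "hip_hinging": "hinging",
    "bending": "hinging",
}


class ParseError(ValueError):
    """Raised for malformed snapshot tables; carries the offending row."""


@dataclasses.dataclass(frozen=True)
class SensorSnapshot:
    """One timestamped five-angle reading.

    Angles are forward tilts in degrees, sensor 1 lowest on the spine.
    """

    user_id: str
    position: str
    guidance: str
    timestamp: dt.datetime
    angles: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValueError(f"unknown position {self.position!r}")
        if self.guidance not in GUIDANCES:
            raise ValueError(f"unknown guidance {self.guidance!r}")
        if len(self.angles) != N_SENSORS:
            raise ValueError(f"expected {N_SENSORS} angles, got {len(self.angles)}")
        for a in self.angles:
            if not math.isfinite(a):
                raise ValueError(f"non-finite angle {a!r}")
            if abs(a) > 180.0:
                raise ValueError(f"implausible tilt angle {a!r} (|angle| > 180)")


@dataclasses.dataclass(frozen=True)
class PosturePair:
    """Matched (earliest unguided, latest guided) snapshots of one user/position."""

    user_id: str
    position: str
    t0: SensorSnapshot
    t1: SensorSnapshot

    def __post_init__(self) -> None:
        if not (self.t0.user_id == self.t1.user_id == self.user_id):
            raise ValueError("pair snapshots must share the pair's user_id")
        if not (self.t0.position == self.t1.position == self.position):
            raise ValueError("pair snapshots must share the pair's position")
        if self.t0.guidance != "unguided" or self.t1.guidance != "guided":
            raise ValueError("t0 must be unguided and t1 guided")
        if self.t1.timestamp < self.t0.timestamp:
            raise ValueError("t1 must not precede t0")

    @property
    def pair_id(self) -> str:
        return f"{self.user_id}:{self.position}"

    @property
    def time_difference(self) -> dt.timedelta:
        return self.t1.timestamp - self.t0.timestamp

    @property
    def angle_deltas(self) -> tuple[float, ...]:
        """Per-sensor guided-minus-unguided angle change (degrees)."""
        return tuple(a1 - a0 for a0, a1 in zip(self.t0.angles, self.t1.angles))


@dataclasses.dataclass(frozen=True)
class PositionSummary:
    n_pairs: int
    n_users: int
    dt_min: dt.timedelta
    dt_mean: dt.timedelta
    dt_median: dt.timedelta
    dt_max: dt.timedelta


@dataclasses.dataclass(frozen=True)
class DatabaseSummary:
    """Pair counts and between-snapshot time statistics, per position and overall."""

    per_position: Mapping[str, PositionSummary]
    overall: PositionSummary | None


def format_duration(td: dt.timedelta) -> str:
    """Render a duration as ``d hh:mm:ss`` (days unpadded, rest zero-padded)."""
    total = int(round(td.total_seconds()))
    if total < 0:
        raise ValueError("durations must be nonnegative")
    days, rem = divmod(total, 86400)
    hh, rem = divmod(rem, 3600)
    mm, ss = divmod(rem, 60)
    return f"{days} {hh:02d}:{mm:02d}:{ss:02d}"


def _parse_row(row: Mapping[str, str], row_no: int) -> SensorSnapshot:
    try:
        raw_pos = str(row["position"]).strip().lower()
        position = _POSITION_ALIASES.get(raw_pos)
        if position is None:
            raise ValueError(f"unknown position {raw_pos!r}")
        guidance = str(row["guidance"]).strip().lower()
        if guidance not in GUIDANCES:
            raise ValueError(f"unknown guidance {guidance!r}")
        ts_raw = str(row["timestamp"]).strip()
        try:
            timestamp = dt.datetime.fromisoformat(ts_raw)
        except ValueError as exc:
            raise ValueError(f"unparseable timestamp {ts_raw!r}") from exc
        if timestamp.tzinfo is not None:
            timestamp = timestamp.replace(tzinfo=None)
        angles = []
        for i in range(1, N_SENSORS + 1):
            raw = row[f"angle_{i}"]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
                raise ValueError(f"missing angle_{i}")
            try:
                angles.append(float(raw))
            except ValueError as exc:
                raise ValueError(f"unparseable angle_{i} {raw!r}") from exc
        return SensorSnapshot(
            user_id=str(row["user_id"]),
            position=position,
            guidance=guidance,
            timestamp=timestamp,
            angles=tuple(angles),
        )
    except ValueError as exc:
        raise ParseError(f"row {row_no}: {exc}") from exc


def read_snapshots(
    path: str | Path,
    *,
    delimiter: str = ",",
    column_map: Mapping[str, str] | None = None,
) -> list[SensorSnapshot]:
    """Read a snapshot table from delimited text.

    Parameters
    ----------
    path
        File with a header row naming (after optional remapping) the columns
        ``user_id, position, guidance, timestamp, angle_1..angle_5``.
    delimiter
        Field separator, comma by default.
    column_map
        Optional mapping canonical-name -> actual header, adapting foreign
        schemas without rewriting the file.

    Returns
    -------
    One :class:`SensorSnapshot` per row, input order preserved.  Malformed
    rows raise :class:`ParseError` naming the 1-based data row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in SNAPSHOT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s): {', '.join(missing)}")
    snapshots = []
    for idx, row in enumerate(df.to_dict("records"), start=1):
        snapshots.append(_parse_row(row, idx))
    return snapshots


def snapshots_to_frame(snapshots: Iterable[SensorSnapshot]) -> pd.DataFrame:
    rows = [
        {
            "user_id": s.user_id,
            "position": s.position,
            "guidance": s.guidance,
            "timestamp": s.timestamp.isoformat(sep="T", timespec="seconds"),
            **{f"angle_{i + 1}": s.angles[i] for i in range(N_SENSORS)},
        }
        for s in snapshots
    ]
    return pd.DataFrame(rows, columns=list(SNAPSHOT_COLUMNS))


def write_snapshots(
    snapshots: Iterable[SensorSnapshot], path: str | Path, *, delimiter: str = ","
) -> None:
    snapshots_to_frame(snapshots).to_csv(path, sep=delimiter, index=False)


def extract_pairs(snapshots: Sequence[SensorSnapshot]) -> list[PosturePair]:
    """Form exactly one posture pair per (user, position).

    ``t0`` is the earliest unguided snapshot by timestamp and ``t1`` the
    latest guided one; a user/position lacking either kind — or whose latest
    guided snapshot precedes its earliest unguided one — contributes no pair.
    Timestamp ties break by input order (first occurrence wins), so extraction
    is reproducible.  Output order follows first appearance in the input.
    """
    groups: OrderedDict[tuple[str, str], dict[str, list[tuple[int, SensorSnapshot]]]] = OrderedDict()
    for idx, snap in enumerate(snapshots):
        key = (snap.user_id, snap.position)
        bucket = groups.setdefault(key, {"unguided": [], "guided": []})
        bucket[snap.guidance].append((idx, snap))

    pairs: list[PosturePair] = []
    n_skipped = 0
    for (user_id, position), bucket in groups.items():
        if not bucket["unguided"] or not bucket["guided"]:
            n_skipped += 1
            continue
        _, t0 = min(bucket["unguided"], key=lambda item: (item[1].timestamp, item[0]))
        _, t1 = max(bucket["guided"], key=lambda item: (item[1].timestamp, -item[0]))
        if t1.timestamp < t0.timestamp:
            n_skipped += 1
            continue
        pairs.append(PosturePair(user_id=user_id, position=position, t0=t0, t1=t1))
    if n_skipped:
        logger.info("extract_pairs: skipped %d incomplete user/position groups", n_skipped)
    return pairs


def _summarize_deltas(pairs: Sequence[PosturePair]) -> PositionSummary:
    deltas = sorted(p.time_difference for p in pairs)
    n = len(deltas)
    mean = sum(deltas, dt.timedelta(0)) / n
    if n % 2:
        median = deltas[n // 2]
    else:
        median = (deltas[n // 2 - 1] + deltas[n // 2]) / 2
    return PositionSummary(
        n_pairs=n,
        n_users=len({p.user_id for p in pairs}),
        dt_min=deltas[0],
        dt_mean=mean,
        dt_median=median,
        dt_max=deltas[-1],
    )


def summarize_database(pairs: Sequence[PosturePair]) -> DatabaseSummary:
    """Pair counts and unguided-to-guided time statistics per position and overall."""
    per_position = {}
    for position in POSITIONS:
        subset = [p for p in pairs if p.position == position]
        if subset:
            per_position[position] = _summarize_deltas(subset)
    overall = _summarize_deltas(list(pairs)) if pairs else None
    return DatabaseSummary(per_position=per_position, overall=overall)


def summary_to_frame(summary: DatabaseSummary) -> pd.DataFrame:
    rows = []
    items = list(summary.per_position.items())
    if summary.overall is not None:
        items.append(("full", summary.overall))
    for name, s in items:
        rows.append(
            {
                "position": name,
                "n_pairs": s.n_pairs,
                "n_users": s.n_users,
                "dt_min": format_duration(s.dt_min),
                "dt_mean": format_duration(s.dt_mean),
                "dt_median": format_duration(s.dt_median),
                "dt_max": format_duration(s.dt_max),
            }
        )
    return pd.DataFrame(rows)


def pairs_to_frame(pairs: Iterable[PosturePair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        row = {
            "pair_id": p.pair_id,
            "user_id": p.user_id,
            "position": p.position,
            "t0_timestamp": p.t0.timestamp.isoformat(sep="T", timespec="seconds"),
            "t1_timestamp": p.t1.timestamp.isoformat(sep="T", timespec="seconds"),
        }
        for i in range(N_SENSORS):
            row[f"t0_angle_{i + 1}"] = p.t0.angles[i]
        for i in range(N_SENSORS):
            row[f"t1_angle_{i + 1}"] = p.t1.angles[i]
        rows.append(row)
    return pd.DataFrame(rows)


def write_pairs(pairs: Iterable[PosturePair], path: str | Path, *, delimiter: str = ",") -> None:
    pairs_to_frame(pairs).to_csv(path, sep=delimiter, index=False)


def read_pairs(path: str | Path, *, delimiter: str = ",") -> list[PosturePair]:
    """Read a pairs table written by :func:`write_pairs`."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    pairs = []
    for idx, row in enumerate(df.to_dict("records"), start=1):
        try:
            t0 = SensorSnapshot(
                user_id=str(row["user_id"]),
                position=str(row["position"]),
                guidance="unguided",
                timestamp=dt.datetime.fromisoformat(str(row["t0_timestamp"])),
                angles=tuple(float(row[f"t0_angle_{i + 1}"]) for i in range(N_SENSORS)),
            )
            t1 = SensorSnapshot(
                user_id=str(row["user_id"]),
                position=str(row["position"]),
                guidance="guided",
                timestamp=dt.datetime.fromisoformat(str(row["t1_timestamp"])),
                angles=tuple(float(row[f"t1_angle_{i + 1}"]) for i in range(N_SENSORS)),
            )
            pairs.append(PosturePair(str(row["user_id"]), str(row["position"]), t0, t1))
        except (KeyError, ValueError) as exc:
            raise ParseError(f"row {idx}: {exc}") from exc
    return pairs
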