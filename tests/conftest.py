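import datetime as dt

import numpy as np
import pytest

from spinechange.io import PosturePair, SensorSnapshot

EPOCH = dt.datetime(2018, 1, 1, 10, 0, 0)


def make_snapshot(
    user="u1",
    position="standing",
    guidance="unguided",
    ts=EPOCH,
    angles=(19.6, 10.1, -4.1, -12.3, -12.0),
):
    return SensorSnapshot(user, position, guidance, ts, tuple(float(a) for a in angles))


def make_pair(t0_angles, t1_angles, user="u1", position="standing", gap_hours=24.0):
    t0 = make_snapshot(user, position, "unguided", EPOCH, t0_angles)
    t1 = make_snapshot(
        user, position, "guided", EPOCH + dt.timedelta(hours=gap_hours), t1_angles
    )
    return PosturePair(user, position, t0, t1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def snapshot_csv(tmp_path):
    """A small well-formed snapshot table on disk."""
    path = tmp_path / "snapshots.csv"
    path.write_text(
        "user_id,position,guidance,timestamp,angle_1,angle_2,angle_3,angle_4,angle_5\n"
        "u1,standing,unguided,2018-01-01T10:00:00,19.6,10.1,-4.1,-12.3,-12.0\n"
        "u1,standing,guided,2018-01-03T10:00:00,22.5,13.8,-0.1,-8.2,-7.6\n"
        "u2,sitting,unguided,2018-02-01T09:00:00,12.0,6.0,-0.6,-6.8,-6.9\n"
        "u2,sitting,guided,2018-02-02T09:00:00,16.7,6.3,-1.0,-6.9,-6.7\n"
    )
    return path
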