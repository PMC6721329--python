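"""Descriptive angle statistics and the Wilcoxon signed-rank test."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from spinechange.stats import (
    angle_report,
    descriptive_table,
    format_p,
    wilcoxon_per_sensor,
    wilcoxon_signed_rank,
)

from conftest import make_pair


def enumerate_exact_p(diffs):
    """Full 2^n sign-enumeration oracle for the two-sided exact p-value."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    total = 2**n
    p_le = np.sum(ws <= w_obs + 1e-12) / total
    p_ge = np.sum(ws >= w_obs - 1e-12) / total
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_five_positive_differences(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.method == "exact"
        assert res.statistic == pytest.approx(15.0)
        assert res.p_value == pytest.approx(0.0625)

    def test_symmetric_differences_are_insignificant(self):
        res = wilcoxon_signed_rank([3.0, -3.0, 1.5, -1.5, 2.0, -2.0])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 7, 10, 12])
    def test_exact_matches_enumeration(self, rng, n):
        for _ in range(10):
            d = np.round(rng.normal(size=n), 1)  # rounding induces ties
            d = np.where(d == 0, 0.1, d)
            res = wilcoxon_signed_rank(d)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(enumerate_exact_p(d), abs=1e-12)

    def test_matches_scipy_exact_on_tie_free_data(self, rng):
        for _ in range(20):
            d = rng.normal(size=15)
            mine = wilcoxon_signed_rank(d)
            ref = scipy_wilcoxon(d, method="exact")
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_crossover(self, rng):
        deviations = []
        for _ in range(100):
            d = rng.normal(size=25)
            exact = wilcoxon_signed_rank(d, exact_threshold=25).p_value
            approx = wilcoxon_signed_rank(d, exact_threshold=0).p_value
            deviations.append(abs(exact - approx))
        assert max(deviations) < 0.01

    def test_zero_differences_discarded(self):
        with_zeros = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, -3.0])
        without = wilcoxon_signed_rank([1.0, 2.0, -3.0])
        assert with_zeros.n_effective == 3
        assert with_zeros.p_value == pytest.approx(without.p_value)

    def test_degenerate_all_zero_sample(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0 and res.n_effective == 0

    def test_invariance_under_relabeling_and_sign_flip(self, rng):
        d = rng.normal(size=14)
        base = wilcoxon_signed_rank(d).p_value
        assert wilcoxon_signed_rank(d[::-1]).p_value == pytest.approx(base, abs=1e-12)
        assert wilcoxon_signed_rank(-d).p_value == pytest.approx(base, abs=1e-12)

    @pytest.mark.parametrize("bad", [[], [np.nan, 1.0]])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(bad)


class TestDescriptiveTable:
    def test_constant_angles_collapse_spread(self):
        pairs = [make_pair((5.0,) * 5, (7.0,) * 5, user=f"u{i}") for i in range(4)]
        df = descriptive_table(pairs)
        t0 = df[(df["role"] == "t0") & (df["sensor"] == 1)].iloc[0]
        assert t0["sd"] == 0.0 and t0["iqr"] == 0.0
        assert t0["min"] == t0["max"] == t0["median"] == 5.0

    def test_symmetric_triple(self):
        pairs = [
            make_pair((a,) * 5, (a + 1,) * 5, user=f"u{i}")
            for i, a in enumerate((10.0, 20.0, 30.0))
        ]
        row = descriptive_table(pairs).query("role == 't0' and sensor == 1").iloc[0]
        assert row["mean"] == pytest.approx(20.0)
        assert row["median"] == pytest.approx(20.0)
        assert row["sd"] == pytest.approx(10.0)
        assert row["iqr"] == pytest.approx(10.0)

    def test_wilcoxon_per_sensor_flags(self, rng):
        # sensor 1 shifts by +3, the rest carry symmetric noise only
        pairs = []
        for i in range(30):
            t0 = rng.normal(0, 5, 5)
            shift = np.array([3.0, 0, 0, 0, 0])
            t1 = t0 + shift + rng.normal(0, 0.5, 5)
            pairs.append(make_pair(tuple(t0), tuple(t1), user=f"u{i}"))
        df = wilcoxon_per_sensor(pairs)
        assert bool(df[df["sensor"] == 1]["significant"].iloc[0])
        assert df["method"].eq("normal").all()  # 30 pairs > exact threshold

    def test_angle_report_shape_and_star(self):
        pairs = [
            make_pair((i, 0, 0, 0, 0), (i + 4, 0, 0, 0, 0), user=f"u{i}")
            for i in range(10)
        ]
        report = angle_report(pairs)
        assert len(report) == 5  # one position x five sensors
        assert set(report.columns) >= {"t0_mean", "t1_mean", "p_value", "star"}
        assert report[report["sensor"] == 1]["star"].iloc[0] == "*"
        # remaining sensors never change -> degenerate, never starred
        assert (report[report["sensor"] != 1]["star"] == "").all()


def test_p_display_truncation():
    assert format_p(1e-8) == "<1e-06"
    assert format_p(0.0321) == "0.0321"
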