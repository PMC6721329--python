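"""Descriptive angle statistics and per-sensor paired Wilcoxon tests.

Sensor tilt angles are not normally distributed, so the guided-vs-unguided
comparison uses the nonparametric Wilcoxon signed-rank test on the per-pair
differences of each sensor.  The implementation follows the classical
procedure: zero differences are discarded, absolute differences are
midranked, and the null distribution of the positive-rank sum W+ is

* enumerated exactly (via the generating function of the rank sums) for
  effective sample sizes up to ``exact_threshold`` (default 25), which is
  valid with or without ties;
* otherwise approximated by a normal with tie-corrected variance and a
  continuity correction.

p-values are two-sided.  No multiple-testing correction is applied across
sensors or positions; reports state this in their header.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .io import N_SENSORS, POSITIONS, PosturePair

#: reporting convention: p-values below this display as "<1e-06"
EPS_DISPLAY = 1e-6

_STAT_COLUMNS = ("mean", "sd", "min", "max", "median", "iqr")


@dataclasses.dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+, sum of positive ranks
    p_value: float
    n_effective: int  # nonzero differences entering the test
    method: str  # "exact" | "normal" | "degenerate"


def _exact_p_two_sided(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumerating the null distribution of W+.

    Ties yield half-integer midranks; doubling makes all rank sums integer,
    so the 2^n sign assignments are counted with an integer convolution
    (generating-function) table rather than explicit enumeration.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= 2.0 ** len(r2)
    w2 = int(np.rint(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_p_two_sided(d_nonzero: np.ndarray, ranks: np.ndarray, w_plus: float) -> float:
    n = len(d_nonzero)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d_nonzero), return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return 1.0
    dev = w_plus - mean
    # continuity correction: shrink the deviation by half a step
    dev -= 0.5 * np.sign(dev)
    z = dev / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def wilcoxon_signed_rank(
    differences: Sequence[float], exact_threshold: int = 25
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded (the classical treatment).  If every
    difference is zero the sample is degenerate: p is reported as 1 with a
    warning rather than an error, so batch reports survive constant sensors.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("need a non-empty 1D array of differences")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; Wilcoxon test is degenerate", stacklevel=2)
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_effective=0, method="degenerate")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_threshold:
        p = _exact_p_two_sided(ranks, w_plus)
        method = "exact"
    else:
        p = _normal_p_two_sided(d, ranks, w_plus)
        method = "normal"
    return WilcoxonResult(statistic=w_plus, p_value=p, n_effective=n, method=method)


def format_p(p: float, eps: float = EPS_DISPLAY) -> str:
    return f"<{eps:g}" if p < eps else f"{p:.4g}"


def _angle_columns(pairs: Sequence[PosturePair], sensor: int, role: str) -> np.ndarray:
    snaps = [(p.t0 if role == "t0" else p.t1) for p in pairs]
    return np.array([s.angles[sensor] for s in snaps])


def _describe(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0], method="linear")
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "min": float(values.min()),
        "max": float(values.max()),
        "median": float(med),
        "iqr": float(q3 - q1),
    }


def descriptive_table(pairs: Sequence[PosturePair]) -> pd.DataFrame:
    """Per position / sensor / snapshot-role descriptive statistics (degrees).

    SD uses the n-1 denominator; the IQR percentile method matches the
    bundle percentiles (linear interpolation).  Values are kept at full
    precision; display rounding is the caller's concern.
    """
    rows = []
    for position in POSITIONS:
        subset = [p for p in pairs if p.position == position]
        if not subset:
            continue
        for sensor in range(N_SENSORS):
            for role in ("t0", "t1"):
                stats = _describe(_angle_columns(subset, sensor, role))
                rows.append(
                    {"position": position, "sensor": sensor + 1, "role": role, **stats}
                )
    return pd.DataFrame(rows, columns=["position", "sensor", "role", *_STAT_COLUMNS])


def wilcoxon_per_sensor(
    pairs: Sequence[PosturePair], alpha: float = 0.05, exact_threshold: int = 25
) -> pd.DataFrame:
    """Wilcoxon signed-rank test of t1 - t0 per position and sensor."""
    rows = []
    for position in POSITIONS:
        subset = [p for p in pairs if p.position == position]
        if not subset:
            continue
        for sensor in range(N_SENSORS):
            d = _angle_columns(subset, sensor, "t1") - _angle_columns(subset, sensor, "t0")
            res = wilcoxon_signed_rank(d, exact_threshold=exact_threshold)
            rows.append(
                {
                    "position": position,
                    "sensor": sensor + 1,
                    "n_pairs": len(subset),
                    "n_effective": res.n_effective,
                    "w_plus": res.statistic,
                    "p_value": res.p_value,
                    "p_display": format_p(res.p_value),
                    "method": res.method,
                    "significant": res.p_value < alpha,
                }
            )
    return pd.DataFrame(rows)


def angle_report(pairs: Sequence[PosturePair], alpha: float = 0.05) -> pd.DataFrame:
    """Wide per-sensor report: t0 and t1 descriptive stats plus significance star.

    One row per (position, sensor) with ``t0_``/``t1_``-prefixed statistics,
    mirroring the usual side-by-side presentation of before/after snapshots.
    """
    desc = descriptive_table(pairs)
    wil = wilcoxon_per_sensor(pairs, alpha=alpha)
    rows = []
    for (position, sensor), grp in desc.groupby(["position", "sensor"], sort=False):
        row: dict[str, object] = {"position": position, "sensor": sensor}
        for role in ("t0", "t1"):
            sub = grp[grp["role"] == role].iloc[0]
            for c in _STAT_COLUMNS:
                row[f"{role}_{c}"] = sub[c]
        wrow = wil[(wil["position"] == position) & (wil["sensor"] == sensor)].iloc[0]
        row["p_value"] = wrow["p_value"]
        row["p_display"] = wrow["p_display"]
        row["star"] = "*" if wrow["significant"] else ""
        rows.append(row)
    return pd.DataFrame(rows)
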