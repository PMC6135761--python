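"""Longitudinal stability statistics across days and probes.

Chronic recordings yield, per probe and per session day, an evoked dopamine
amplitude and a decay time.  Stability is assessed by (i) the slope and
Pearson correlation of each metric against days postimplant, with a
two-sided t-test of R against zero; (ii) standard scores (Z-scores) that
put probes with very different absolute amplitudes on a common scale;
(iii) monthly bins (months 1, 2, 3, and >3) summarizing the distribution
of detected concentrations over time; and (iv) unpaired two-tailed t-tests
and one-way ANOVA for comparisons across probes and animals.  No
multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProbeTimeSeries",
    "TrendResult",
    "fit_trend",
    "zscore_series",
    "monthly_bins",
    "compare_groups",
    "MONTH_BIN_EDGES_DAYS",
]

# Month bins: 30-day months; ">3 months" = day > 90.
MONTH_BIN_EDGES_DAYS = (0, 30, 60, 90)
MONTH_BIN_LABELS = ("month 1", "month 2", "month 3", ">3 months")


@dataclass
class ProbeTimeSeries:
    """Per-probe longitudinal record of evoked amplitude and decay time."""

    probe_id: str
    rat_id: str
    days: np.ndarray
    dda_nM: np.ndarray
    decay_ms: np.ndarray
    stim_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.dda_nM = np.asarray(self.dda_nM, dtype=float)
        self.decay_ms = np.asarray(self.decay_ms, dtype=float)
        n = len(self.days)
        if len(self.dda_nM) != n or len(self.decay_ms) != n:
            raise ValueError("days, dda_nM and decay_ms must be equal length")
        if np.any(self.days < 0):
            raise ValueError("days postimplant must be >= 0")
        if np.any(np.diff(self.days) < 0):
            raise ValueError("observations must be ordered by day")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, probe_id: str) -> "ProbeTimeSeries":
        """Build from a records table with columns
        (probe_id, rat_id, day, dDA_nM, decay_ms[, stim_id])."""
        sub = df[df["probe_id"] == probe_id].sort_values("day")
        if sub.empty:
            raise ValueError(f"no records for probe {probe_id!r}")
        return cls(
            probe_id=probe_id,
            rat_id=str(sub["rat_id"].iloc[0]),
            days=sub["day"].to_numpy(),
            dda_nM=sub["dDA_nM"].to_numpy(),
            decay_ms=sub["decay_ms"].to_numpy(),
            stim_id=sub["stim_id"].to_numpy() if "stim_id" in sub else None,
        )

    def metric(self, name: str) -> np.ndarray:
        if name == "dDA":
            return self.dda_nM
        if name == "decay":
            return self.decay_ms
        raise ValueError(f"unknown metric {name!r}; expected 'dDA' or 'decay'")


@dataclass
class TrendResult:
    """Line fit of a metric vs days postimplant, with its Pearson R test."""

    probe_id: str
    metric: str
    slope: float  # nM/day or ms/day
    intercept: float
    pearson_r: float  # NaN when undefined (constant metric)
    p_value: float  # two-sided, H0: R = 0, t with n-2 df; NaN if R undefined
    mean: float
    std: float  # sample SD (ddof=1)
    n: int

    @property
    def r_defined(self) -> bool:
        return not math.isnan(self.pearson_r)

    def summary(self) -> str:
        r = f"{self.pearson_r:.4f}" if self.r_defined else "undefined"
        p = f"{self.p_value:.4f}" if self.r_defined else "-"
        unit = "nM" if self.metric == "dDA" else "ms"
        return (
            f"probe {self.probe_id} [{self.metric}] n={self.n}: "
            f"mean {self.mean:.1f} {unit}, SD {self.std:.1f} {unit}, "
            f"trend {self.slope:+.3f} {unit}/day, R={r}, p={p}"
        )


def fit_trend(series: ProbeTimeSeries, metric: str = "dDA") -> TrendResult:
    """OLS trend of a longitudinal metric against days postimplant.

    Requires >= 3 observations on >= 2 distinct days.  A constant metric
    yields slope 0 with R and p undefined (NaN).
    """
    y = series.metric(metric)
    x = series.days
    if len(x) < 3:
        raise ValueError("trend fitting requires >= 3 observations")
    if len(np.unique(x)) < 2:
        raise ValueError("trend fitting requires >= 2 distinct days")
    mean = float(np.mean(y))
    std = float(np.std(y, ddof=1))
    if np.ptp(y) == 0:
        return TrendResult(
            probe_id=series.probe_id, metric=metric, slope=0.0,
            intercept=mean, pearson_r=float("nan"), p_value=float("nan"),
            mean=mean, std=std, n=len(x),
        )
    res = stats.linregress(x, y)
    return TrendResult(
        probe_id=series.probe_id,
        metric=metric,
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        mean=mean,
        std=std,
        n=len(x),
    )


def zscore_series(values: Sequence[float]) -> np.ndarray:
    """Standard scores (x - mean) / SD using the sample SD (ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("z-scores require >= 2 values")
    sd = np.std(v, ddof=1)
    if sd == 0:
        raise ValueError("z-scores undefined for zero-variance input")
    return (v - v.mean()) / sd


def monthly_bins(records: pd.DataFrame, metric: str = "dDA_nM") -> pd.DataFrame:
    """Summarize a metric by month postimplant across all probes.

    Bins are 30-day months (days 1-30, 31-60, 61-90) plus ">3 months"
    (day > 90).  Each present bin reports n, min, max, mean and a 95% CI
    half-width of exactly 1.96 x SEM; bins with a single record have an
    undefined CI (NaN) and empty bins are absent from the output.
    """
    if "day" not in records or metric not in records:
        raise ValueError(f"records must carry 'day' and {metric!r} columns")
    edges = list(MONTH_BIN_EDGES_DAYS) + [np.inf]
    labels = list(MONTH_BIN_LABELS)
    binned = pd.cut(records["day"], bins=edges, labels=labels, right=True)
    rows = []
    for label in labels:
        vals = records.loc[binned == label, metric].to_numpy(dtype=float)
        if vals.size == 0:
            continue
        if vals.size > 1:
            ci = 1.96 * np.std(vals, ddof=1) / np.sqrt(vals.size)
        else:
            ci = float("nan")
        rows.append(
            {
                "month_bin": label,
                "n": vals.size,
                "min": vals.min(),
                "max": vals.max(),
                "mean": vals.mean(),
                "ci95_half_width": ci,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    groups: Sequence[Sequence[float]], design: str = "two-sample"
) -> tuple[float, float]:
    """Unpaired two-tailed t-test or one-way ANOVA across metric groups.

    Returns ``(statistic, p_value)``: the t statistic for ``"two-sample"``
    (exactly two groups) or the F statistic for ``"oneway"``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    if design == "two-sample":
        if len(arrays) != 2:
            raise ValueError("two-sample design requires exactly 2 groups")
        res = stats.ttest_ind(arrays[0], arrays[1])
    elif design == "oneway":
        if len(arrays) < 2:
            raise ValueError("one-way ANOVA requires >= 2 groups")
        res = stats.f_oneway(*arrays)
    else:
        raise ValueError(f"unknown design {design!r}")
    return float(res.statistic), float(res.pvalue)


def trend_report(
    records: pd.DataFrame, metric: str = "dDA"
) -> pd.DataFrame:
    """Per-probe trend table (probe, rat, n, mean, SD, slope, R, p)."""
    rows = []
    for probe_id in records["probe_id"].unique():
        series = ProbeTimeSeries.from_dataframe(records, probe_id)
        t = fit_trend(series, metric)
        rows.append(
            {
                "probe_id": probe_id,
                "rat_id": series.rat_id,
                "n": t.n,
                "mean": t.mean,
                "std": t.std,
                "slope_per_day": t.slope,
                "pearson_r": t.pearson_r,
                "p_value": t.p_value,
            }
        )
    return pd.DataFrame(rows)
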