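"""Flash/continuous glucose monitoring summaries.

Implements the standard ambulatory glucose metrics: duration-weighted mean
and coefficient of variation, the time-in-range family (below 3.9 mmol/l,
within [3.9, 10], above 10) plus the additional 7.8 and 6.7 mmol/l
thresholds, and pooled daily (clock-time) percentile profiles.

Boundary conventions: "within 3.9 and 10" is the closed interval, "below"
and "above" are strict, so the three ranges exactly partition wear time.
Samples separated from their successor by more than ``max_gap_factor``
times the nominal interval contribute no wear time; percentages are always
quoted against valid wear time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CgmTrace", "CgmSummary", "summarize", "daily_profile"]

MGDL_PER_MMOL = 18.016


@dataclass
class CgmTrace:
    """Timestamped interstitial glucose series (mmol/l)."""

    times: np.ndarray  # datetime64[ns]
    glucose: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.times.shape != self.glucose.shape or self.times.ndim != 1:
            raise ValueError("times and glucose must be 1-d arrays of equal length")
        if np.any(np.diff(self.times).astype("timedelta64[ns]").astype(np.int64) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.glucose <= 0):
            raise ValueError("glucose must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, units: str = "mmol") -> "CgmTrace":
        g = df["glucose_mmol_l"].to_numpy(float) if units == "mmol" else (
            df.iloc[:, -1].to_numpy(float) / MGDL_PER_MMOL
        )
        return cls(times=pd.to_datetime(df["timestamp"]).to_numpy(), glucose=g)

    def to_frame(self, subject_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"timestamp": self.times, "glucose_mmol_l": self.glucose})
        if subject_id is not None:
            df.insert(0, "subject_id", subject_id)
        return df


@dataclass(frozen=True)
class CgmSummary:
    """Wear-time-weighted glucose summary; all time metrics in percent."""

    mean: float
    cv: float
    tbr_3_9: float
    tir_3_9_10: float
    tar_10: float
    t_above_7_8: float
    t_above_6_7: float
    wear_hours: float


def _durations_min(trace: CgmTrace, nominal_interval_min: float, max_gap_factor: float) -> np.ndarray:
    """Valid wear minutes attributed to each sample (left-sample convention)."""
    dt = np.diff(trace.times).astype("timedelta64[s]").astype(float) / 60.0
    dur = np.append(dt, nominal_interval_min)  # last sample carries one nominal interval
    dur[dur > max_gap_factor * nominal_interval_min] = 0.0  # gap: no wear time
    return dur


def summarize(
    trace: CgmTrace,
    nominal_interval_min: float = 15.0,
    max_gap_factor: float = 2.0,
    exclude_leading_hours: float = 0.0,
) -> CgmSummary:
    """Duration-weighted glucose summary over valid wear time.

    Requires at least 24 h of valid (non-gap) data. ``exclude_leading_hours``
    drops an optional sensor warm-up window at the start of the trace.
    CV is the population SD over the mean, in percent.
    """
    t, g = trace.times, trace.glucose
    if exclude_leading_hours > 0:
        keep = t >= t[0] + np.timedelta64(int(exclude_leading_hours * 3600), "s")
        t, g = t[keep], g[keep]
    sub = CgmTrace(t, g)
    w = _durations_min(sub, nominal_interval_min, max_gap_factor)
    wear_min = w.sum()
    if wear_min < 24 * 60:
        raise ValueError(
            f"insufficient CGM coverage: {wear_min/60:.1f} h of valid wear time, need >= 24 h"
        )
    mean = float(np.average(g, weights=w))
    sd = float(np.sqrt(np.average((g - mean) ** 2, weights=w)))

    def pct(mask: np.ndarray) -> float:
        return float(100.0 * w[mask].sum() / wear_min)

    return CgmSummary(
        mean=mean,
        cv=100.0 * sd / mean,
        tbr_3_9=pct(g < 3.9),
        tir_3_9_10=pct((g >= 3.9) & (g <= 10.0)),
        tar_10=pct(g > 10.0),
        t_above_7_8=pct(g > 7.8),
        t_above_6_7=pct(g > 6.7),
        wear_hours=wear_min / 60.0,
    )


def daily_profile(trace: CgmTrace, bin_minutes: int = 60) -> pd.DataFrame:
    """Pooled ambulatory daily profile: per clock-time bin median, 10th and
    90th percentiles across all monitored days.

    ``bin_minutes`` must divide 24 h; requires at least 3 days of data span.
    Returns a DataFrame indexed by bin start minute-of-day with columns
    median, p10, p90, n.
    """
    if (24 * 60) % bin_minutes != 0:
        raise ValueError("bin_minutes must divide 24 h")
    span_days = (trace.times[-1] - trace.times[0]) / np.timedelta64(1, "D")
    if span_days < 3:
        raise ValueError("daily profile requires at least 3 days of data")
    ts = pd.DatetimeIndex(trace.times)
    minute_of_day = ts.hour * 60 + ts.minute + ts.second / 60.0
    bin_start = (minute_of_day // bin_minutes).astype(int) * bin_minutes
    df = pd.DataFrame({"bin": bin_start, "glucose": trace.glucose})
    out = df.groupby("bin")["glucose"].agg(
        median="median",
        p10=lambda v: np.percentile(v, 10),
        p90=lambda v: np.percentile(v, 90),
        n="count",
    )
    out.index.name = "minute_of_day"
    return out
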