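"""Trace analysis: drift correction, relative ratios, and summaries.

Long recordings accumulate a slow photobleaching drift in the ratio
baseline.  The processing chain, in fixed order:

1. :func:`correct_drift` — fit a least-squares line to the pre-stimulus
   baseline samples only, extrapolate it over the whole trace, and
   remove it while preserving the baseline level.  Fitting through
   stimulus periods would absorb real signal, hence baseline-only.
2. :func:`relative_ratio` — express the trace as percent change
   100*(R - R0)/R0 with R0 the baseline-window mean.
3. :func:`median_filter5` — sliding five-point median, used for display
   and timepoint read-outs to suppress single-frame artifacts (transient
   focus loss).  Slopes are estimated on the unfiltered trace so the
   filter cannot bias them.

Timepoint metrics (:func:`timepoint_value`), windowed slopes
(:func:`estimate_slope`, percent/min) and group mean +/- SEM summaries
(:func:`group_summary`) implement the reported quantities.  Missing
samples (NaN from masked frames) are excluded from fits and means,
never interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import RatioTrace

__all__ = [
    "BaselineWindow",
    "RelativeTrace",
    "SlopeEstimate",
    "GroupTraceSummary",
    "correct_drift",
    "relative_ratio",
    "median_filter5",
    "timepoint_value",
    "estimate_slope",
    "group_summary",
]


@dataclass(frozen=True)
class BaselineWindow:
    """Pre-stimulus control window [start, end) in minutes.

    Conventionally 10 min long, ending at the first protocol event.
    """

    start_min: float
    end_min: float

    def __post_init__(self) -> None:
        if self.end_min <= self.start_min:
            raise ValueError("baseline window must have positive length")

    def mask(self, time_min: np.ndarray) -> np.ndarray:
        return (time_min >= self.start_min) & (time_min < self.end_min)

    @classmethod
    def before_event(cls, event_time_min: float, length_min: float = 10.0
                     ) -> "BaselineWindow":
        return cls(max(0.0, event_time_min - length_min), event_time_min)


@dataclass
class RelativeTrace:
    """Baseline-normalized trace in percent: 100*(R - R0)/R0."""

    cell_id: str
    time_min: np.ndarray
    value_pct: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.value_pct = np.asarray(self.value_pct, dtype=float)
        if self.time_min.shape != self.value_pct.shape:
            raise ValueError("time and value arrays must align")


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS slope over a post-event window, in percent/min."""

    value_pct_per_min: float
    window_min: tuple[float, float]
    n_points: int
    residual_se: float


@dataclass
class GroupTraceSummary:
    """Per-timepoint mean, SEM and n over a group of cells."""

    time_min: np.ndarray
    mean_pct: np.ndarray
    sem_pct: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_min": self.time_min, "mean_pct": self.mean_pct,
            "sem_pct": self.sem_pct, "n": self.n,
        })


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _baseline_samples(trace_t: np.ndarray, trace_v: np.ndarray,
                      baseline: BaselineWindow, min_samples: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    if baseline.start_min < trace_t[0] - 1e-9 or baseline.end_min > trace_t[-1] + 1e-9:
        raise ValueError("baseline window lies outside the trace support")
    sel = baseline.mask(trace_t) & np.isfinite(trace_v)
    if sel.sum() < min_samples:
        raise ValueError(
            f"need at least {min_samples} finite baseline samples, got {int(sel.sum())}"
        )
    return trace_t[sel], trace_v[sel]


def correct_drift(trace: RatioTrace, baseline: BaselineWindow) -> RatioTrace:
    """Remove the baseline's linear drift from the whole trace.

    A least-squares line is fitted to the baseline samples only,
    extrapolated over the full recording and subtracted; the baseline
    mean is added back so the baseline level (hence R0) is preserved
    while its slope is removed.  Any post-event step riding on the drift
    is preserved exactly.
    """
    tb, vb = _baseline_samples(trace.time_min, trace.R, baseline, min_samples=5)
    slope, intercept = np.polyfit(tb, vb, 1)
    fitted = slope * trace.time_min + intercept
    corrected = trace.R - fitted + vb.mean()
    return RatioTrace(cell_id=trace.cell_id, time_min=trace.time_min.copy(),
                      R=corrected)


def relative_ratio(trace: RatioTrace, baseline: BaselineWindow) -> RelativeTrace:
    """Percent change relative to the baseline-window mean ratio R0."""
    _, vb = _baseline_samples(trace.time_min, trace.R, baseline, min_samples=1)
    r0 = vb.mean()
    if r0 <= 0:
        raise ValueError("baseline mean ratio must be positive")
    return RelativeTrace(
        cell_id=trace.cell_id,
        time_min=trace.time_min.copy(),
        value_pct=100.0 * (trace.R - r0) / r0,
    )


def median_filter5(trace: RelativeTrace) -> RelativeTrace:
    """Centered sliding five-point median.

    The window shrinks symmetrically at the edges (3-point at the second
    and second-to-last samples, passthrough at the endpoints), so a
    constant trace is unchanged and no out-of-range padding is invented.
    NaN samples stay NaN and are ignored inside windows.
    """
    v = trace.value_pct
    n = len(v)
    out = np.empty(n)
    for i in range(n):
        half = min(2, i, n - 1 - i)
        window = v[i - half : i + half + 1]
        finite = window[np.isfinite(window)]
        out[i] = np.nan if not np.isfinite(v[i]) else (
            np.median(finite) if finite.size else np.nan
        )
    return RelativeTrace(cell_id=trace.cell_id, time_min=trace.time_min.copy(),
                         value_pct=out)


def timepoint_value(trace: RelativeTrace, t_after_event_min: float,
                    event_time_min: float) -> float:
    """Trace value at the sample nearest to event + t (earlier sample
    wins a tie)."""
    target = event_time_min + t_after_event_min
    if target < trace.time_min[0] - 1e-9 or target > trace.time_min[-1] + 1e-9:
        raise ValueError("requested timepoint lies outside the trace")
    dist = np.abs(trace.time_min - target)
    # stable argmin returns the first (earlier) index on exact ties
    return float(trace.value_pct[int(np.argmin(dist))])


def estimate_slope(trace: RelativeTrace, window_after_event_min: tuple[float, float],
                   event_time_min: float) -> SlopeEstimate:
    """OLS slope (percent/min) over a window after the event.

    Computed on the (drift-corrected, unfiltered) relative trace;
    requires at least 3 finite samples in the window; endpoints
    inclusive.
    """
    w0, w1 = window_after_event_min
    if w1 <= w0:
        raise ValueError("slope window must have positive length")
    t0, t1 = event_time_min + w0, event_time_min + w1
    sel = (trace.time_min >= t0 - 1e-9) & (trace.time_min <= t1 + 1e-9)
    sel &= np.isfinite(trace.value_pct)
    npts = int(sel.sum())
    if npts < 3:
        raise ValueError("need at least 3 samples in the slope window")
    tt, vv = trace.time_min[sel], trace.value_pct[sel]
    slope, intercept = np.polyfit(tt, vv, 1)
    resid = vv - (slope * tt + intercept)
    dof = npts - 2
    rse = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else np.nan
    return SlopeEstimate(value_pct_per_min=float(slope),
                         window_min=(w0, w1), n_points=npts, residual_se=rse)


def group_summary(traces: list[RelativeTrace]) -> GroupTraceSummary:
    """Per-timepoint mean and SEM (sd/sqrt(n)) across cells.

    All traces must share one time grid; cells with a missing (NaN)
    value at a timepoint drop out of that timepoint's statistics.
    """
    if len(traces) < 2:
        raise ValueError("need at least two traces to summarize")
    t0 = traces[0].time_min
    for tr in traces[1:]:
        if tr.time_min.shape != t0.shape or not np.allclose(tr.time_min, t0):
            raise ValueError("traces must share a common time grid")
    values = np.vstack([tr.value_pct for tr in traces])
    n = np.isfinite(values).sum(axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=0)
        sd = np.nanstd(values, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    return GroupTraceSummary(time_min=t0.copy(), mean_pct=mean, sem_pct=sem, n=n)
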