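"""Device-verification arm: onset-based lag estimation.

Traces are up-sampled to 1000 Hz by linear interpolation followed by a
zero-phase moving-average smoother, onsets are detected as the first sample
exceeding 10% of that trace's own maximum, the per-trial lag is the onset
difference between the horizontal and vertical channels (positive =
vertical leads), lags are averaged per lag condition, and commanded vs
measured condition means are compared with a Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .device import TrialRecording
from .traces import ForceTrace

__all__ = [
    "OnsetResult",
    "LagCorrelationResult",
    "upsample_trace",
    "detect_onset",
    "trial_lag",
    "condition_means",
    "correlate_lags",
    "analyze_recording_set",
]

DEFAULT_UPSAMPLE_RATE = 1000.0
DEFAULT_SMOOTH_WINDOW = 11  # samples at 1000 Hz, i.e. 11 ms
DEFAULT_ONSET_FRACTION = 0.10


@dataclass(frozen=True)
class OnsetResult:
    """Threshold crossing of one trace: time, level and trace maximum."""

    onset_time: float
    threshold_level: float
    max_amplitude: float


@dataclass(frozen=True)
class LagCorrelationResult:
    """Commanded vs measured per-condition lags with their linear fit."""

    per_condition_target: np.ndarray
    per_condition_actual_mean: np.ndarray
    per_condition_actual_se: np.ndarray
    r: float
    p: float
    slope: float
    intercept: float


def upsample_trace(
    trace: ForceTrace,
    target_rate: float = DEFAULT_UPSAMPLE_RATE,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> ForceTrace:
    """Linear interpolation onto the target grid plus zero-phase smoothing.

    The moving-average window is in output samples, must be odd, and is
    applied with reflected boundaries so endpoints are preserved for
    constant traces and no phase shift is introduced.
    """
    if target_rate < trace.sample_rate:
        raise ValueError("target_rate must be >= the input sample rate")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd sample count")
    n_out = int(round(trace.duration * target_rate)) + 1
    t_out = trace.t0 + np.arange(n_out) / target_rate
    vals = np.interp(t_out, trace.times, trace.values)
    if smooth_window > 1:
        vals = uniform_filter1d(vals, size=smooth_window, mode="reflect")
    return ForceTrace(target_rate, vals, trace.t0)


def detect_onset(
    trace: ForceTrace, threshold_fraction: float = DEFAULT_ONSET_FRACTION
) -> OnsetResult:
    """First instant the signal strictly exceeds a fraction of its maximum.

    The threshold is relative to the trace's own maximum, so onsets are
    invariant to positive rescaling.  Raises if the trace has no positive
    excursion.
    """
    if not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    vmax = float(np.max(trace.values))
    if vmax <= 0:
        raise ValueError("trace has no positive maximum: onset undefined")
    level = threshold_fraction * vmax
    above = trace.values > level
    if not above.any():  # pragma: no cover - level < vmax guarantees a hit
        raise ValueError("no sample exceeds the onset threshold")
    idx = int(np.argmax(above))
    return OnsetResult(
        onset_time=float(trace.t0 + idx / trace.sample_rate),
        threshold_level=level,
        max_amplitude=vmax,
    )


def trial_lag(
    rec: TrialRecording,
    which: str = "measured",
    upsample_rate: float = DEFAULT_UPSAMPLE_RATE,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    threshold_fraction: float = DEFAULT_ONSET_FRACTION,
) -> float:
    """Onset lag (ms) between channels at the target or measured stage.

    lag = onset(horizontal) - onset(vertical), so positive lags mean the
    vertical stimulation led, matching the commanded-lag sign convention.
    """
    if which == "target":
        v, h = rec.target_v, rec.target_h
    elif which == "measured":
        v, h = rec.measured_v, rec.measured_h
    else:
        raise ValueError("which must be 'target' or 'measured'")
    onset_v = detect_onset(upsample_trace(v, upsample_rate, smooth_window), threshold_fraction)
    onset_h = detect_onset(upsample_trace(h, upsample_rate, smooth_window), threshold_fraction)
    return (onset_h.onset_time - onset_v.onset_time) * 1000.0


def condition_means(
    trials: Iterable[tuple[int, float]],
    expected_lags: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Mean and standard error of measured lags per lag condition.

    ``trials`` yields (commanded lag ms, measured lag ms) pairs.  The result
    is ordered by commanded lag with columns ``lag_ms``, ``mean_ms``,
    ``se_ms``, ``n``.  Every condition must have at least two trials; if
    ``expected_lags`` is given, a missing condition raises an error naming
    it.
    """
    df = pd.DataFrame(list(trials), columns=["lag_ms", "measured_ms"])
    if expected_lags is not None:
        missing = sorted(set(expected_lags) - set(df["lag_ms"].unique()))
        if missing:
            raise ValueError(f"missing lag conditions: {missing}")
    grouped = df.groupby("lag_ms")["measured_ms"]
    counts = grouped.count()
    if (counts < 2).any():
        bad = sorted(counts[counts < 2].index.tolist())
        raise ValueError(f"conditions with fewer than 2 trials: {bad}")
    out = pd.DataFrame(
        {
            "lag_ms": counts.index.to_numpy(),
            "mean_ms": grouped.mean().to_numpy(),
            "se_ms": (grouped.std(ddof=1) / np.sqrt(counts)).to_numpy(),
            "n": counts.to_numpy(),
        }
    ).sort_values("lag_ms", ignore_index=True)
    return out


def correlate_lags(
    target: Sequence[float], actual: Sequence[float], se: Sequence[float] | None = None
) -> LagCorrelationResult:
    """Pearson correlation and regression line of commanded vs measured lags."""
    x = np.asarray(target, dtype=float)
    y = np.asarray(actual, dtype=float)
    if x.size != y.size:
        raise ValueError("target and actual must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 conditions to correlate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    se_arr = (
        np.asarray(se, dtype=float) if se is not None else np.full(x.size, np.nan)
    )
    return LagCorrelationResult(
        per_condition_target=x,
        per_condition_actual_mean=y,
        per_condition_actual_se=se_arr,
        r=float(r),
        p=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def analyze_recording_set(
    recordings: Iterable[TrialRecording],
    which: str = "measured",
    upsample_rate: float = DEFAULT_UPSAMPLE_RATE,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    threshold_fraction: float = DEFAULT_ONSET_FRACTION,
) -> tuple[pd.DataFrame, pd.DataFrame, LagCorrelationResult]:
    """Full verification pipeline over a set of trial recordings.

    Returns (per-trial lags, per-condition summary, correlation result).
    The correlation is computed on the per-condition means, mirroring how
    the device's lag accuracy is summarized.
    """
    rows = []
    for i, rec in enumerate(recordings, start=1):
        rows.append(
            {
                "trial_id": i,
                "lag_ms": rec.commanded_lag,
                "lag_ms_target_stage": trial_lag(
                    rec, "target", upsample_rate, smooth_window, threshold_fraction
                ),
                "lag_ms_motor_stage": trial_lag(
                    rec, which, upsample_rate, smooth_window, threshold_fraction
                )
                if which != "target"
                else np.nan,
            }
        )
    per_trial = pd.DataFrame(rows)
    stage_col = "lag_ms_motor_stage" if which != "target" else "lag_ms_target_stage"
    cond = condition_means(
        zip(per_trial["lag_ms"], per_trial[stage_col])
    )
    corr = correlate_lags(cond["lag_ms"], cond["mean_ms"], cond["se_ms"])
    return per_trial, cond, corr
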