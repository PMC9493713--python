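"""Strike-level event detection, trial alignment, and summary statistics.

Gape is operationalized as the 3D distance between anterior jaw-tip
landmarks.  Strike onset and jaw close bracket the gape excursion at a
configurable fraction of its peak; all peak times are also expressed in
milliseconds relative to peak gape (negative = before).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, NoStrikeError


def gape_series(upper_tip: np.ndarray, lower_tip: np.ndarray) -> np.ndarray:
    """Per-frame 3D distance between the jaw-tip landmark trajectories (cm)."""
    u = np.asarray(upper_tip, dtype=float)
    l = np.asarray(lower_tip, dtype=float)
    if u.shape != l.shape:
        raise ConfigError("jaw-tip trajectories must match in shape")
    return np.linalg.norm(u - l, axis=1)


@dataclass
class StrikeEvents:
    """Frame indices and relative timings of the strike landmarks.

    ``peaks`` maps channel name -> frame of first extremum (largest absolute
    excursion from zero); ``peak_times_ms`` holds the same events in ms
    relative to peak gape.
    """

    fps: float
    onset_frame: int
    peak_gape_frame: int
    jaw_close_frame: int | None
    peaks: dict[str, int] = field(default_factory=dict)
    peak_times_ms: dict[str, float] = field(default_factory=dict)

    @property
    def time_to_peak_gape_ms(self) -> float:
        return (self.peak_gape_frame - self.onset_frame) / self.fps * 1000.0

    @property
    def strike_duration_ms(self) -> float | None:
        if self.jaw_close_frame is None:
            return None
        return (self.jaw_close_frame - self.onset_frame) / self.fps * 1000.0

    def rel_ms(self, frame: int) -> float:
        return (frame - self.peak_gape_frame) / self.fps * 1000.0


def _first_extremum(series: np.ndarray) -> int:
    """First frame attaining the largest absolute excursion from zero."""
    x = np.asarray(series, dtype=float)
    target = np.nanmax(np.abs(x))
    return int(np.argmax(np.abs(x) >= target - 1e-12))


def detect_events(
    gape: np.ndarray,
    channels: dict[str, np.ndarray] | None = None,
    fps: float = 500.0,
    threshold: float = 0.05,
    baseline: float | None = None,
) -> StrikeEvents:
    """Locate strike onset, peak gape, jaw close, and per-channel peaks.

    Onset is the last frame before the gape excursion exceeds
    ``threshold * (peak - baseline)``; jaw close is the first frame after
    peak gape back below that level (None if the trial ends open).  Ties at
    a plateaued maximum resolve to the first frame.  ``channels`` should be
    zeroed and filtered upstream.
    """
    if not (0 < threshold < 0.5):
        raise ConfigError("threshold fraction must be in (0, 0.5)")
    g = np.asarray(gape, dtype=float)
    if baseline is None:
        baseline = float(g[0])
    exc = g - baseline
    peak_exc = float(np.max(exc))
    if peak_exc <= 0:
        raise NoStrikeError("gape never exceeds baseline")
    level = threshold * peak_exc
    above = exc > level
    if not above.any():
        raise NoStrikeError("no excursion above threshold")
    first_above = int(np.argmax(above))
    onset = max(first_above - 1, 0)
    # first frame attaining the max (plateau tie-break: first frame)
    peak_frame = int(np.argmax(exc >= peak_exc - 1e-12))
    after = np.nonzero(~above[peak_frame:])[0]
    close = int(peak_frame + after[0]) if len(after) else None

    events = StrikeEvents(
        fps=fps, onset_frame=onset, peak_gape_frame=peak_frame,
        jaw_close_frame=close,
    )
    for name, series in (channels or {}).items():
        f = _first_extremum(np.asarray(series, dtype=float))
        events.peaks[name] = f
        events.peak_times_ms[name] = events.rel_ms(f)
    return events


@dataclass
class EnsembleSummary:
    """Trial-aligned mean +/- s.e.m. time series (time 0 at peak gape)."""

    time_ms: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray  # trials covering each time point
    single_trial: bool


def align_and_average(
    trials: list[np.ndarray], events: list[StrikeEvents], fps: float
) -> EnsembleSummary:
    """Resample trials onto a common grid centred at peak gape and average.

    Each trial contributes only over its own recorded span (no
    extrapolation); s.e.m. = sample std / sqrt(n) per time point, 0 where a
    single trial covers the point.
    """
    if not trials or len(trials) != len(events):
        raise ConfigError("need matching non-empty trials and events")
    rel_times = [
        (np.arange(len(tr)) - ev.peak_gape_frame) / fps * 1000.0
        for tr, ev in zip(trials, events)
    ]
    t_lo = min(rt[0] for rt in rel_times)
    t_hi = max(rt[-1] for rt in rel_times)
    step = 1000.0 / fps
    grid = np.arange(t_lo, t_hi + step / 2, step)
    stack = np.full((len(trials), len(grid)), np.nan)
    for i, (tr, rt) in enumerate(zip(trials, rel_times)):
        inside = (grid >= rt[0] - 1e-9) & (grid <= rt[-1] + 1e-9)
        stack[i, inside] = np.interp(grid[inside], rt, np.asarray(tr, dtype=float))
    n = np.sum(np.isfinite(stack), axis=0)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # ddof on n=1 slices
        mean = np.nanmean(stack, axis=0)
        std = np.nanstd(stack, axis=0, ddof=1)
    sem = np.where(n > 1, std / np.sqrt(np.maximum(n, 1)), 0.0)
    return EnsembleSummary(
        time_ms=grid, mean=mean, sem=sem, n=n, single_trial=len(trials) == 1
    )


def summarize_trials(trial_variables: list[dict[str, float]]) -> pd.DataFrame:
    """Mean +/- s.e.m. per kinematic variable across trials.

    ``trial_variables`` holds one dict per trial (variable name -> value);
    the output table has columns mean, sem, n per variable.
    """
    if not trial_variables:
        raise ConfigError("need at least one trial")
    df = pd.DataFrame(trial_variables)
    mean = df.mean()
    n = df.count()
    sem = df.std(ddof=1) / np.sqrt(n)
    sem = sem.where(n > 1, 0.0)
    return pd.DataFrame({"mean": mean, "sem": sem, "n": n})


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def body_length_regression(records: pd.DataFrame) -> RegressionResult:
    """OLS of time to peak gape (ms) on body length (mm) across species.

    ``records`` needs columns ``body_length_mm`` and ``time_to_peak_gape_ms``
    (extra columns such as species or prey type are ignored).
    """
    required = {"body_length_mm", "time_to_peak_gape_ms"}
    if not required.issubset(records.columns):
        raise ConfigError(f"records must have columns {sorted(required)}")
    x = records["body_length_mm"].to_numpy(dtype=float)
    y = records["time_to_peak_gape_ms"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ConfigError("need >=3 records")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ConfigError("lengths and times must be positive")
    if np.ptp(x) == 0:
        raise ConfigError("constant body length: slope undefined")
    if np.ptp(y) == 0:
        # flat response: slope 0 with no variance explained
        return RegressionResult(slope=0.0, intercept=float(y[0]),
                                r_squared=0.0, p_value=1.0, n=len(x))
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
    )
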