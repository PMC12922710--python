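"""Fixational eye-motion traces: curation flags and drift statistics.

Traces are time-stamped retinal positions (ms, arcmin) sampled at the
native registration rate (nominally 864 Hz).  Because fine-scale samples
carry registration jitter, all drift statistics are computed on the trace
down-sampled to the video frame rate (27 Hz, one position per frame taken
at the frame's temporal center by linear interpolation).

Statistics follow the conventions of AOSLO micro-psychophysics:

* retinal slip: sum of the lengths of the successive frame-to-frame
  displacement vectors over the stimulus-on frames,
* mean drift velocity: slip divided by the elapsed time between the first
  and last stimulus-on frame,
* MSD: per-trial squared displacement from the position at stimulus onset
  as a function of lag; drift variance is the across-trial variance of the
  MSD curves at a reference lag (600 ms),
* microsaccade flag: instantaneous speed of the smoothed native-rate trace
  exceeding 30 arcmin/s anywhere in the stimulus window.

Single-frame (~3 ms) presentations are assumed to have zero slip.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import DegenerateInputError, GapError, OutOfDomainError


@dataclass
class DriftTrace:
    """Retinal position samples for one trial."""

    t_ms: np.ndarray          # strictly increasing
    xy_arcmin: np.ndarray     # (n, 2)
    valid: np.ndarray | None = None
    rate_hz: float = 864.0
    frame_rate_hz: float = 27.0
    stimulus_window: tuple | None = None  # (onset_ms, offset_ms)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, float)
        self.xy_arcmin = np.asarray(self.xy_arcmin, float)
        if self.valid is None:
            self.valid = np.ones(len(self.t_ms), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, bool)
        if np.any(np.diff(self.t_ms) <= 0):
            raise DegenerateInputError("timestamps must be strictly increasing")
        if self.stimulus_window is not None:
            on, off = self.stimulus_window
            if on < self.t_ms[0] - 1e-9 or off > self.t_ms[-1] + 1e-9:
                raise DegenerateInputError("stimulus window outside trace extent")

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz


def read_trace_csv(path, **kwargs) -> DriftTrace:
    """Read a trace CSV with columns ``t_ms,x_arcmin,y_arcmin,valid``."""
    df = pd.read_csv(path)
    return DriftTrace(df["t_ms"].to_numpy(),
                      df[["x_arcmin", "y_arcmin"]].to_numpy(),
                      valid=df["valid"].to_numpy(bool), **kwargs)


def write_trace_csv(trace: DriftTrace, path) -> None:
    pd.DataFrame({"t_ms": trace.t_ms,
                  "x_arcmin": trace.xy_arcmin[:, 0],
                  "y_arcmin": trace.xy_arcmin[:, 1],
                  "valid": trace.valid.astype(int)}).to_csv(path, index=False)


def frame_centers(trace: DriftTrace) -> np.ndarray:
    """Temporal centers (ms) of the video frames overlapping the trace."""
    T = trace.frame_period_ms
    t0, t1 = trace.t_ms[0], trace.t_ms[-1]
    first = int(np.floor(t0 / T))
    last = int(np.ceil(t1 / T))
    centers = (np.arange(first, last + 1) + 0.5) * T
    return centers[(centers >= t0) & (centers <= t1)]


def downsample(trace: DriftTrace) -> DriftTrace:
    """One position per video frame, linearly interpolated at the frame's
    temporal center between the nearest native samples."""
    centers = frame_centers(trace)
    if len(centers) < 1:
        raise DegenerateInputError("trace shorter than one frame")
    T = trace.frame_period_ms
    # every frame center must have a native sample within one frame period
    nearest = np.min(np.abs(trace.t_ms[None, :] - centers[:, None]), axis=1)
    if np.any(nearest > T):
        raise GapError("video frame with no native samples within one period")
    x = np.interp(centers, trace.t_ms, trace.xy_arcmin[:, 0])
    y = np.interp(centers, trace.t_ms, trace.xy_arcmin[:, 1])
    # a frame is valid only if all native samples within it are valid
    valid = np.array([trace.valid[np.abs(trace.t_ms - c) <= T / 2].all()
                      if np.any(np.abs(trace.t_ms - c) <= T / 2) else True
                      for c in centers])
    return replace(trace, t_ms=centers, xy_arcmin=np.column_stack([x, y]),
                   valid=valid, rate_hz=trace.frame_rate_hz)


def _window_slice(trace: DriftTrace, pad_ms: float = 0.0) -> np.ndarray:
    if trace.stimulus_window is None:
        raise DegenerateInputError("stimulus window not set")
    on, off = trace.stimulus_window
    if off <= on:
        raise DegenerateInputError("empty stimulus window")
    return (trace.t_ms >= on - pad_ms) & (trace.t_ms <= off + pad_ms)


def flag_microsaccade(trace: DriftTrace, v_max: float = 30.0,
                      smooth_ms: float = 15.0) -> bool:
    """True iff smoothed native-rate speed exceeds ``v_max`` (arcmin/s)
    anywhere within the stimulus window.

    The native trace is smoothed with a moving average of ``smooth_ms``
    (suppresses registration jitter while resolving ~20-ms saccadic
    events) before finite differencing.
    """
    sel = _window_slice(trace)
    win = max(1, int(round(trace.rate_hz * smooth_ms / 1000.0)))
    xs = uniform_filter1d(trace.xy_arcmin[:, 0], win, mode="nearest")
    ys = uniform_filter1d(trace.xy_arcmin[:, 1], win, mode="nearest")
    dt_s = np.diff(trace.t_ms) / 1000.0
    speed = np.hypot(np.diff(xs), np.diff(ys)) / dt_s
    in_win = sel[:-1] | sel[1:]
    return bool(np.any(speed[in_win] > v_max))


def flag_blink(trace: DriftTrace) -> bool:
    """True iff any sample within the stimulus window is invalid (dropout)."""
    sel = _window_slice(trace)
    return bool(np.any(~trace.valid[sel]))


def slip_length(frame_xy: np.ndarray) -> float:
    """Retinal slip (arcmin): sum of successive displacement-vector norms
    over the stimulus-on frame positions.  A single-frame presentation has
    zero slip by definition."""
    frame_xy = np.asarray(frame_xy, float)
    if len(frame_xy) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(frame_xy, axis=0), axis=1).sum())


def mean_velocity(frame_xy: np.ndarray, frame_period_ms: float) -> float:
    """Mean drift velocity (arcmin/s): slip over elapsed time between the
    first and last on-frame centers.  NaN for single-frame trials."""
    n = len(frame_xy)
    if n < 2:
        return float("nan")
    return slip_length(frame_xy) / ((n - 1) * frame_period_ms / 1000.0)


def msd_curve(frame_xy: np.ndarray, frame_period_ms: float):
    """Squared displacement from the first (onset-frame) position at each
    lag.  Returns ``(lags_ms, sq_disp_arcmin2)``; MSD(0) = 0."""
    frame_xy = np.asarray(frame_xy, float)
    disp = frame_xy - frame_xy[0]
    sq = (disp**2).sum(axis=1)
    lags = np.arange(len(frame_xy)) * frame_period_ms
    return lags, sq


def drift_variance(curves: list, t_ref_ms: float = 600.0) -> float:
    """Across-trial (sample, n-1) variance of the MSD curves at ``t_ref``.

    Each element of ``curves`` is ``(lags_ms, msd)``; values are linearly
    interpolated at the reference lag.
    """
    if len(curves) < 2:
        raise DegenerateInputError("need >= 2 trials for drift variance")
    vals = []
    for lags, m in curves:
        if t_ref_ms > lags[-1] + 1e-9:
            raise OutOfDomainError(
                f"t_ref {t_ref_ms} ms beyond trial extent {lags[-1]:.1f} ms")
        vals.append(np.interp(t_ref_ms, lags, m))
    return float(np.var(vals, ddof=1))
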