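"""Three-stage ΔF/F preprocessing and supra-threshold Ca²⁺ event detection.

The ΔF/F computation mirrors the single-channel fiber-photometry
pipeline common to CCD-based acquisition systems:

1. F_AVG(t)      — mean of F_RAW over a trailing sliding window
                   (default 0.75 s, current frame included).
2. F_BASELINE(t) — minimum of F_AVG over the window (default 3 s)
                   strictly preceding the frame; then
                   ΔF/F(t) = (F_RAW(t) - F_BASELINE(t)) / F_BASELINE(t).
3. Smoothing     — exponentially weighted moving average over a trailing
                   window of width w (default 1 s) with weights
                   ∝ exp(-Δt/τ), τ = 0.2 s by default, normalized to
                   sum 1 over the frames available.

Both windows are causal (trailing); frames without a full baseline
history are NaN and stay NaN through smoothing.  A centered variant of
the stage-1 mean is available behind ``DffParams.centered_avg``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .synthetic import RawTrace


def _n_frames_lt(window_s: float, fps: float) -> int:
    """Number of integer frame offsets k >= 0 with k/fps < window_s."""
    return int(math.ceil(window_s * fps - 1e-9))


def _n_frames_le(window_s: float, fps: float) -> int:
    """Number of integer frame offsets k >= 1 with k/fps <= window_s."""
    return int(math.floor(window_s * fps + 1e-9))


@dataclass(frozen=True)
class DffParams:
    """ΔF/F pipeline parameters (seconds)."""

    avg_window_s: float = 0.75
    baseline_window_s: float = 3.0
    tau_s: float = 0.2
    smooth_width_s: float = 1.0
    centered_avg: bool = False

    def __post_init__(self) -> None:
        for name in ("avg_window_s", "baseline_window_s", "tau_s",
                     "smooth_width_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.baseline_window_s < self.avg_window_s:
            raise ValueError("baseline_window_s must be >= avg_window_s")


@dataclass
class DffTrace:
    """Per-frame ΔF/F with optional pipeline intermediates.

    ``dff`` is the smoothed trace; ``dff_unsmoothed`` the stage-2 output.
    Warm-up frames (no full baseline window) are NaN.
    """

    fps: float
    dff: np.ndarray
    params: DffParams
    dff_unsmoothed: np.ndarray | None = None
    f_avg: np.ndarray | None = None
    f_baseline: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.dff)

    @property
    def duration_s(self) -> float:
        return len(self.dff) / self.fps


@dataclass(frozen=True)
class CaEvent:
    """Maximal run of frames with ΔF/F at/above the detection threshold."""

    onset_frame: int
    duration_s: float
    peak_dff: float


@dataclass(frozen=True)
class EventSummary:
    n_events: int
    frequency_per_min: float
    mean_duration_s: float  # NaN when there are no events


def compute_dff(raw: RawTrace, params: DffParams | None = None,
                keep_intermediates: bool = True,
                smooth: bool = True) -> DffTrace:
    """Run the three-stage ΔF/F pipeline on a raw fluorescence trace."""
    if params is None:
        params = DffParams()
    x = np.asarray(raw.values, dtype=float)
    if x.ndim != 1 or len(x) < 1:
        raise ValueError("raw trace must be a non-empty 1-D array")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("non-positive fluorescence")
    fps = raw.fps
    n = len(x)
    n_avg = _n_frames_lt(params.avg_window_s, fps)
    n_base = _n_frames_le(params.baseline_window_s, fps)
    if n <= n_base:
        raise ValueError(
            f"trace ({n} frames) shorter than baseline window ({n_base} frames)")

    # stage 1: sliding mean
    f_avg = np.full(n, np.nan)
    if params.centered_avg:
        half = n_avg // 2
        width = 2 * half + 1
        if n >= width:
            f_avg[half:n - half] = sliding_window_view(x, width).mean(axis=-1)
    else:
        f_avg[n_avg - 1:] = sliding_window_view(x, n_avg).mean(axis=-1)

    # stage 2: preceding-window minimum baseline, then ratio
    f_base = np.full(n, np.nan)
    f_base[n_base:] = sliding_window_view(f_avg, n_base).min(axis=-1)[:n - n_base]
    dff_raw = (x - f_base) / f_base

    if smooth:
        dff = _ewma_trailing(dff_raw, fps, params.tau_s, params.smooth_width_s)
    else:
        dff = dff_raw.copy()

    return DffTrace(
        fps=fps, dff=dff, params=params,
        dff_unsmoothed=dff_raw if keep_intermediates else None,
        f_avg=f_avg if keep_intermediates else None,
        f_baseline=f_base if keep_intermediates else None)


def _ewma_trailing(x: np.ndarray, fps: float, tau_s: float,
                   width_s: float) -> np.ndarray:
    """Exponentially weighted trailing moving average, NaN-aware.

    Weights exp(-(k/fps)/τ) for lags k = 0..n_w-1 are renormalized over
    the non-NaN frames in each window; all-NaN windows stay NaN, so the
    warm-up region is preserved without extending it.
    """
    n = len(x)
    n_w = _n_frames_lt(width_s, fps)
    w = np.exp(-(np.arange(n_w) / fps) / tau_s)
    w_rev = w[::-1]  # window rows run oldest -> current
    pad = np.concatenate([np.full(n_w - 1, np.nan), x])
    win = sliding_window_view(pad, n_w)
    finite = np.isfinite(win)
    num = np.nansum(win * w_rev, axis=-1)
    den = finite @ w_rev
    out = np.full(n, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def detect_events(dff: DffTrace | np.ndarray, threshold: float = 0.02,
                  fps: float | None = None) -> list[CaEvent]:
    """Detect Ca²⁺ events: maximal runs of frames with ΔF/F >= threshold.

    NaN frames (warm-up) break runs and never belong to an event.  The
    default 2% criterion is applied to the smoothed trace.
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    if isinstance(dff, DffTrace):
        x, fps = dff.dff, dff.fps
    else:
        x = np.asarray(dff, dtype=float)
        if fps is None:
            raise ValueError("fps required when passing a bare array")
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("all-NaN ΔF/F trace")
    above = finite & (x >= threshold)
    padded = np.concatenate([[False], above, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [CaEvent(onset_frame=int(s),
                    duration_s=float((e - s) / fps),
                    peak_dff=float(np.max(x[s:e])))
            for s, e in zip(starts, ends)]


def summarize_events(events: Sequence[CaEvent],
                     trace_duration_s: float) -> EventSummary:
    """Events/minute and mean event duration over the recording."""
    if not trace_duration_s > 0:
        raise ValueError("trace_duration_s must be > 0")
    n = len(events)
    freq = n / (trace_duration_s / 60.0)
    mean_dur = float(np.mean([e.duration_s for e in events])) if n else math.nan
    return EventSummary(n_events=n, frequency_per_min=freq,
                        mean_duration_s=mean_dur)
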