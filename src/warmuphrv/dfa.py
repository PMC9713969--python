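"""Detrended Fluctuation Analysis: the short-term scaling exponent alpha-1.

The RR series is integrated after mean subtraction, the profile is split
into non-overlapping boxes of n beats, a least-squares line is removed in
each box, and the root-mean-square residual F(n) is measured.  The slope of
log10 F(n) against log10 n over box sizes 4-16 beats is alpha-1:
roughly 0.5 for uncorrelated series, 1.0 for 1/f (fractal) series and 1.5
for strongly correlated, Brownian-like series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from warmuphrv.errors import DegenerateSignalError, InsufficientDataError, ParameterError
from warmuphrv.rr_core import RRSeries, mean_heart_rate


@dataclass(frozen=True)
class FluctuationFunction:
    """RMS fluctuation per box size, in ms."""

    n_values: np.ndarray
    F: np.ndarray

    def __post_init__(self):
        n_values = np.asarray(self.n_values, dtype=int)
        F = np.asarray(self.F, dtype=float)
        if n_values.size != F.size:
            raise ParameterError("n_values and F must have equal length")
        if n_values.size and np.any(np.diff(n_values) <= 0):
            raise ParameterError("n_values must be strictly increasing")
        object.__setattr__(self, "n_values", n_values)
        object.__setattr__(self, "F", F)


@dataclass(frozen=True)
class DFAConfig:
    """Box-size range and validity settings for alpha-1.

    ``min_beats`` guards against unstable slopes from very short windows;
    the default of 100 is comfortably exceeded by a 2-minute segment at
    warm-up heart rates (~120-150 bpm gives 240-300 beats).
    """

    n_min: int = 4
    n_max: int = 16
    min_beats: int = 100

    def __post_init__(self):
        if not (4 <= self.n_min < self.n_max):
            raise ParameterError("require 4 <= n_min < n_max")
        if self.min_beats <= 2 * self.n_max:
            raise ParameterError("min_beats must exceed 2 * n_max")


@dataclass(frozen=True)
class DFAResult:
    alpha1: float
    fluct: FluctuationFunction
    n_beats: int
    window_range: tuple[int, int]
    mean_hr: float
    meta: dict = field(default_factory=dict)


def integrate_profile(intervals: np.ndarray) -> np.ndarray:
    """Cumulative sum of mean-subtracted intervals (the DFA profile)."""
    x = np.asarray(intervals, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("profile needs at least 2 intervals")
    return np.cumsum(x - x.mean())


def fluctuation(profile: np.ndarray, n: int) -> float:
    """RMS residual around per-box linear fits at box size ``n``.

    The profile is split into floor(N/n) consecutive boxes from the start;
    beats beyond the last full box are discarded.  F(n) is the RMS of the
    residuals pooled over all covered points.
    """
    y = np.asarray(profile, dtype=float)
    N = y.size
    if n < 2 or 2 * n > N:
        raise ParameterError(f"box size {n} invalid for profile of length {N}")
    n_boxes = N // n
    boxes = y[: n_boxes * n].reshape(n_boxes, n)
    t = np.arange(n, dtype=float)
    t_mean = t.mean()
    t_var = ((t - t_mean) ** 2).sum()
    box_means = boxes.mean(axis=1)
    slopes = ((t - t_mean) * (boxes - box_means[:, None])).sum(axis=1) / t_var
    fits = box_means[:, None] + slopes[:, None] * (t - t_mean)
    resid = boxes - fits
    return float(np.sqrt(np.mean(resid**2)))


def alpha1(series: RRSeries, cfg: DFAConfig | None = None) -> DFAResult:
    """Short-term scaling exponent over box sizes ``n_min``..``n_max``.

    F(n) is computed at every integer box size in the range and alpha-1 is
    the unweighted least-squares slope of log10 F against log10 n.
    """
    cfg = cfg or DFAConfig()
    n_beats = series.n_beats
    if n_beats < cfg.min_beats:
        raise InsufficientDataError(
            f"alpha-1 needs at least {cfg.min_beats} beats, got {n_beats}"
        )
    profile = integrate_profile(series.intervals)
    n_values = np.arange(cfg.n_min, cfg.n_max + 1)
    F = np.array([fluctuation(profile, int(n)) for n in n_values])
    if np.any(F <= 0):
        raise DegenerateSignalError("zero fluctuation at some box size; no slope defined")
    slope = np.polyfit(np.log10(n_values), np.log10(F), 1)[0]
    return DFAResult(
        alpha1=float(slope),
        fluct=FluctuationFunction(n_values=n_values, F=F),
        n_beats=n_beats,
        window_range=(cfg.n_min, cfg.n_max),
        mean_hr=mean_heart_rate(series),
        meta=dict(series.meta),
    )


def rolling_alpha1(
    series: RRSeries,
    window_s: float = 120.0,
    step_s: float = 15.0,
    cfg: DFAConfig | None = None,
) -> list[tuple[float, float]]:
    """alpha-1 over a trailing window, re-evaluated every ``step_s`` seconds.

    Returns (window-end time, alpha1) pairs; windows with too few beats (or
    degenerate fluctuation) yield NaN rather than raising, so a monitoring
    loop can keep running through dropouts.
    """
    cfg = cfg or DFAConfig()
    if step_s <= 0 or window_s <= 0:
        raise ParameterError("window_s and step_s must be positive")
    t = series.t_cum
    duration = series.duration_s
    out: list[tuple[float, float]] = []
    end = window_s
    while end <= duration + 1e-9:
        mask = (t >= end - window_s) & (t < end)
        sub = series.with_intervals(series.intervals[mask])
        if sub.n_beats < cfg.min_beats:
            out.append((end, float("nan")))
        else:
            try:
                out.append((end, alpha1(sub, cfg).alpha1))
            except DegenerateSignalError:
                out.append((end, float("nan")))
        end += step_s
    if not out:
        # recording shorter than one window: single missing marker
        out.append((duration, float("nan")))
    return out
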