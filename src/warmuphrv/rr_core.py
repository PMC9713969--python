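"""RR-interval series: reading, artifact correction, detrending, segmenting.

The raw signal is the ordered sequence of beat-to-beat (RR) intervals in
milliseconds.  Before the fractal exponent is computed the series is cleaned
(ectopic/missed/extra beats replaced by spline interpolation), the analysis
window is cut out of the recording, and the slow trend is removed with a
smoothness-priors (regularized second-difference) smoother.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import CubicSpline

from warmuphrv.errors import (
    CoverageError,
    EmptyInputError,
    FormatError,
    InsufficientDataError,
    ParameterError,
)

#: Physiological plausibility window for a corrected RR interval, ms.
PLAUSIBLE_RR_MS = (200.0, 3000.0)


@dataclass(frozen=True)
class RRSeries:
    """Ordered beat-to-beat intervals in milliseconds.

    ``t_cum`` (seconds) is derived: ``t_cum[k]`` is the cumulative time of
    the end of beat ``k`` since the start of the recording.
    """

    intervals: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1:
            raise ParameterError("intervals must be one-dimensional")
        if arr.size and not np.all(arr > 0):
            raise ParameterError("all RR intervals must be positive")
        object.__setattr__(self, "intervals", arr)

    @property
    def t_cum(self) -> np.ndarray:
        """Cumulative occurrence time (s) of each beat end."""
        return np.cumsum(self.intervals) / 1000.0

    @property
    def duration_s(self) -> float:
        return float(self.intervals.sum() / 1000.0)

    @property
    def n_beats(self) -> int:
        return int(self.intervals.size)

    def with_intervals(self, intervals: np.ndarray) -> "RRSeries":
        return replace(self, intervals=np.asarray(intervals, dtype=float))


@dataclass(frozen=True)
class ArtifactReport:
    """Outcome of artifact screening on one series."""

    flags: np.ndarray  # per-beat: True where suspect
    corrected_count: int
    percent_corrected: float
    excluded: bool


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing settings for one analysis.

    lambda_sp
        Smoothness-priors regularization (dimensionless); higher values
        remove slower trends only.
    artifact_threshold_pct
        Recordings whose corrected-beat percentage exceeds this are excluded
        from analysis (subject-level screening).
    segment_start_s / segment_end_s
        Half-open analysis window [start, end) in seconds from recording
        start; the default keeps minute 7 through minute 8 of a 10-minute
        warm-up.
    artifact_c
        Multiplier on the rolling quartile deviation of successive RR
        differences used as detection threshold.
    artifact_window_beats
        Width (beats) of the rolling window for the time-varying threshold.
    """

    lambda_sp: float = 500.0
    artifact_threshold_pct: float = 5.0
    segment_start_s: float = 360.0
    segment_end_s: float = 480.0
    plausible_rr_ms: tuple[float, float] = PLAUSIBLE_RR_MS
    artifact_c: float = 5.2
    artifact_window_beats: int = 91

    def __post_init__(self):
        if self.lambda_sp <= 0:
            raise ParameterError("lambda_sp must be positive")
        if self.segment_end_s <= self.segment_start_s:
            raise ParameterError("segment_end_s must exceed segment_start_s")


def read_rr(path: str | Path, dialect: str = "plain_ms", meta: dict | None = None) -> RRSeries:
    """Read an RR series from a text file.

    dialect ``plain_ms``: one interval in ms per line, ``#`` comments and
    blank lines ignored.  dialect ``csv_time_ms``: header plus two columns,
    cumulative time in s and interval in ms; intervals are taken from the
    second column and cumulative time is re-derived from them.
    """
    path = Path(path)
    text = path.read_text()
    meta = dict(meta or {})
    meta.setdefault("source", path.name)

    lines = text.splitlines()
    values: list[float] = []
    if dialect == "plain_ms":
        for lineno, raw in enumerate(lines, start=1):
            entry = raw.split("#", 1)[0].strip()
            if not entry:
                continue
            try:
                values.append(float(entry))
            except ValueError:
                raise FormatError(f"{path}: unparsable RR value at line {lineno}: {raw!r}")
    elif dialect == "csv_time_ms":
        content = [(i, ln.strip()) for i, ln in enumerate(lines, start=1) if ln.strip()]
        if not content:
            raise EmptyInputError(f"{path}: empty file")
        header_line, rest = content[0], content[1:]
        if any(ch.isdigit() for ch in header_line[1].split(",")[0]):
            raise FormatError(f"{path}: header row required for csv_time_ms")
        for lineno, raw in rest:
            parts = raw.split(",")
            if len(parts) < 2:
                raise FormatError(f"{path}: expected two columns at line {lineno}")
            try:
                values.append(float(parts[1]))
            except ValueError:
                raise FormatError(f"{path}: unparsable RR value at line {lineno}: {raw!r}")
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")

    if not values:
        raise EmptyInputError(f"{path}: no RR intervals found")
    if len(values) < 2:
        raise InsufficientDataError(f"{path}: need at least 2 intervals, got {len(values)}")
    return RRSeries(intervals=np.array(values, dtype=float), meta=meta)


def _rolling_quartile_deviation(x: np.ndarray, window: int) -> np.ndarray:
    """Rolling (Q3-Q1)/2 of ``x`` in a centered window, edges clamped."""
    n = x.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        q1, q3 = np.percentile(x[lo:hi], [25, 75])
        out[i] = (q3 - q1) / 2.0
    return out


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    n = x.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def detect_and_correct_artifacts(
    series: RRSeries, cfg: PreprocessConfig | None = None
) -> tuple[RRSeries, ArtifactReport]:
    """Flag aberrant beats and replace them by cubic-spline interpolation.

    A beat is suspect when its deviation from the local (11-beat) median
    exceeds ``c`` times the rolling quartile deviation of the successive
    RR differences — a time-varying threshold that adapts to the local HRV
    level, so ectopic beats, merged (missed) beats and spurious extra
    detections are caught without flagging ordinary variability.  Suspect
    beats are replaced by a cubic spline through the surrounding normal
    beats; the input series is not modified.
    """
    cfg = cfg or PreprocessConfig()
    rr = series.intervals
    n = rr.size
    if n < 10:
        raise InsufficientDataError(f"artifact correction needs >= 10 beats, got {n}")

    drr = np.diff(rr)
    qd = _rolling_quartile_deviation(drr, cfg.artifact_window_beats)
    # Floor the threshold so metronomic (near-zero-variability) stretches do
    # not flag everything; 20 ms is far below any genuine ectopic deviation.
    thresh = np.maximum(cfg.artifact_c * qd, 20.0)
    thresh_per_beat = np.empty(n)
    thresh_per_beat[0] = thresh[0]
    thresh_per_beat[1:] = thresh

    local_med = _rolling_median(rr, 11)
    dev = np.abs(rr - local_med)
    lo, hi = cfg.plausible_rr_ms
    flags = (dev > thresh_per_beat) | (rr < lo) | (rr > hi)

    corrected = rr.copy()
    count = int(flags.sum())
    if count and count < n - 1:
        idx = np.arange(n)
        good = ~flags
        spline = CubicSpline(idx[good], rr[good])
        corrected[flags] = spline(idx[flags])
        corrected = np.clip(corrected, lo, hi)

    pct = 100.0 * count / n
    report = ArtifactReport(
        flags=flags,
        corrected_count=count,
        percent_corrected=pct,
        excluded=pct > cfg.artifact_threshold_pct,
    )
    return series.with_intervals(corrected), report


def smoothness_priors_detrend(series: RRSeries, lambda_sp: float = 500.0) -> RRSeries:
    """Remove the slow trend with a smoothness-priors smoother.

    The trend is ``(I + lambda^2 D2' D2)^-1 z`` where ``D2`` is the
    (N-2) x N second-difference operator; the detrended series is
    ``z - trend`` with the original mean re-added, so mean heart rate is
    unchanged while DFA (which is mean-invariant) sees the detrended
    fluctuations.
    """
    if lambda_sp <= 0:
        raise ParameterError("lambda_sp must be positive")
    z = series.intervals
    n = z.size
    if n < 3:
        raise InsufficientDataError(f"detrending needs >= 3 beats, got {n}")

    d2 = sp.diags_array([1.0, -2.0, 1.0], offsets=[0, 1, 2], shape=(n - 2, n), format="csc")
    a = sp.eye_array(n, format="csc") + (lambda_sp**2) * (d2.T @ d2)
    trend = spla.spsolve(a, z)
    detrended = z - trend + z.mean()
    return series.with_intervals(detrended)


def extract_segment(series: RRSeries, start_s: float, end_s: float) -> RRSeries:
    """Keep beats whose end time falls in the half-open window [start, end).

    Interval values are preserved bit-exactly; the returned series is
    re-zeroed (its cumulative time starts from the first retained beat).
    """
    if end_s <= start_s:
        raise ParameterError(f"segment end ({end_s}) must exceed start ({start_s})")
    duration = series.duration_s
    if end_s - duration > 1e-6:
        raise CoverageError(
            f"recording spans {duration:.1f} s, shorter than requested end {end_s:.1f} s"
        )
    t = series.t_cum
    mask = (t >= start_s) & (t < end_s)
    return series.with_intervals(series.intervals[mask])


def mean_heart_rate(series: RRSeries) -> float:
    """Mean heart rate in bpm: 60000 divided by the mean RR interval (ms)."""
    if series.n_beats == 0:
        raise EmptyInputError("cannot compute heart rate of an empty series")
    return 60000.0 / float(series.intervals.mean())
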