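"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators, plus the packaged 11-triathlete study fixture:

* fractal RR series with a target short-term scaling exponent, produced by
  spectral synthesis of power-law (1/f^beta) Gaussian noise with
  beta = 2*alpha1 - 1 (alpha1 0.5 -> white noise, 1.0 -> pink, 1.5 ->
  Brownian-like);
* artifact injection (ectopic, missed, extra beats) with ground-truth
  positions, conserving total recording time;
* paired PRE/POST cohorts from the additive measurement model
  value = mu + participant effect + true change (POST only) + noise,
  whose noise SD is, by construction, the typical error the estimator
  should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from warmuphrv.cohort_stats import DEFAULT_REGISTRY, CohortTable
from warmuphrv.errors import ParameterError
from warmuphrv.rr_core import PLAUSIBLE_RR_MS, RRSeries


@dataclass(frozen=True)
class FractalRRSpec:
    """Target properties of a generated RR series."""

    target_alpha1: float = 1.0
    n_beats: int = 1000
    mean_rr: float = 450.0  # warm-up intensity (~133 bpm), as in the study cohort
    sd_rr: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.sd_rr <= 0:
            raise ParameterError("sd_rr must be positive")
        if self.n_beats < 64:
            raise ParameterError("n_beats must be >= 64")


@dataclass(frozen=True)
class VariableSpec:
    """Measurement model for one cohort variable."""

    mean: float
    between_sd: float
    noise_sd: float  # equals the typical error by construction
    delta_light: float = 0.0
    delta_heavy: float = 0.0
    var_class: str = "physiological_or_psychometric"


@dataclass(frozen=True)
class CohortSpec:
    """Paired-cohort generator settings.

    Defaults mirror the study's DFA alpha-1 conditions: 11 athletes, a
    between-subject SD of 0.24, measurement noise of 0.18 (the typical
    error), no true change after the light session and a -0.28 true change
    after the heavy one.
    """

    n_participants: int = 11
    variables: dict[str, VariableSpec] = field(
        default_factory=lambda: {
            "dfa_a1": VariableSpec(
                mean=1.0, between_sd=0.24, noise_sd=0.18,
                delta_light=0.0, delta_heavy=-0.28,
            )
        }
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 0:
            raise ParameterError("n_participants must be >= 0")
        for name, v in self.variables.items():
            if v.between_sd < 0 or v.noise_sd < 0:
                raise ParameterError(f"{name}: SDs must be >= 0")


def generate_fractal_rr(spec: FractalRRSpec) -> RRSeries:
    """Spectral synthesis of an RR series with a target scaling exponent.

    A Gaussian spectrum with power proportional to f^(-beta),
    beta = 2*target_alpha1 - 1, is given random phases and inverse-FFT'd,
    then rescaled to the requested mean/SD and clipped to the plausibility
    window.  Deterministic per seed.  The alpha1 <-> beta mapping is
    asymptotic, so estimates recover the target only to within the
    stochastic tolerance of a finite series.
    """
    if not (0.5 <= spec.target_alpha1 <= 1.5):
        import warnings

        warnings.warn(
            f"target_alpha1={spec.target_alpha1} outside [0.5, 1.5]; "
            "the spectral mapping is approximate there",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_beats
    beta = 2.0 * spec.target_alpha1 - 1.0
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    nonzero = freqs > 0
    amp[nonzero] = freqs[nonzero] ** (-beta / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = spectrum[-1].real
    x = np.fft.irfft(spectrum, n=n)
    x = (x - x.mean()) / x.std()
    rr = spec.mean_rr + spec.sd_rr * x
    rr = np.clip(rr, *PLAUSIBLE_RR_MS)
    return RRSeries(
        intervals=rr,
        meta={"generator": "spectral", "target_alpha1": spec.target_alpha1, "seed": spec.seed},
    )


def inject_artifacts(
    series: RRSeries,
    kinds: tuple[str, ...] = ("ectopic",),
    rate: float = 0.02,
    seed: int = 0,
) -> tuple[RRSeries, list[int]]:
    """Inject beat-detection artifacts; returns the series and truth indices.

    ``rate`` is the fraction of beats used as artifact events.  Per event:
    ectopic shortens beat k by 40% and lengthens k+1 by the same amount;
    missed merges beats k and k+1 into one; extra splits beat k in two.
    Total recording time is conserved exactly.  Truth indices refer to the
    returned series and cover every beat an event touched.
    """
    if not 0 <= rate <= 0.2:
        raise ParameterError("rate must be in [0, 0.2]")
    for k in kinds:
        if k not in ("ectopic", "missed", "extra"):
            raise ParameterError(f"unknown artifact kind {k!r}")
    rng = np.random.default_rng(seed)
    rr = series.intervals.copy()
    n = rr.size
    n_events = int(round(rate * n))
    if n_events == 0:
        return series.with_intervals(rr), []

    # choose non-overlapping event anchors with a one-beat guard band,
    # away from the edges so splines have neighbors on both sides
    candidates = np.arange(3, n - 3)
    rng.shuffle(candidates)
    anchors: list[int] = []
    taken = np.zeros(n, dtype=bool)
    for c in candidates:
        if taken[c - 2 : c + 3].any():
            continue
        anchors.append(int(c))
        taken[c - 1 : c + 2] = True
        if len(anchors) == n_events:
            break
    if len(anchors) < n_events:
        raise ParameterError(
            f"cannot place {n_events} non-overlapping artifacts in {n} beats"
        )
    event_kinds = rng.choice(list(kinds), size=n_events)

    # apply from the end so earlier anchor indices stay valid under
    # insertions/deletions; record per-event output index offsets afterwards
    events = sorted(zip(anchors, event_kinds), key=lambda e: -e[0])
    out = list(rr)
    truth_raw: list[tuple[int, str]] = []
    for k, kind in events:
        if kind == "ectopic":
            shift = 0.4 * out[k]
            out[k] -= shift
            out[k + 1] += shift
            truth_raw.append((k, kind))
        elif kind == "missed":
            merged = out[k] + out[k + 1]
            out[k : k + 2] = [merged]
            truth_raw.append((k, kind))
        else:  # extra
            half = out[k] / 2.0
            out[k : k + 1] = [half, half]
            truth_raw.append((k, kind))

    # map anchors (applied descending, so offsets from later events are 0)
    truth: list[int] = []
    offset = 0
    for k, kind in sorted(truth_raw, key=lambda e: e[0]):
        if kind == "ectopic":
            truth.extend([k + offset, k + 1 + offset])
        elif kind == "missed":
            truth.append(k + offset)
            offset -= 1
        else:
            truth.extend([k + offset, k + 1 + offset])
            offset += 1
    return series.with_intervals(np.array(out)), sorted(truth)


def generate_cohort(spec: CohortSpec, registry: dict | None = None) -> CohortTable:
    """Paired PRE/POST cohort from the additive measurement model."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for name, v in spec.variables.items():
        b = rng.normal(0.0, v.between_sd, size=spec.n_participants)
        for i in range(spec.n_participants):
            pid = i + 1
            for session, delta in (("light", v.delta_light), ("heavy", v.delta_heavy)):
                for occasion in ("PRE", "POST"):
                    value = (
                        v.mean
                        + b[i]
                        + (delta if occasion == "POST" else 0.0)
                        + rng.normal(0.0, v.noise_sd)
                    )
                    rows.append((pid, session, occasion, name, value))
    df = pd.DataFrame(
        rows, columns=["participant", "session", "occasion", "variable", "value"]
    )
    if registry is None:
        registry = {
            name: {"units": "", "class": v.var_class}
            for name, v in spec.variables.items()
        }
    return CohortTable(data=df, registry=registry)


def study_fixture() -> CohortTable:
    """The packaged 11-triathlete cohort (individual values as published):
    PRE/POST light and heavy sessions, 8 monitoring variables plus RPE,
    with participant 11's jump/tap measurements missing in the heavy
    session."""
    with resources.files("warmuphrv.data").joinpath("tables3_4.csv").open() as f:
        df = pd.read_csv(f)
    table = CohortTable(data=df, registry=dict(DEFAULT_REGISTRY))
    table.validate()
    return table
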