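"""Monitoring statistics for paired PRE/POST cohort measurements.

Implements the reliability-and-inference toolkit used to judge whether a
measured change in an athlete's monitoring variable is real and worthwhile:

* reference statistics — typical error (TE), coefficient of variation (CV)
  and smallest worthwhile change (SWC) from repeated-baseline data;
* paired PRE/POST comparisons with a Shapiro-Wilk normality gate selecting
  a paired t-test or a Wilcoxon signed-rank test, 90% confidence intervals,
  and standardized effect sizes (Cohen's dz, or r = |z|/sqrt(n));
* group magnitude-based inference (MBI): the chances that the true mean
  change is substantially negative / trivial / substantially positive
  relative to +-SWC, from a Student-t sampling distribution of the mean
  change;
* individual change inference: the same chance triplet for one athlete's
  change score, using a normal distribution whose SD is sqrt(2)*TE.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from warmuphrv.errors import ParameterError, SchemaError, WarmupHRVError

SESSIONS = ("light", "heavy")
OCCASIONS = ("PRE", "POST")

#: Default variable registry: units, SWC class and (optionally) a forced
#: test choice overriding the normality gate.  Performance measures use the
#: 0.3 x CV x mean rule for SWC; physiological and psychometric measures
#: use 0.5 x CV x mean.
DEFAULT_REGISTRY: dict[str, dict] = {
    "rec": {"units": "0-6", "class": "physiological_or_psychometric"},
    "stress": {"units": "0-6", "class": "physiological_or_psychometric"},
    "dfa_a1": {"units": "", "class": "physiological_or_psychometric"},
    "hr": {"units": "bpm", "class": "physiological_or_psychometric"},
    "cmjh": {"units": "cm", "class": "performance"},
    "cmjf": {"units": "N/kg", "class": "performance"},
    "ftc": {"units": "contacts", "class": "performance"},
    "ftf": {"units": "Hz", "class": "performance"},
    "rpe": {
        "units": "0-10",
        "class": "physiological_or_psychometric",
        # recorded once per session (after training): analyzed as a
        # heavy-vs-light contrast, not PRE/POST; an ordinal category-ratio
        # scale, so the signed-rank test is used regardless of the gate
        "session_contrast": True,
        "skip_reference": True,
        "forced_test": "wilcoxon",
    },
}

SWC_FACTORS = {"performance": 0.3, "physiological_or_psychometric": 0.5}

#: Probability scale for qualitative descriptors (percent chances).
PROBABILITY_SCALE = (
    (0.5, "most unlikely"),
    (5.0, "very unlikely"),
    (25.0, "unlikely"),
    (75.0, "possibly"),
    (95.0, "likely"),
    (99.5, "very likely"),
    (100.0001, "most likely"),
)

EFFECT_DESCRIPTORS = ((0.2, "trivial"), (0.5, "small"), (0.8, "moderate"), (np.inf, "large"))


def _probability_word(pct: float) -> str:
    for bound, word in PROBABILITY_SCALE:
        if pct < bound:
            return word
    return "most likely"


def _effect_descriptor(es: float) -> str:
    a = abs(es)
    for bound, word in EFFECT_DESCRIPTORS:
        if a < bound:
            return word
    return "large"


@dataclass(frozen=True)
class CohortTable:
    """Long-format participant x session x occasion x variable measurements."""

    data: pd.DataFrame
    registry: dict[str, dict] = field(default_factory=lambda: dict(DEFAULT_REGISTRY))

    REQUIRED_COLUMNS = ("participant", "session", "occasion", "variable", "value")

    def __post_init__(self):
        df = self.data
        missing = [c for c in self.REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort table missing columns: {missing}")

    def validate(self) -> None:
        """Raise SchemaError listing every violation with its coordinates."""
        df = self.data
        violations: list[str] = []
        bad_session = df.loc[~df["session"].isin(SESSIONS)]
        for _, row in bad_session.iterrows():
            violations.append(
                f"participant={row['participant']} variable={row['variable']}: "
                f"unknown session {row['session']!r}"
            )
        bad_occ = df.loc[~df["occasion"].isin(OCCASIONS)]
        for _, row in bad_occ.iterrows():
            violations.append(
                f"participant={row['participant']} variable={row['variable']}: "
                f"unknown occasion {row['occasion']!r}"
            )
        keys = df[["participant", "session", "occasion", "variable"]]
        dup = keys[keys.duplicated(keep=False)].drop_duplicates()
        for _, row in dup.iterrows():
            violations.append(
                "duplicate key participant={participant} session={session} "
                "occasion={occasion} variable={variable}".format(**row)
            )
        if violations:
            raise SchemaError(
                f"{len(violations)} schema violation(s)", violations=violations
            )

    def variables(self) -> list[str]:
        return sorted(self.data["variable"].unique())

    def values(self, variable: str, session: str, occasion: str) -> pd.Series:
        df = self.data
        sel = df[
            (df["variable"] == variable)
            & (df["session"] == session)
            & (df["occasion"] == occasion)
        ]
        return sel.set_index("participant")["value"].astype(float)

    def paired_values(
        self, variable: str, session: str
    ) -> tuple[pd.Series, pd.Series]:
        """PRE and POST values aligned on participant (pairwise deletion)."""
        pre = self.values(variable, session, "PRE")
        post = self.values(variable, session, "POST")
        common = pre.index.intersection(post.index)
        return pre.loc[common], post.loc[common]

    @classmethod
    def from_csv(cls, path: str | Path, registry: dict | None = None) -> "CohortTable":
        df = pd.read_csv(path)
        table = cls(data=df, registry=dict(registry or DEFAULT_REGISTRY))
        table.validate()
        return table

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class ReferenceStats:
    """Per-variable reliability references, in the variable's own units."""

    variable: str
    te: float
    cv_pct: float
    swc: float
    n: int


@dataclass(frozen=True)
class PairedComparison:
    variable: str
    session: str
    n: int
    mean_diff: float
    sd_diff: float
    ci90: tuple[float, float]
    p_value: float
    effect_size: float
    effect_kind: str  # cohen_dz | rank_r
    test_used: str  # paired_t | wilcoxon
    descriptor: str


@dataclass(frozen=True)
class GroupMBI:
    chances: tuple[float, float, float]  # negative, trivial, positive (%)
    descriptor: str
    clinical: str

    @property
    def display(self) -> str:
        neg, triv, pos = (int(round(c)) for c in self.chances)
        return f"{neg:02d}/{triv:02d}/{pos:02d}"


@dataclass(frozen=True)
class IndividualChange:
    participant: object
    session: str
    delta: float
    ci50: tuple[float, float]
    chances: tuple[float, float, float]
    descriptor: str


# ---------------------------------------------------------------------------
# reference statistics


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def reference_stats(
    cohort: CohortTable, variable: str, var_class: str | None = None
) -> ReferenceStats:
    """TE, CV and SWC for one variable from the repeated-baseline design.

    CV = 100 * SD/mean over the PRE values of the light session; SWC is the
    class factor (0.3 performance, 0.5 physiological/psychometric) times
    CV/100 times the PRE-light mean — algebraically factor * SD.  TE is the
    SD of the per-participant PRE-light minus PRE-heavy differences divided
    by sqrt(2), the two baselines acting as a test-retest pair.
    """
    if variable not in cohort.data["variable"].values:
        raise WarmupHRVError(f"unknown variable {variable!r}")
    if var_class is None:
        var_class = cohort.registry.get(variable, {}).get(
            "class", "physiological_or_psychometric"
        )
    if var_class not in SWC_FACTORS:
        raise ParameterError(f"unknown variable class {var_class!r}")

    pre_light = cohort.values(variable, "light", "PRE")
    pre_heavy = cohort.values(variable, "heavy", "PRE")
    common = pre_light.index.intersection(pre_heavy.index)
    if len(common) < 3:
        raise WarmupHRVError(
            f"{variable}: need >= 3 paired PRE values across sessions, got {len(common)}"
        )
    diffs = (pre_light.loc[common] - pre_heavy.loc[common]).to_numpy()
    te = _sd(diffs) / math.sqrt(2.0)

    baseline = pre_light.to_numpy()
    mean = float(baseline.mean())
    sd = _sd(baseline)
    cv = 100.0 * sd / mean if mean != 0 else 0.0
    swc = SWC_FACTORS[var_class] * (cv / 100.0) * mean if mean != 0 else SWC_FACTORS[var_class] * sd
    return ReferenceStats(variable=variable, te=te, cv_pct=cv, swc=swc, n=len(common))


def build_reference_table(cohort: CohortTable) -> dict[str, ReferenceStats]:
    """Reference statistics for every registered variable present in the data."""
    out: dict[str, ReferenceStats] = {}
    for variable in cohort.variables():
        entry = cohort.registry.get(variable, {})
        if entry.get("skip_reference"):
            continue
        try:
            out[variable] = reference_stats(cohort, variable, entry.get("class"))
        except WarmupHRVError:
            continue
    return out


# ---------------------------------------------------------------------------
# paired comparisons


def _wilcoxon_exact_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p via a generating-function DP.

    Midranks are doubled so tied ranks stay integral; the null distribution
    of W+ is built by convolving (1 + x^(2r)) over all ranks, which is valid
    under ties (unlike the tie-free closed form).
    """
    ranks = stats.rankdata(np.abs(diffs))
    w_pos = float(ranks[diffs > 0].sum())
    doubled = np.round(2 * ranks).astype(int)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = pmf + shifted
    pmf /= pmf.sum()
    w2 = int(round(2 * w_pos))
    cdf = pmf[: w2 + 1].sum()
    sf = pmf[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def _wilcoxon(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided p and rank-biserial-style effect size r = |z| / sqrt(n).

    z is the plain normal approximation of W+ with no tie or continuity
    correction; p is exact (sign-flip enumeration via DP) when n <= 25 and
    there are no zero differences, else from the same z.
    """
    d = diffs[diffs != 0]
    n = d.size
    if n == 0:
        return float("nan"), float("nan")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (w_pos - mu) / sigma
    if n <= 25 and diffs.size == n:
        p = _wilcoxon_exact_p(d)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    r = abs(z) / math.sqrt(n)
    return p, r


def _compare_paired(
    diffs: np.ndarray, variable: str, session: str, forced_test: str | None = None
) -> PairedComparison:
    n = diffs.size
    if n < 3:
        raise WarmupHRVError(f"{variable}/{session}: need >= 3 complete pairs, got {n}")
    mean_diff = float(diffs.mean())
    sd_diff = _sd(diffs)
    se = sd_diff / math.sqrt(n)
    tcrit = stats.t.ppf(0.95, df=n - 1)
    ci90 = (mean_diff - tcrit * se, mean_diff + tcrit * se)

    if sd_diff == 0:
        return PairedComparison(
            variable=variable, session=session, n=n, mean_diff=mean_diff,
            sd_diff=0.0, ci90=(mean_diff, mean_diff), p_value=float("nan"),
            effect_size=float("nan"), effect_kind="cohen_dz",
            test_used="degenerate", descriptor="trivial",
        )

    if forced_test is not None:
        test = forced_test
    else:
        sw_p = stats.shapiro(diffs).pvalue
        test = "paired_t" if sw_p > 0.05 else "wilcoxon"

    if test == "paired_t":
        tstat = mean_diff / se
        p = float(2.0 * stats.t.sf(abs(tstat), df=n - 1))
        es = mean_diff / sd_diff
        kind = "cohen_dz"
    elif test == "wilcoxon":
        p, es = _wilcoxon(diffs)
        kind = "rank_r"
    else:
        raise ParameterError(f"unknown test {forced_test!r}")

    return PairedComparison(
        variable=variable, session=session, n=n, mean_diff=mean_diff,
        sd_diff=sd_diff, ci90=ci90, p_value=p, effect_size=float(es),
        effect_kind=kind, test_used=test, descriptor=_effect_descriptor(es),
    )


def paired_comparison(cohort: CohortTable, variable: str, session: str) -> PairedComparison:
    """POST minus PRE comparison of one variable within one session."""
    pre, post = cohort.paired_values(variable, session)
    diffs = (post - pre).to_numpy(dtype=float)
    forced = cohort.registry.get(variable, {}).get("forced_test")
    return _compare_paired(diffs, variable, session, forced)


def session_contrast(
    cohort: CohortTable, variable: str = "rpe", occasion: str = "POST"
) -> PairedComparison:
    """Heavy-minus-light paired contrast for a once-per-session variable."""
    light = cohort.values(variable, "light", occasion)
    heavy = cohort.values(variable, "heavy", occasion)
    common = light.index.intersection(heavy.index)
    diffs = (heavy.loc[common] - light.loc[common]).to_numpy(dtype=float)
    forced = cohort.registry.get(variable, {}).get("forced_test")
    return _compare_paired(diffs, variable, "heavy_vs_light", forced)


# ---------------------------------------------------------------------------
# magnitude-based inference


def group_mbi(comparison: PairedComparison, swc: float) -> GroupMBI:
    """Chances that the true mean change is beyond +-SWC, from a t sampling
    distribution of the mean change (df = n - 1, SE = SD(diff)/sqrt(n))."""
    if swc <= 0:
        raise ParameterError("swc must be positive")
    if comparison.n < 3:
        raise WarmupHRVError("group MBI needs n >= 3")
    n = comparison.n
    mean_diff = comparison.mean_diff
    sd = comparison.sd_diff
    if sd == 0:
        if mean_diff > swc:
            chances = (0.0, 0.0, 100.0)
        elif mean_diff < -swc:
            chances = (100.0, 0.0, 0.0)
        else:
            chances = (0.0, 100.0, 0.0)
    else:
        se = sd / math.sqrt(n)
        pos = 100.0 * stats.t.sf((swc - mean_diff) / se, df=n - 1)
        neg = 100.0 * stats.t.cdf((-swc - mean_diff) / se, df=n - 1)
        chances = (float(neg), float(100.0 - neg - pos), float(pos))
    return GroupMBI(
        chances=chances,
        descriptor=_mbi_descriptor(chances),
        clinical=_clinical_label(chances),
    )


def _mbi_descriptor(chances: tuple[float, float, float]) -> str:
    neg, triv, pos = chances
    dominant, label = (neg, "negative") if neg >= pos else (pos, "positive")
    if dominant >= 25.0:
        return f"{_probability_word(dominant)} {label}"
    return f"{_probability_word(triv)} trivial"


def _clinical_label(chances: tuple[float, float, float]) -> str:
    neg, _, pos = chances
    if neg > 5.0 and pos > 5.0:
        return "unclear"
    return "clear"


def individual_change(
    pre: float,
    post: float,
    te: float,
    swc: float,
    participant: object = None,
    session: str = "",
) -> IndividualChange:
    """Magnitude inference for a single athlete's PRE-to-POST change.

    The change score's noise SD is sqrt(2)*TE (two measurements each with
    noise SD = TE); chances are normal-distribution tail areas beyond +-SWC
    around the observed change, and the 50% CI is delta +- 0.6745*sqrt(2)*TE.
    """
    if te <= 0:
        raise ParameterError("te must be positive")
    if swc <= 0:
        raise ParameterError("swc must be positive")
    delta = post - pre
    noise_sd = math.sqrt(2.0) * te
    q75 = stats.norm.ppf(0.75)
    ci50 = (delta - q75 * noise_sd, delta + q75 * noise_sd)
    pos = 100.0 * stats.norm.sf((swc - delta) / noise_sd)
    neg = 100.0 * stats.norm.cdf((-swc - delta) / noise_sd)
    chances = (float(neg), float(100.0 - neg - pos), float(pos))
    return IndividualChange(
        participant=participant,
        session=session,
        delta=float(delta),
        ci50=ci50,
        chances=chances,
        descriptor=_mbi_descriptor(chances),
    )


# ---------------------------------------------------------------------------
# full study report


@dataclass(frozen=True)
class StudyReport:
    reference: dict[str, ReferenceStats]
    comparisons: list[PairedComparison]
    group_inferences: dict[tuple[str, str], GroupMBI]
    individuals: list[IndividualChange]
    contrast: PairedComparison | None

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for comp in self.comparisons:
            key = (comp.variable, comp.session)
            mbi = self.group_inferences.get(key)
            ref = self.reference.get(comp.variable)
            rows.append(
                {
                    "variable": comp.variable,
                    "session": comp.session,
                    "n": comp.n,
                    "te": ref.te if ref else float("nan"),
                    "cv_pct": ref.cv_pct if ref else float("nan"),
                    "swc": ref.swc if ref else float("nan"),
                    "mean_diff": comp.mean_diff,
                    "ci90_low": comp.ci90[0],
                    "ci90_high": comp.ci90[1],
                    "p_value": comp.p_value,
                    "effect_size": comp.effect_size,
                    "effect_kind": comp.effect_kind,
                    "test_used": comp.test_used,
                    "effect_descriptor": comp.descriptor,
                    "mbi_display": mbi.display if mbi else "",
                    "mbi_descriptor": mbi.descriptor if mbi else "",
                    "mbi_clinical": mbi.clinical if mbi else "",
                }
            )
        return pd.DataFrame(rows)

    def individuals_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": ic.participant,
                "session": ic.session,
                "delta": ic.delta,
                "ci50_low": ic.ci50[0],
                "ci50_high": ic.ci50[1],
                "chance_negative": ic.chances[0],
                "chance_trivial": ic.chances[1],
                "chance_positive": ic.chances[2],
                "descriptor": ic.descriptor,
            }
            for ic in self.individuals
        )

    def to_json(self) -> str:
        payload = {
            "reference": {
                v: {"te": r.te, "cv_pct": r.cv_pct, "swc": r.swc, "n": r.n}
                for v, r in self.reference.items()
            },
            "comparisons": self.report_frame().to_dict(orient="records"),
            "individuals": self.individuals_frame().to_dict(orient="records"),
            "contrast": None
            if self.contrast is None
            else {
                "variable": self.contrast.variable,
                "n": self.contrast.n,
                "mean_diff": self.contrast.mean_diff,
                "p_value": self.contrast.p_value,
                "effect_size": self.contrast.effect_size,
                "effect_kind": self.contrast.effect_kind,
                "test_used": self.contrast.test_used,
            },
        }
        return json.dumps(payload, indent=2)


def build_study_report(
    cohort: CohortTable, individual_variable: str = "dfa_a1"
) -> StudyReport:
    """Full analysis: per variable x session comparisons with group MBI,
    per participant x session individual inference for ``individual_variable``,
    and the heavy-vs-light contrast for once-per-session variables (RPE)."""
    cohort.validate()
    reference = build_reference_table(cohort)

    comparisons: list[PairedComparison] = []
    group_inferences: dict[tuple[str, str], GroupMBI] = {}
    contrast = None
    for variable in cohort.variables():
        entry = cohort.registry.get(variable, {})
        if entry.get("session_contrast"):
            contrast = session_contrast(cohort, variable)
            continue
        for session in SESSIONS:
            pre, post = cohort.paired_values(variable, session)
            if len(pre) < 3:
                continue
            comp = paired_comparison(cohort, variable, session)
            comparisons.append(comp)
            ref = reference.get(variable)
            if ref and ref.swc > 0:
                group_inferences[(variable, session)] = group_mbi(comp, ref.swc)

    individuals: list[IndividualChange] = []
    ref = reference.get(individual_variable)
    if ref and ref.te > 0 and ref.swc > 0:
        for session in SESSIONS:
            pre, post = cohort.paired_values(individual_variable, session)
            for pid in pre.index:
                individuals.append(
                    individual_change(
                        pre.loc[pid], post.loc[pid], ref.te, ref.swc,
                        participant=pid, session=session,
                    )
                )
    return StudyReport(
        reference=reference,
        comparisons=comparisons,
        group_inferences=group_inferences,
        individuals=individuals,
        contrast=contrast,
    )
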