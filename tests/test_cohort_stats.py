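"""Reliability statistics, paired comparisons and magnitude-based inference."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from warmuphrv import (
    CohortSpec,
    CohortTable,
    build_reference_table,
    build_study_report,
    generate_cohort,
    group_mbi,
    individual_change,
    paired_comparison,
    reference_stats,
    session_contrast,
)
from warmuphrv.cohort_stats import PairedComparison
from warmuphrv.errors import ParameterError, SchemaError, WarmupHRVError
from warmuphrv.synthetic import VariableSpec


class TestReferenceStats:
    def test_dfa_a1_reliability(self, cohort):
        ref = reference_stats(cohort, "dfa_a1")
        assert round(ref.te, 2) == 0.18
        assert round(ref.cv_pct) == 25
        assert round(ref.swc, 2) == 0.12

    def test_swc_uses_class_factor(self, cohort):
        # performance measures use 0.3 x SD, physiological 0.5 x SD
        assert round(reference_stats(cohort, "cmjf").swc, 2) == 0.69
        assert round(reference_stats(cohort, "hr").swc, 2) == round(
            0.5 * cohort.values("hr", "light", "PRE").std(ddof=1), 2
        )

    def test_swc_equals_factor_times_baseline_sd(self, cohort):
        # CV x mean cancels algebraically back to the SD
        for var, factor in (("dfa_a1", 0.5), ("cmjf", 0.3)):
            sd = cohort.values(var, "light", "PRE").std(ddof=1)
            assert reference_stats(cohort, var).swc == pytest.approx(
                factor * sd, abs=1e-12
            )

    def test_identical_baselines_give_zero_te(self):
        rows = []
        for pid in range(1, 6):
            for session in ("light", "heavy"):
                for occ in ("PRE", "POST"):
                    rows.append((pid, session, occ, "x", 10.0 + pid))
        table = CohortTable(
            pd.DataFrame(rows, columns=["participant", "session", "occasion", "variable", "value"]),
            registry={"x": {"class": "performance"}},
        )
        assert reference_stats(table, "x").te == 0.0

    def test_unknown_variable(self, cohort):
        with pytest.raises(WarmupHRVError):
            reference_stats(cohort, "vo2max")

    def test_build_reference_table_covers_fixture(self, reference):
        assert set(reference) == {"rec", "stress", "dfa_a1", "hr", "cmjh", "cmjf", "ftc", "ftf"}
        assert reference["hr"].te == pytest.approx(6.58, abs=0.15)

    def test_empty_cohort_gives_empty_table(self):
        empty = CohortTable(
            pd.DataFrame(columns=["participant", "session", "occasion", "variable", "value"])
        )
        assert build_reference_table(empty) == {}


class TestPairedComparison:
    def test_heavy_session_dfa(self, cohort):
        c = paired_comparison(cohort, "dfa_a1", "heavy")
        assert c.test_used == "paired_t"
        assert c.mean_diff == pytest.approx(-0.28, abs=0.005)
        assert 0.0005 <= c.p_value <= 0.002
        assert c.effect_size == pytest.approx(-1.44, abs=0.05)
        assert c.ci90[0] < c.mean_diff < c.ci90[1]

    def test_light_session_cmjf(self, cohort):
        c = paired_comparison(cohort, "cmjf", "light")
        assert c.p_value == pytest.approx(0.020, abs=0.003)
        assert c.effect_size == pytest.approx(0.84, abs=0.03)
        assert c.descriptor == "large"

    def test_rpe_session_contrast(self, cohort):
        c = session_contrast(cohort, "rpe")
        assert c.test_used == "wilcoxon"
        assert c.p_value < 0.001
        assert c.effect_kind == "rank_r"
        assert c.effect_size == pytest.approx(0.89, abs=0.01)

    def test_effect_size_sign_follows_mean_diff(self, cohort):
        for var in ("dfa_a1", "hr", "cmjf"):
            for session in ("light", "heavy"):
                c = paired_comparison(cohort, var, session)
                if c.effect_kind == "cohen_dz" and c.mean_diff != 0:
                    assert math.copysign(1, c.effect_size) == math.copysign(1, c.mean_diff)

    def test_pairwise_deletion(self, cohort):
        # participant 11 is missing jump measurements in the heavy session
        assert paired_comparison(cohort, "cmjh", "heavy").n == 10
        assert paired_comparison(cohort, "cmjh", "light").n == 11

    def test_zero_variance_degenerate(self):
        diffs = pd.DataFrame(
            [
                (pid, "light", occ, "x", 5.0 if occ == "PRE" else 6.0)
                for pid in range(1, 6)
                for occ in ("PRE", "POST")
            ],
            columns=["participant", "session", "occasion", "variable", "value"],
        )
        c = paired_comparison(CohortTable(diffs, registry={"x": {}}), "x", "light")
        assert c.test_used == "degenerate"
        assert math.isnan(c.p_value)

    def test_too_few_pairs(self, cohort):
        sub = CohortTable(
            cohort.data[cohort.data["participant"] == 1].copy(), registry=cohort.registry
        )
        with pytest.raises(WarmupHRVError):
            paired_comparison(sub, "dfa_a1", "light")


class TestGroupMBI:
    def test_heavy_dfa_chances(self, cohort, reference):
        c = paired_comparison(cohort, "dfa_a1", "heavy")
        mbi = group_mbi(c, reference["dfa_a1"].swc)
        assert tuple(round(x) for x in mbi.chances) == (99, 1, 0)
        assert mbi.descriptor == "very likely negative"
        assert mbi.display == "99/01/00"

    def test_light_dfa_chances(self, cohort, reference):
        c = paired_comparison(cohort, "dfa_a1", "light")
        mbi = group_mbi(c, reference["dfa_a1"].swc)
        for got, want in zip(mbi.chances, (10, 74, 16)):
            assert abs(got - want) <= 1.0
        assert mbi.descriptor == "possibly trivial"

    def test_point_mass_inside_swc(self):
        c = PairedComparison(
            variable="x", session="light", n=10, mean_diff=0.0, sd_diff=0.0,
            ci90=(0.0, 0.0), p_value=float("nan"), effect_size=float("nan"),
            effect_kind="cohen_dz", test_used="degenerate", descriptor="trivial",
        )
        assert group_mbi(c, 0.5).chances == (0.0, 100.0, 0.0)

    def test_chances_conserved(self, cohort, reference):
        for var in ("dfa_a1", "hr", "cmjf"):
            for session in ("light", "heavy"):
                c = paired_comparison(cohort, var, session)
                mbi = group_mbi(c, reference[var].swc)
                assert sum(mbi.chances) == pytest.approx(100.0, abs=1e-9)

    def test_monotone_in_mean_diff(self):
        base = dict(
            variable="x", session="light", n=11, sd_diff=0.2,
            ci90=(0.0, 0.0), p_value=1.0, effect_size=0.0,
            effect_kind="cohen_dz", test_used="paired_t", descriptor="trivial",
        )
        chances = [
            group_mbi(PairedComparison(mean_diff=md, **base), 0.12).chances[2]
            for md in np.linspace(-0.5, 0.5, 11)
        ]
        assert all(a < b for a, b in zip(chances, chances[1:]))

    def test_swc_limits(self):
        c = PairedComparison(
            variable="x", session="light", n=11, mean_diff=0.1, sd_diff=0.2,
            ci90=(0.0, 0.2), p_value=0.1, effect_size=0.5,
            effect_kind="cohen_dz", test_used="paired_t", descriptor="small",
        )
        assert group_mbi(c, 1e-9).chances[1] == pytest.approx(0.0, abs=1e-6)
        assert group_mbi(c, 1e9).chances[1] == pytest.approx(100.0, abs=1e-6)

    def test_invalid_swc(self):
        c = PairedComparison(
            variable="x", session="light", n=11, mean_diff=0.1, sd_diff=0.2,
            ci90=(0.0, 0.2), p_value=0.1, effect_size=0.5,
            effect_kind="cohen_dz", test_used="paired_t", descriptor="small",
        )
        with pytest.raises(ParameterError):
            group_mbi(c, 0.0)


class TestIndividualChange:
    def test_published_example_athletes(self):
        te, swc = 0.183, 0.12
        assert round(individual_change(0.77, 1.13, te, swc).chances[2]) == 82
        assert round(individual_change(0.93, 1.22, te, swc).chances[2]) == 74
        # chances are reported as integer percentages; the published 64
        assert abs(round(individual_change(0.76, 0.54, te, swc).chances[0]) - 64) <= 1

    def test_zero_delta_is_symmetric(self):
        ic = individual_change(1.0, 1.0, te=0.18, swc=0.12)
        assert ic.chances[0] == pytest.approx(ic.chances[2], abs=1e-9)

    def test_ci50_width(self):
        te = 0.18
        ic = individual_change(1.0, 1.2, te=te, swc=0.12)
        half = 0.6744897501960817 * math.sqrt(2) * te
        assert ic.ci50 == pytest.approx((0.2 - half, 0.2 + half), abs=1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            individual_change(1.0, 1.1, te=0.0, swc=0.12)
        with pytest.raises(ParameterError):
            individual_change(1.0, 1.1, te=0.18, swc=-1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        delta=st.floats(-1.0, 1.0),
        te=st.floats(0.01, 1.0),
        swc=st.floats(0.01, 1.0),
    )
    def test_chance_conservation_property(self, delta, te, swc):
        ic = individual_change(1.0, 1.0 + delta, te=te, swc=swc)
        assert sum(ic.chances) == pytest.approx(100.0, abs=1e-9)

    def test_monotone_in_delta(self):
        pos = [
            individual_change(1.0, 1.0 + d, te=0.18, swc=0.12).chances[2]
            for d in np.linspace(-0.5, 0.5, 11)
        ]
        assert all(a < b for a, b in zip(pos, pos[1:]))


class TestTERecovery:
    def test_te_estimator_consistent_on_synthetic_cohorts(self):
        # known measurement noise 0.18; at n=200 the estimate lands within 10%
        true_te = 0.18
        estimates = []
        for seed in range(50):
            spec = CohortSpec(
                n_participants=200,
                variables={
                    "dfa_a1": VariableSpec(mean=1.0, between_sd=0.24, noise_sd=true_te)
                },
                seed=seed,
            )
            table = generate_cohort(spec)
            estimates.append(reference_stats(table, "dfa_a1").te)
        assert abs(np.mean(estimates) - true_te) <= 0.1 * true_te
        within = [abs(e - true_te) <= 0.1 * true_te for e in estimates]
        assert np.mean(within) >= 0.9

    def test_te_error_shrinks_with_cohort_size(self):
        true_te = 0.18
        errors = {}
        for n in (20, 200):
            ests = [
                reference_stats(
                    generate_cohort(
                        CohortSpec(
                            n_participants=n,
                            variables={
                                "dfa_a1": VariableSpec(
                                    mean=1.0, between_sd=0.24, noise_sd=true_te
                                )
                            },
                            seed=seed,
                        )
                    ),
                    "dfa_a1",
                ).te
                for seed in range(30)
            ]
            errors[n] = np.mean([abs(e - true_te) for e in ests])
        assert errors[200] < errors[20]


class TestStudyReport:
    def test_fixture_report_shape(self, cohort):
        report = build_study_report(cohort)
        frame = report.report_frame()
        # 8 PRE/POST variables x 2 sessions
        assert len(frame) == 16
        assert set(frame["variable"]) == {
            "rec", "stress", "dfa_a1", "hr", "cmjh", "cmjf", "ftc", "ftf",
        }
        individuals = report.individuals_frame()
        assert len(individuals) == 22  # 11 athletes x 2 sessions
        assert report.contrast is not None
        assert report.contrast.variable == "rpe"

    def test_single_participant_rejected(self, cohort):
        sub = CohortTable(
            cohort.data[cohort.data["participant"] == 1].copy(), registry=cohort.registry
        )
        with pytest.raises(WarmupHRVError):
            paired_comparison(sub, "dfa_a1", "light")

    def test_synthetic_cohort_end_to_end(self):
        table = generate_cohort(CohortSpec(seed=5))
        report = build_study_report(table)
        assert len(report.report_frame()) == 2
        assert report.to_json()

    def test_duplicate_key_listed(self, cohort):
        df = pd.concat([cohort.data, cohort.data.iloc[[0]]], ignore_index=True)
        table = CohortTable(df, registry=cohort.registry)
        with pytest.raises(SchemaError) as exc:
            table.validate()
        assert any("duplicate" in v for v in exc.value.violations)
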