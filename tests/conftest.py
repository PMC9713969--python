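import numpy as np
import pytest

from warmuphrv import (
    CohortTable,
    FractalRRSpec,
    RRSeries,
    build_reference_table,
    generate_fractal_rr,
    study_fixture,
)


@pytest.fixture(scope="session")
def cohort() -> CohortTable:
    """The packaged 11-triathlete study cohort."""
    return study_fixture()


@pytest.fixture(scope="session")
def reference(cohort):
    return build_reference_table(cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231107)


@pytest.fixture()
def fractal_series() -> RRSeries:
    """A clean fractal warm-up series (~800 ms beats, 600 of them)."""
    return generate_fractal_rr(
        FractalRRSpec(target_alpha1=1.0, n_beats=600, mean_rr=800.0, sd_rr=40.0, seed=7)
    )


def naive_alpha1(rr, n_min=4, n_max=16):
    """Loop-based DFA alpha-1 reference, independent of the library path."""
    rr = np.asarray(rr, dtype=float)
    profile = np.cumsum(rr - rr.mean())
    n_values, F = [], []
    for n in range(n_min, n_max + 1):
        n_boxes = len(profile) // n
        sq = []
        for b in range(n_boxes):
            seg = profile[b * n : (b + 1) * n]
            t = np.arange(n, dtype=float)
            design = np.vstack([t, np.ones(n)]).T
            coef, *_ = np.linalg.lstsq(design, seg, rcond=None)
            sq.extend((seg - design @ coef) ** 2)
        n_values.append(n)
        F.append(np.sqrt(np.mean(sq)))
    return np.polyfit(np.log10(n_values), np.log10(F), 1)[0]
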