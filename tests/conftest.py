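import numpy as np
import pytest

from tiadose import (
    LU177,
    BiExp3Params,
    BiExp4Params,
    MonoExpParams,
    SCHEDULES,
    TimeActivitySeries,
    eval_model,
)


@pytest.fixture(scope="session")
def constants():
    return LU177


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


def series_from_model(family, params, schedule="patientA", region="region",
                      noise_sd=0.0, rng=None, **kwargs):
    """Sample a model at one of the patient schedules (helper, not a fixture)."""
    t = np.asarray(SCHEDULES[schedule] if isinstance(schedule, str)
                   else schedule, dtype=float)
    a = np.asarray(eval_model(family, params, t), dtype=float)
    if noise_sd > 0:
        a = np.maximum(a * (1 + rng.normal(0, noise_sd, t.shape)), 0.0)
    return TimeActivitySeries(region, tuple(t), tuple(a), **kwargs)


@pytest.fixture
def kidney_series():
    """Noiseless fast-uptake kidney: monoexp washout at patient A's schedule."""
    return series_from_model("monoexp", MonoExpParams(A=100.0, lam=0.013),
                             region="kidney")


@pytest.fixture
def lesion_series():
    """Noiseless lesion: uptake then washout at patient B's schedule."""
    return series_from_model(
        "biexp3", BiExp3Params(A=150.0, lam1=0.008, lam2=0.12),
        schedule="patientB", region="lesion")


def random_washout_series(rng, schedule="patientA", noise_sd=0.05,
                          lam_range=(0.006, 0.03), region="r"):
    """Random monoexponential washout series; redrawn until the last segment
    decreases so every catalog tail rule is applicable."""
    t = np.asarray(SCHEDULES[schedule], dtype=float)
    for _ in range(100):
        A = rng.uniform(20.0, 500.0)
        lam = rng.uniform(*lam_range)
        a = A * np.exp(-lam * t)
        if noise_sd > 0:
            a = np.maximum(a * (1 + rng.normal(0, noise_sd, t.shape)), 1e-9)
        if a[-1] < a[-2] and a[-1] < a[-3]:
            return TimeActivitySeries(region, tuple(t), tuple(a)), \
                MonoExpParams(A=A, lam=lam)
    raise AssertionError("could not draw a decreasing washout series")
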