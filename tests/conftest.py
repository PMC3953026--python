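import numpy as np
import pandas as pd
import pytest

from telotrack import cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-parameter synthetic cohort, small n, fixed seed."""
    cfg = cohort.GeneratorConfig(n_participants=800, seed=7)
    return cfg, cohort.generate_cohort(cfg)


@pytest.fixture(scope="session")
def midsize_cohort():
    """Cohort large enough for stable moment checks."""
    cfg = cohort.GeneratorConfig(n_participants=20000, seed=11)
    return cfg, cohort.generate_cohort(cfg)


@pytest.fixture(scope="session")
def registry(small_cohort):
    cfg, tabs = small_cohort
    return cohort.simulate_registry(tabs["truth"], tabs["exam2"], cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_exam(pid, dates, age, tl, **overrides):
    """Minimal well-formed examination table for unit tests."""
    n = len(pid)
    base = dict(
        participant_id=pid,
        exam_id="exam1",
        exam_date=pd.to_datetime(dates),
        age=age,
        sex=["female"] * n,
        current_smoking=0.0,
        tobacco_g_day=0.0,
        weight_kg=70.0,
        height_m=1.7,
        bmi=70.0 / 1.7**2,
        alcohol_g_week=50.0,
        exercise_h_week=5.0,
        tl_bp=tl,
    )
    base.update(overrides)
    return pd.DataFrame(base)
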