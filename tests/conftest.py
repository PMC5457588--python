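import numpy as np
import pandas as pd
import pytest

import uef


def make_sinusoid_trace(
    amplitude=200.0,
    freq=0.5,
    duration=20.0,
    fs=100.0,
    upperarm=None,
    amp_of_t=None,
):
    """Noise-free quasi-sinusoidal elbow trial with optional amplitude schedule.

    ``amp_of_t`` maps cycle-midpoint time to amplitude (per-cycle constant),
    default constant ``amplitude``.
    """
    t = np.arange(int(round(duration * fs))) / fs
    if amp_of_t is None:
        elbow = amplitude * np.sin(2 * np.pi * freq * t)
    else:
        cycle = np.floor(freq * t).astype(int)
        mid_t = (np.arange(cycle.max() + 1) + 0.5) / freq
        a = np.array([amp_of_t(m) for m in mid_t])
        elbow = a[cycle] * np.sin(2 * np.pi * freq * t)
    upper = np.zeros_like(t) if upperarm is None else upperarm
    return uef.MotionTrace(fs, t, elbow + upper, upper)


def extract_cohort(cohort, traces, **kwargs):
    """Append the eight extracted UEF parameters to a cohort table."""
    rows = []
    for _, r in cohort.iterrows():
        p = uef.extract_parameters(
            traces[r["id"]], mass_kg=r["weight_kg"], height_cm=r["height_cm"], **kwargs
        )
        rows.append(p.as_dict())
    return cohort.assign(**pd.DataFrame(rows, index=cohort.index))


@pytest.fixture(scope="session")
def default_cohort_352():
    """Defaults-generated 352-subject cohort with extracted UEF parameters."""
    cfg = uef.RunConfig(seed=7)
    cohort, traces = uef.generate_cohort(cfg, seed=7)
    return extract_cohort(cohort, traces)


@pytest.fixture(scope="session")
def small_cohort_80():
    """Smaller extracted cohort for cheaper per-module tests."""
    cfg = uef.RunConfig(seed=3, n_subjects=80)
    cohort, traces = uef.generate_cohort(cfg, seed=3)
    return extract_cohort(cohort, traces)
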