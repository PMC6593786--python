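import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gesturesync import SyntheticConfig
from gesturesync.synthetic import simulate_records

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_records() -> pd.DataFrame:
    """Record-level draw at the study's scale (10 participants, ~160 s each)."""
    return simulate_records(SyntheticConfig.study_scale(n_participants=10), seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def gaussian_bell_motion(rate_hz=240.0, t_total=4.0, t0=2.0, sigma_g=0.15, v_peak=30.0):
    """Motion whose speed is an analytic Gaussian bell (position = its integral)."""
    from scipy.special import erf

    from gesturesync import MotionTrace

    t = np.arange(int(t_total * rate_hz) + 1) / rate_hz
    # integral of v_peak * exp(-(t-t0)^2 / (2 sigma^2))
    z = v_peak * sigma_g * np.sqrt(np.pi / 2) * erf((t - t0) / (np.sqrt(2) * sigma_g))
    pos = np.zeros((len(t), 3))
    pos[:, 2] = z
    return MotionTrace(time_s=t, pos_cm=pos, rate_hz=rate_hz), t0, sigma_g, v_peak
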