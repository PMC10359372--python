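import dataclasses

import numpy as np
import pandas as pd
import pytest

from rtnfb.bold_sim import SimParams, simulate_run
from rtnfb.learning_analysis import AnalysisConfig
from rtnfb.paradigm import build_course, build_run


@pytest.fixture(scope="session")
def run1():
    return build_run(1)


@pytest.fixture(scope="session")
def run2():
    return build_run(2)


@pytest.fixture(scope="session")
def course8():
    return build_course(8)


@pytest.fixture(scope="session")
def noise_free_params():
    """Generator with every stochastic term off and an exactly recoverable
    effect: no delay, single-step hemodynamic model, no control leak."""
    return SimParams(
        noise_sd_pct=0.0,
        drift_pct_per_min=0.0,
        global_amp_pct=0.0,
        hrf_delay_s=0.0,
        hrf_rise_steps=1,
        amp0_pct=2.0,
        learning_slope_pct=0.0,
        control_leak=0.0,
    )


@pytest.fixture(scope="session")
def exact_config():
    """Analysis settings matched to noise_free_params (lag = delay = 0,
    no detrending) so block scores equal the programmed amplitude."""
    return AnalysisConfig(lag_s=0.0, detrend="none")


@pytest.fixture()
def clinical_table():
    """Small deterministic clinical table with a clear time effect."""
    rng = np.random.default_rng(7)
    rows = []
    for j in range(12):
        group = "NFB" if j < 6 else "CBT"
        base = rng.normal(27, 2.5)
        for t_idx, time in enumerate(("pre", "mid", "post")):
            decline = 5 if group == "NFB" else 7
            rows.append(
                {
                    "subject_id": f"s{j:02d}",
                    "group": group,
                    "time": time,
                    "madrs": float(base - decline * t_idx + rng.normal(0, 2)),
                    "bdi": float(base - 2 * t_idx + rng.normal(0, 3)),
                    "zsrds": float(50 + rng.normal(0, 4)),
                }
            )
    return pd.DataFrame(rows)
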