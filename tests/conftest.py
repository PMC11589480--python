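import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from napdyn import nap_model, synthetic

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> nap_model.NAPParameters:
    return nap_model.NAPParameters.defaults()


@pytest.fixture(scope="session")
def arf_tables():
    """One noisy fold-change table and its noise-free ground truth."""
    return synthetic.make_arf_timecourse(n_replicates=3, rep_cv=0.1, seed=7)


@pytest.fixture(scope="session")
def small_scene() -> synthetic.SyntheticScene:
    return synthetic.random_scene(n_nuclei=10, seed=3)


def ratio_series(rng: np.random.Generator, n_nuclei: int, times, shifts,
                 sd: float = 0.3, gemma: str = "g1") -> pd.DataFrame:
    """Synthetic per-nucleus log2-ratio series with a known shift per time."""
    base = rng.normal(0.0, sd, size=n_nuclei)
    rows = []
    for t, shift in zip(times, shifts):
        vals = base + shift + (rng.normal(0.0, sd, size=n_nuclei) if t != times[0] else 0.0)
        for i, v in enumerate(vals):
            rows.append({"gemma_id": gemma, "nucleus_id": i, "time_h": t,
                         "ratio": 2.0 ** v, "log2_ratio": v, "censored": False})
    return pd.DataFrame(rows)
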