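import numpy as np
import pandas as pd
import pytest

from gvpatterns.cgm_io import GlucoseSeries
from gvpatterns.preprocess import Window


def make_series(values, start="2019-01-01 00:00", step_min=15, pid="P1"):
    """Regularly sampled helper trace."""
    values = np.asarray(values, dtype=float)
    ts = pd.date_range(start, periods=len(values), freq=f"{step_min}min")
    return GlucoseSeries(pid, ts, values)


def make_window(values, start="2019-01-01 00:00", duration=150, step=15,
                pid="P1"):
    values = np.asarray(values, dtype=float)
    return Window(pid, pd.Timestamp(start), duration,
                  np.arange(len(values)) * step, values)


@pytest.fixture
def constant_series():
    return make_series([5.0] * 20)


@pytest.fixture
def small_cohort():
    """Tiny synthetic cohort: 4 patients, 2 days, deterministic."""
    from gvpatterns.synthetic import SyntheticConfig, generate_cohort
    cfg = SyntheticConfig(n_patients=4, days_per_patient=2, seed=11)
    series, truth = generate_cohort(cfg)
    return series, truth
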