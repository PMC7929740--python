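import numpy as np
import pandas as pd
import pytest

from actifda.basis import MINUTES_PER_DAY, FourierBasis
from actifda.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def basis():
    return FourierBasis()


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic study used by several suites."""
    cfg = SimulationConfig(n_subjects=25, seed=42)
    return simulate_dataset(cfg)


def flat_mean_coefficients(level: float = 500.0) -> np.ndarray:
    """Constant mean curve, high enough that the zero floor never binds."""
    c = np.zeros(9)
    c[0] = level * np.sqrt(MINUTES_PER_DAY)
    return c


def minute_table(curves: np.ndarray, observed: np.ndarray | None = None,
                 subject_ids=None, dates=None) -> pd.DataFrame:
    """Long-format minute records from a (n_days, 1440) array."""
    n = curves.shape[0]
    if observed is None:
        observed = np.ones_like(curves, dtype=bool)
    if subject_ids is None:
        subject_ids = [f"S{i:03d}" for i in range(n)]
    if dates is None:
        dates = ["2016-06-01"] * n
    rows = {
        "subject_id": np.repeat(subject_ids, MINUTES_PER_DAY),
        "date": np.repeat(dates, MINUTES_PER_DAY),
        "minute_of_day": np.tile(np.arange(MINUTES_PER_DAY), n),
        "activity": curves.ravel(),
        "observed": observed.ravel(),
    }
    return pd.DataFrame(rows)
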