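import numpy as np
import pandas as pd
import pytest

from liondens.synth import SimConfig, simulate_study
from liondens.trajectory import Trajectory


def make_traj(lons, lats, start="2011-01-01", freq_h=4, female_id="F1"):
    """Trajectory from coordinate lists on a regular UTC schedule."""
    n = len(lons)
    t = pd.date_range(start, periods=n, freq=f"{freq_h}h", tz="UTC")
    return Trajectory(female_id, pd.DataFrame({"t": t, "lon": lons, "lat": lats}))


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared across tests (fast to build)."""
    cfg = SimConfig(n_females_south=3, n_females_north=3, n_pregnant=2,
                    n_months=12, seed=7)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """The default study conditions (20 females, 12 pregnant, 36 months)."""
    return simulate_study(SimConfig(seed=1))
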