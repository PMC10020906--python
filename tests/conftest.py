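import numpy as np
import pandas as pd
import pytest

from mobitrace.geo import LocalProjection

BERLIN = (52.52, 13.405)


@pytest.fixture(scope="session")
def proj() -> LocalProjection:
    return LocalProjection(*BERLIN)


@pytest.fixture
def xy_gps(proj):
    """Factory: GPS frame from planar meter offsets around the projection center."""

    def make(t_seconds, x, y, start="2022-03-01T08:00:00Z"):
        t0 = pd.Timestamp(start)
        lat, lon = proj.inverse(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        return pd.DataFrame({
            "timestamp": t0 + pd.to_timedelta(np.asarray(t_seconds, dtype=float), unit="s"),
            "lat": np.atleast_1d(lat),
            "lon": np.atleast_1d(lon),
        })

    return make


@pytest.fixture(scope="session")
def small_study():
    """A 2-day synthetic study reused by read-only tests."""
    from mobitrace.synthetic import SimConfig, simulate_study

    return simulate_study(SimConfig(seed=3, n_days=2))
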