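import numpy as np
import pandas as pd
import pytest

TWO_PI = 2.0 * np.pi


def make_rhythm(n, amplitude, acrophase, noise_sd, seed, mesor=0.0,
                times=None):
    """Simple cosine-plus-noise series on clock times (uniform by default)."""
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 24.0, n) if times is None else np.asarray(times)
    y = (mesor + amplitude * np.cos(TWO_PI * (t - acrophase) / 24.0)
         + noise_sd * rng.standard_normal(len(t)))
    return y, t


@pytest.fixture
def demo_frame():
    """Small mixed-demographics frame with local times/dates attached."""
    rng = np.random.default_rng(7)
    n = 400
    dates = pd.Timestamp("2013-01-01") + pd.to_timedelta(
        rng.integers(0, 200, n), unit="D"
    )
    return pd.DataFrame(
        {
            "d_ingroup": rng.normal(0.3, 0.4, n),
            "local_hours": rng.uniform(0, 24, n),
            "local_date": dates,
            "race": rng.choice(["White", "Black", "Other"], n,
                               p=[0.7, 0.15, 0.15]),
            "gender": rng.choice(["female", "male"], n, p=[0.6, 0.4]),
            "age": rng.integers(18, 60, n),
        }
    )
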