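import numpy as np
import pandas as pd
import pytest

from bioprobe.locoh import Track

T0 = pd.Timestamp("2011-07-01 00:00:00", tz="UTC")


def make_track(x, y, minutes=None, animal_id="seal", at_sea=None):
    """Track from coordinate arrays; timestamps every 18 min by default."""
    x = np.asarray(x, dtype=float)
    if minutes is None:
        minutes = np.arange(len(x)) * 18.0
    t = T0 + pd.to_timedelta(np.asarray(minutes, dtype=float), unit="m")
    return Track(animal_id, t, x, np.asarray(y, dtype=float), at_sea)


def random_track(rng, n=60, extent=10_000.0, animal_id="seal"):
    """Random-walk-ish track with 18-min fixes inside a square."""
    x = rng.uniform(0, extent, n)
    y = rng.uniform(0, extent, n)
    return make_track(x, y, animal_id=animal_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20110615)
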