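import numpy as np
import pandas as pd
import pytest

from paintnnd.io import LocalizationTable


def make_table(
    x,
    y,
    z=None,
    lpx=1.0,
    lpy=None,
    lpz=None,
    channel_id="test",
) -> LocalizationTable:
    """Build a LocalizationTable from bare coordinate arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    cols = {
        "frame": np.zeros(n, dtype=np.int64),
        "x": x,
        "y": y,
        "photons": np.full(n, 1000.0),
        "lpx": np.broadcast_to(np.asarray(lpx, dtype=float), (n,)).copy(),
        "lpy": np.broadcast_to(
            np.asarray(lpx if lpy is None else lpy, dtype=float), (n,)).copy(),
    }
    if z is not None:
        cols["z"] = np.asarray(z, dtype=float)
        cols["lpz"] = np.broadcast_to(
            np.asarray(2.0 if lpz is None else lpz, dtype=float), (n,)).copy()
    return LocalizationTable(channel_id=channel_id, data=pd.DataFrame(cols))


def gaussian_site_table(rng, centers, n_per_site=20, sigma=2.0, channel_id="sites"):
    """Localization cloud: n_per_site Gaussian draws around each center."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    pts = np.repeat(centers, n_per_site, axis=0)
    pts = pts + rng.normal(0, sigma, size=pts.shape)
    return make_table(pts[:, 0], pts[:, 1], lpx=sigma, channel_id=channel_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
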