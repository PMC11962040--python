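import numpy as np
import pytest

from oxitrack.trajectory import Trajectory

KM_PER_DEG = 111.19492664455873  # one degree of latitude on the R=6371 sphere


def make_traj(times_h, lats, lons, species="gull", colony=(0.0, 0.0), iid="t1"):
    """Trajectory from hours-since-start and decimal-degree coordinates."""
    return Trajectory(
        individual_id=iid,
        species=species,
        colony=colony,
        time=np.asarray(times_h, dtype=float) * 3600.0,
        lat=np.asarray(lats, dtype=float),
        lon=np.asarray(lons, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def well_separated():
    from oxitrack.synthetic import well_separated_model

    return well_separated_model()
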