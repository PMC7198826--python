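import numpy as np
import pytest

from dynconn.networks import DynNet
from dynconn.simulate import SimParams, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dynnet(rng, n_windows: int, n_roi: int, kind: str = "lo_window") -> DynNet:
    """A DynNet of random symmetric unit-diagonal matrices with entries in [-1, 1]."""
    w = rng.uniform(-1.0, 1.0, size=(n_windows, n_roi, n_roi))
    w = (w + w.transpose(0, 2, 1)) / 2.0
    for k in range(n_windows):
        np.fill_diagonal(w[k], 1.0)
    # window spec consistent with K windows: T=2, S=1, M=K+1
    return DynNet(w, kind=kind, window_length=2, step=1, n_volumes=n_windows + 1)


@pytest.fixture(scope="session")
def effect_cohort():
    """The default synthetic study cohort (45 patients / 47 controls, seed 0)."""
    return generate_cohort(SimParams(seed=0))


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small, fast cohort for pipeline-level tests."""
    params = SimParams(
        n_patients=10, n_controls=10, n_roi=8, n_volumes=80, seed=3
    )
    return generate_cohort(params)
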