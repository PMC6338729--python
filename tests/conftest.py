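import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from subcellmap import ProfileDataset, SyntheticSpec, generate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

SMALL_KW = dict(
    n_classes=6,
    markers_per_class=12,
    unknowns_per_class=20,
    n_multilocal=10,
    n_unrelated=10,
)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(**SMALL_KW)


@pytest.fixture(scope="session")
def small_data(small_spec):
    """Moderate-noise 6-class dataset with markers and ground truth."""
    return generate_dataset(small_spec, seed=11)


@pytest.fixture(scope="session")
def noiseless_spec():
    return SyntheticSpec(**SMALL_KW, noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_data(noiseless_spec):
    """Zero-noise dataset: every profile equals its class template exactly."""
    return generate_dataset(noiseless_spec, seed=11)


def make_dataset(matrix: np.ndarray, accs=None, marker_class=None) -> ProfileDataset:
    """Hand-rolled ProfileDataset for unit fixtures."""
    matrix = np.asarray(matrix, dtype=float)
    n, c = matrix.shape
    accs = accs if accs is not None else [f"P{i}" for i in range(n)]
    cols = [f"ch{j}" for j in range(c)]
    channel_meta = pd.DataFrame({"replicate": 1, "fraction": range(1, c + 1)}, index=cols)
    fm = pd.DataFrame(
        {"marker_class": marker_class if marker_class is not None else "unknown"},
        index=pd.Index(accs),
    )
    return ProfileDataset(pd.DataFrame(matrix, index=accs, columns=cols), channel_meta, fm)
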