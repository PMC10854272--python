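import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from connharm.io import CohortManifest, ConnectivityMatrix, STREAMLINE_COUNT, MEAN_LENGTH

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric(rng, n, scale=10.0, density=1.0):
    """Random symmetric nonnegative matrix with zero diagonal."""
    a = rng.random((n, n)) * scale
    if density < 1.0:
        a *= rng.random((n, n)) < density
    a = np.triu(a, k=1)
    return a + a.T


def small_manifest(n_per_site=3, ages=None):
    rows = []
    k = 0
    for site in ("site1", "site2"):
        for i in range(n_per_site):
            age = ages[k] if ages is not None else 61.0 + 3 * (i % 10)
            rows.append((f"{site}_s{i:02d}", site, age, "F" if i % 2 == 0 else "M"))
            k += 1
    return CohortManifest(pd.DataFrame(rows, columns=["subject_id", "site", "age", "sex"]))


@pytest.fixture
def tiny_cohort(rng):
    """Six subjects (3 per site), 6-node matrices of both weightings."""
    manifest = small_manifest(3)
    mats = []
    for sid in manifest.subject_ids:
        mats.append(ConnectivityMatrix(sid, STREAMLINE_COUNT, random_symmetric(rng, 6, 50.0)))
        mats.append(ConnectivityMatrix(sid, MEAN_LENGTH, random_symmetric(rng, 6, 80.0)))
    return mats, manifest
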