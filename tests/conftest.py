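import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """One full synthetic cohort (n=40) shared across tests."""
    from celtilkit.simulate import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_patients=40, seed=12))


@pytest.fixture(scope="session")
def bundle_dir(small_bundle, tmp_path_factory):
    from celtilkit.simulate import write_bundle

    out = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(small_bundle, out)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_counts():
    """192-gene toy count matrix: 3 samples with simple structure."""
    from celtilkit.expression import HOUSEKEEPING_GENES

    genes = [f"G{i:03d}" for i in range(1, 186)]
    data = {}
    rng = np.random.default_rng(7)
    for s in ["A", "B", "C"]:
        data[s] = rng.integers(1, 500, size=185)
    df = pd.DataFrame(data, index=genes)
    hk = pd.DataFrame(
        {s: rng.integers(50, 200, size=7) for s in df.columns},
        index=list(HOUSEKEEPING_GENES),
    )
    return pd.concat([df, hk])
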