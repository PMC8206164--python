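import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from follitime.matrix import ExpressionMatrix, timecourse_meta
from follitime.synthetic_data import ARCHETYPE_NAMES, ArchetypeSpec, generate_timecourse

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_fixture():
    """20 genes per archetype at the default signal/noise; with ground truth."""
    specs = [ArchetypeSpec(name, 20) for name in ARCHETYPE_NAMES]
    return generate_timecourse(specs, seed=11)


@pytest.fixture(scope="session")
def noiseless_fixture():
    specs = [ArchetypeSpec(name, 5, noise_sd=0.0) for name in ARCHETYPE_NAMES]
    return generate_timecourse(specs, seed=0)


@pytest.fixture()
def random_matrix():
    """Unstructured 100 x 14 matrix with time-course metadata."""
    rng = np.random.default_rng(42)
    meta = timecourse_meta()
    values = pd.DataFrame(
        rng.normal(5.0, 1.0, size=(100, 14)),
        index=pd.Index([f"g{i:03d}" for i in range(100)], name="gene_id"),
        columns=meta.index,
    )
    return ExpressionMatrix(values, meta)
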