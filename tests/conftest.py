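import numpy as np
import pytest

from rsaplan.io_cli import RunConfig, run_pipeline
from rsaplan.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Ten default-spec patients for geometric property checks."""
    return generate_cohort(CohortSpec(n_patients=10, seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Pure-scaling cohort: head size is the only geometric variation."""
    return generate_cohort(CohortSpec.noiseless(n_patients=20, seed=3))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default pipeline run (n = 83, default spec), shared by the
    cardinality, statistics and acceptance tests."""
    out = tmp_path_factory.mktemp("default_run")
    run_pipeline(RunConfig(output_dir=out))
    return out


@pytest.fixture(scope="session")
def wrap_oracle():
    from support import GeodesicWrapOracle
    return GeodesicWrapOracle()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
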