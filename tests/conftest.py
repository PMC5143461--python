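import numpy as np
import pytest

from penumbra.phantom import PhantomSpec, generate_subject
from penumbra.pipeline import PipelineConfig, run_pipeline


def noiseless_spec(seed: int = 1) -> PhantomSpec:
    """Unit-coil, zero-noise, zero-jitter phantom for exact-recovery checks."""
    spec = PhantomSpec(seed=seed)
    spec.noise_sigma = {k: 0.0 for k in spec.noise_sigma}
    spec.coil_amplitude = 0.0
    spec.subject_scale_sd = 0.0
    return spec


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def subject1(default_spec):
    """First subject of the default phantom, all three timepoints."""
    return generate_subject(default_spec, 0)


@pytest.fixture(scope="session")
def noiseless_subject():
    return generate_subject(noiseless_spec(), 0)


@pytest.fixture(scope="session")
def cohort_result():
    """Full default 10-subject pipeline run (the study-table analogue)."""
    return run_pipeline(PipelineConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
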