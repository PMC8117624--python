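import numpy as np
import pytest

from dualae import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-scale phantom: 128x128, two small anomalies."""
    return PhantomSpec(image_size=128, brain_axes=(48.0, 40.0),
                       anomaly_radius_range=(6.0, 10.0), n_anomalies=2)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """One anomalous phantom image + truth mask (seed 11)."""
    from dataclasses import replace
    return generate_phantom(replace(small_spec, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
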