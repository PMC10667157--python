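import numpy as np
import pytest

from fatseg.phantoms import PhantomSpec, generate_slice, generate_subject


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-scale phantom acquisition: 24 slices on a 128 x 128 grid."""
    return PhantomSpec(image_size=128, n_slices=24)


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    return PhantomSpec(image_size=128, n_slices=24, noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_subject(small_spec):
    return generate_subject(small_spec, subject_seed=42)


@pytest.fixture(scope="session")
def mid_slice(small_spec):
    return generate_slice(small_spec, small_spec.n_slices // 2, subject_seed=42)
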