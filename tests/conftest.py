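import warnings

import numpy as np
import pytest

from lminseg.synthfix import FixtureSpec, generate_cell_image


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def separated_cell():
    """One separated-regime synthetic cell: (spec, gray, trilevel, color)."""
    spec = FixtureSpec(random_seed=42)
    gray, tri, color = generate_cell_image(spec)
    return spec, gray, tri, color


@pytest.fixture(scope="session")
def touching_cell():
    """One touching-regime synthetic cell: (spec, gray, trilevel, color)."""
    spec = FixtureSpec(random_seed=7, touching=True)
    gray, tri, color = generate_cell_image(spec)
    return spec, gray, tri, color


@pytest.fixture(autouse=True)
def _no_warning_noise():
    """Silence expected library warnings so test output stays readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        yield
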