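import numpy as np
import pytest

from depstretch import DielectricBody


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def hvec_like():
    """Placeholder cell/buffer dielectric pair (cell eps 60, sigma 0.01 S/m,
    r 7.5 um; buffer eps 78, 50 uS/cm)."""
    particle = DielectricBody(eps_rel=60.0, sigma=0.01, radius=7.5e-6)
    medium = DielectricBody(eps_rel=78.0, sigma=0.005)
    return particle, medium


def random_body(gen, with_radius=False):
    """A random physically admissible dielectric body."""
    return DielectricBody(
        eps_rel=float(gen.uniform(1.0, 100.0)),
        sigma=float(10.0 ** gen.uniform(-6, 1)),
        radius=float(gen.uniform(1e-6, 2e-5)) if with_radius else None,
    )
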