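import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tautodyn as td
from tautodyn import pes, wigner

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hydrogen():
    return wigner.ParticleSpec.hydrogen()


@pytest.fixture(scope="session")
def wobble_profile():
    """Full reaction path emulating the mismatch-to-tautomer topology."""
    return td.interpolate(td.gen_fixture_pes(td.FixturePESSpec.wobble()))


@pytest.fixture(scope="session")
def eckart_profile():
    """Symmetric Eckart-type inner barrier (0.25 eV, 0.5 Å width)."""
    spec = td.FixturePESSpec.trs_barrier(barrier_height=0.25, barrier_width=0.5)
    return td.interpolate(td.gen_fixture_pes(spec))


def harmonic_profile(omega: float, particle, half_width: float = 4.0, n: int = 201):
    """Reaction path sampling a harmonic well V = mu omega^2 s^2 / 2."""
    k = particle.mass * omega**2
    s = np.linspace(-half_width, half_width, n)
    return pes.interpolate(pes.ReactionPath(s=s, energy=0.5 * k * s**2))


@pytest.fixture(scope="session")
def harmonic_soft(hydrogen):
    return harmonic_profile(0.05, hydrogen)
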