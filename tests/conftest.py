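import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from poretrans.model import MONOMER, ParticleSystem


def make_bare_system(positions, charges, box, bonds=None, head_index=-1):
    """Minimal hand-built ParticleSystem of mobile monomer-type beads."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return ParticleSystem(
        positions=positions,
        velocities=np.zeros((n, 3)),
        charges=np.asarray(charges, dtype=float),
        species=np.full(n, MONOMER, dtype=np.int8),
        bonds=(np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
               if bonds is not None else np.empty((0, 2), dtype=np.int64)),
        box=np.asarray(box, dtype=float),
        mobile=np.ones(n, dtype=bool),
        head_index=head_index)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
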