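import numpy as np
import pytest

from navperm import Environment, PQRAtom


@pytest.fixture
def env295():
    """Recording-temperature environment (RT/F ~ 25.4 mV)."""
    return Environment(temperature=295.0)


@pytest.fixture
def carboxylate_ring():
    """Four carboxylate-like partial charges in a ring of radius 4 Å at z=0."""
    return make_ring(radius=4.0, charge=-0.76, n=4, z=0.0)


def make_ring(radius: float, charge: float, n: int, z: float,
              atom_radius: float = 1.5) -> list[PQRAtom]:
    return [
        PQRAtom(xyz=(radius * np.cos(t), radius * np.sin(t), z),
                charge=charge, radius=atom_radius)
        for t in np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    ]
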