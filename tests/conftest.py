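import numpy as np
import pytest

from poreblock.core_structures import AtomRecord, Structure, apply_c3_symmetry
from poreblock.synthetic_data import (
    CoordinationFixtureSpec,
    MUTANT_SITE_ROSTER,
    WILD_TYPE_SITE_ROSTER,
    build_channel_scaffold,
    build_coordination_fixture,
)


@pytest.fixture
def scaffold():
    """C3 pseudo-pore with marker rings at 429/433/436."""
    return build_channel_scaffold({429: 8.0, 433: 5.0, 436: 7.0})


@pytest.fixture
def mutant_shell_structure():
    """Pentagonal-bipyramidal binding-site fixture: three gate aspartates
    (one bidentate), one glutamate, two waters at 2.4 A."""
    return build_coordination_fixture(
        CoordinationFixtureSpec("pentagonal_bipyramidal", MUTANT_SITE_ROSTER)
    )


@pytest.fixture
def wild_type_shell_structure():
    """Octahedral site fixture: one aspartate oxygen per subunit, three waters."""
    return build_coordination_fixture(
        CoordinationFixtureSpec("octahedral", WILD_TYPE_SITE_ROSTER)
    )


@pytest.fixture
def prolate_trimer():
    """A C3 bundle of Calpha rods parallel to the (1,1,1) axis; its unique
    smallest-moment inertia axis is the symmetry axis."""
    axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
    perp = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
    mono = Structure(
        atoms=[
            AtomRecord(i + 1, "CA", "C", "ALA", 400 + i, "A", 8.0 * perp + 1.5 * i * axis)
            for i in range(20)
        ]
    )
    return apply_c3_symmetry(mono, axis=axis)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
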