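import numpy as np
import pytest

from agentchem.atoms import AtomsData
from agentchem.agent import ToolContext


@pytest.fixture
def ctx(tmp_path):
    """Tool context writing into a per-test temp dir, fixed embedding seed."""
    return ToolContext(workdir=tmp_path, seed=42)


@pytest.fixture
def water():
    """A bent water geometry (not optimized for any particular method)."""
    return AtomsData(
        [8, 1, 1],
        [[0.0, 0.0, 0.119], [0.0, 0.763, -0.477], [0.0, -0.763, -0.477]],
    )


@pytest.fixture
def h2():
    return AtomsData([1, 1], [[0.0, 0.0, 0.0], [0.0, 0.0, 0.74]])


@pytest.fixture
def methane_xyz():
    return (
        "5\n"
        "methane\n"
        "C 0.00000000 0.00000000 0.00000000\n"
        "H 0.62900000 0.62900000 0.62900000\n"
        "H -0.62900000 -0.62900000 0.62900000\n"
        "H 0.62900000 -0.62900000 -0.62900000\n"
        "H -0.62900000 0.62900000 -0.62900000\n"
    )


def random_atoms(rng: np.random.Generator, n: int) -> AtomsData:
    return AtomsData(
        rng.integers(1, 119, size=n),
        rng.normal(scale=5.0, size=(n, 3)),
        rng.normal(scale=3.0, size=(3, 3)),
        rng.integers(0, 2, size=3).astype(bool),
    )
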