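import numpy as np
import pytest

from pdzdesign import (
    DesignSpec,
    load_forcefield,
    load_rotamer_library,
    make_scaffold,
)
from pdzdesign.synthetic import SyntheticScaffoldConfig


@pytest.fixture(scope="session")
def ff():
    return load_forcefield()


@pytest.fixture(scope="session")
def library():
    return load_rotamer_library()


@pytest.fixture(scope="session")
def helix5():
    return make_scaffold(SyntheticScaffoldConfig(5, "helix"))


@pytest.fixture(scope="session")
def helix6():
    return make_scaffold(SyntheticScaffoldConfig(6, "helix"))


@pytest.fixture(scope="session")
def toy_spec(helix6):
    """Four design positions with a restricted alphabet (fast oracles)."""
    allowed = frozenset({"A", "S", "C", "L", "K"})
    return DesignSpec(
        ("frozen", "mutable", "mutable", "rotamer_only", "mutable", "frozen"),
        (None, allowed, allowed, None, allowed, None),
        native_sequence=helix6.sequence,
    )


def cask_like_scaffold():
    """An 83-residue scaffold with the study's composition: 7 Gly, 2 Pro."""
    seq = list("A" * 83)
    for i in (4, 15, 27, 38, 50, 62, 74):
        seq[i] = "G"
    for i in (9, 55):
        seq[i] = "P"
    return make_scaffold(
        SyntheticScaffoldConfig(83, "helix-hairpin", "".join(seq))
    )


CASK_INTERFACE_IDS = frozenset(
    {2, 7, 12, 20, 25, 31, 36, 42, 47, 60, 66, 71, 78}
)


@pytest.fixture(scope="session")
def cask_like():
    return cask_like_scaffold()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
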