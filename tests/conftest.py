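import numpy as np
import pytest

from phylochron.tree_io import Chronogram, CladeDefinition


@pytest.fixture
def basic_tree() -> Chronogram:
    return Chronogram.from_newick("((A:1.0,B:1.0):1.0,C:2.0);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def clade_ab() -> CladeDefinition:
    return CladeDefinition(name="AB", taxa=frozenset({"A", "B"}), mode="crown")


def write_newick_sample(path, newicks):
    path.write_text("".join(n.rstrip("\n").rstrip(";") + ";\n" for n in newicks))
    return str(path)
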