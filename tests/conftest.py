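import pytest

from structflux import ObjectiveSpec, enumerate_elementary_modes
from structflux.synthgen import ToySpec, make_toy_network


@pytest.fixture(scope="session")
def diamond():
    """Uptake -> A; A -> B; A -> C; B -> out1; C -> out2 (5 irreversible)."""
    model, known = make_toy_network(ToySpec(family="diamond"))
    assert known == 2
    return model


@pytest.fixture(scope="session")
def diamond_modes(diamond):
    return enumerate_elementary_modes(diamond)


@pytest.fixture(scope="session")
def chain3():
    """Sext -> M1 -> M2 -> Pext (3 irreversible reactions, 1 mode)."""
    model, known = make_toy_network(ToySpec(family="chain", size=3))
    assert known == 1
    return model


@pytest.fixture(scope="session")
def fan4():
    model, known = make_toy_network(ToySpec(family="fan", size=4))
    assert known == 4
    return model


@pytest.fixture
def b_export_objective():
    """Objective on the diamond's B branch export."""
    return ObjectiveSpec(name="b_export", objective_reaction="e1")
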