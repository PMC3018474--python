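import numpy as np
import pytest

from dnabubble import NucleotideSequence, ThermoParams


@pytest.fixture(scope="session")
def params() -> ThermoParams:
    return ThermoParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_seq(rng: np.random.Generator, length: int, id: str = "r") -> NucleotideSequence:
    return NucleotideSequence(id, "".join(rng.choice(list("ACGT"), size=length)))
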