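import numpy as np
import pytest

from bsclones.amplicons import AmpliconSpec, load_amplicons


@pytest.fixture(scope="session")
def specs():
    return load_amplicons()


@pytest.fixture(scope="session")
def h19(specs):
    return specs["H19"]


@pytest.fixture(scope="session")
def dazl(specs):
    return specs["DAZL"]


@pytest.fixture(scope="session")
def line1(specs):
    return specs["LINE1"]


def make_toy_spec(n_noncpg_c: int, name: str = "TOY") -> AmpliconSpec:
    """Small amplicon with one CpG (preceded by a non-CpG C, so a
    CpG-adjacent unconverted C is constructible) and exactly
    ``n_noncpg_c`` non-CpG cytosines."""
    assert n_noncpg_c >= 1
    parts = ["AT", "CCG", "AT"]  # C at pos 3 is non-CpG, adjacent to CpG at 4
    for _ in range(n_noncpg_c - 1):
        parts.append("ACA")  # isolated non-CpG C, never CpG-adjacent
    parts.append("TT")
    spec = AmpliconSpec(name=name, sequence="".join(parts))
    assert spec.n_cpgs == 1
    assert len(spec.noncpg_c_positions()) == n_noncpg_c
    return spec


@pytest.fixture(scope="session")
def toy20():
    return make_toy_spec(20)


@pytest.fixture(scope="session")
def toy30():
    return make_toy_spec(30)


@pytest.fixture()
def rng():
    return np.random.default_rng(20130828)
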