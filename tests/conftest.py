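"""Shared fixtures: the worked toy chains and the synthetic fixture suite."""

import io

import pytest

from epilift import build_index, parse_chain_file
from epilift.simulate import default_fixture_suite

CH1 = "chain 1000 chrA 20 + 0 20 chrB 22 + 0 22 1\n10 2 4\n8\n"
CH2 = "chain 900 chrA 20 + 0 20 chrB 25 + 0 25 2\n10 0 5\n10\n"
CH3 = "chain 500 chrD 10 + 0 10 chrE 10 - 0 10 3\n10\n"


def chains_from(text: str):
    return parse_chain_file(io.StringIO(text))


@pytest.fixture
def ch1():
    return chains_from(CH1)


@pytest.fixture
def ch2():
    return chains_from(CH2)


@pytest.fixture
def ch3():
    return chains_from(CH3)


@pytest.fixture(scope="session")
def suite():
    """The package's default synthetic assembly-pair suite (300 kb total)."""
    return default_fixture_suite()
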