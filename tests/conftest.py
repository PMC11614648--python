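import pytest

from inteinkit import datasets


@pytest.fixture(scope="session")
def gfp():
    return datasets.gfp_fixture()


@pytest.fixture(scope="session")
def mass_table():
    return datasets.residue_mass_table()


@pytest.fixture(scope="session")
def codon_table():
    return datasets.human_codon_usage()


@pytest.fixture(scope="session")
def registry():
    return datasets.intein_registry()


@pytest.fixture(scope="session")
def npu(registry):
    return next(p for p in registry if p.name == "NpuDnaE")
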