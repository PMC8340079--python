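import pytest

from glycoform import bundled_path
from glycoform.io import read_fasta


@pytest.fixture(scope="session")
def hcg_sequences() -> dict[str, str]:
    return read_fasta(str(bundled_path("hcg.fasta")))


@pytest.fixture(scope="session")
def hcg_alpha(hcg_sequences) -> str:
    return hcg_sequences["hCG_alpha"]


@pytest.fixture(scope="session")
def hcg_beta(hcg_sequences) -> str:
    return hcg_sequences["hCG_beta"]
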