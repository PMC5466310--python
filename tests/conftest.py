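import pytest

from mitochar import genome_model as gm
from mitochar import synthetic_data as sd


@pytest.fixture(scope="session")
def ref_genome() -> gm.AnnotatedGenome:
    """The printed reference annotation table (table-only mode)."""
    return gm.load_reference_annotation()


@pytest.fixture(scope="session")
def syn_bundle():
    """One default synthetic genome (seed 1) plus its truth record."""
    return sd.generate_mitogenome(sd.default_genome_spec(seed=1))


@pytest.fixture(scope="session")
def syn_genome(syn_bundle) -> gm.AnnotatedGenome:
    return syn_bundle[0]


@pytest.fixture(scope="session")
def syn_truth(syn_bundle) -> list[dict]:
    return syn_bundle[1]
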