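import pytest

from snokturn.synthetic_data import GenerationSpec, generate_snorna
from snokturn.functional_classification import Category

UNIFORM_MIX = {cat: 0.2 for cat in Category}


@pytest.fixture(scope="session")
def small_benchmark():
    """50 labelled records, uniform over the five categories, fixed seed."""
    spec = GenerationSpec(seed=42, n=50, category_mix=dict(UNIFORM_MIX))
    return generate_snorna(spec)


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">sno1 test record\nAUGAUGACCCGUACGU\n>sno2\nacgtacgt\n")
    return path
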