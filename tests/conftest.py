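import pytest

from taxabench import (
    AbundanceProfile,
    ExpectedComposition,
    TaxonRecord,
    build_taxonomy_index,
    generate_mini_taxdump,
)
from taxabench.simulate import SPECIES_POOL


@pytest.fixture(scope="session")
def pool_index(tmp_path_factory):
    """Taxonomy index over the full generator species pool."""
    d = tmp_path_factory.mktemp("taxdump")
    generate_mini_taxdump(SPECIES_POOL, d / "names.dmp", d / "nodes.dmp")
    return build_taxonomy_index(d / "names.dmp", d / "nodes.dmp")


@pytest.fixture
def simple_expected():
    return ExpectedComposition(
        "toy",
        [
            TaxonRecord("Escherichia coli", 562, 60.0),
            TaxonRecord("Salmonella enterica", 28901, 40.0),
        ],
    )


def make_profile(records, sample_id="s1", pipeline_id="p1", unclassified=None):
    return AbundanceProfile(
        sample_id,
        pipeline_id,
        [TaxonRecord(n, t, a) for n, t, a in records],
        unclassified,
    )


@pytest.fixture
def make_profile_factory():
    return make_profile
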