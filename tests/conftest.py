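import pytest

import rrnplasmid as rp


@pytest.fixture(scope="session")
def positive_genome():
    """A plasmid-only-rrn genome: 50-kb chromosome with markers, 25-kb
    Rep_3 plasmid carrying two tandem rrn operons at copy number 8."""
    spec = rp.positive_scenario("pos", operons=2)
    record, truth = rp.forge_genome(spec, 11)
    return spec, record, truth


@pytest.fixture(scope="session")
def persicobacter_like():
    """Three tandem rrs-trnI-trnA-rrl-rrf operons on a single ~30-kb
    Rep-bearing plasmid, the configuration seen in Persicobacteraceae."""
    spec = rp.ScenarioSpec(
        genome_id="persico",
        chromosome_length=50_000,
        plasmids=[rp.PlasmidSpec(30_000, "Rep_3", 3, 10.9)],
        he_gene_count=5,
        background_cds_count=5,
    )
    record, truth = rp.forge_genome(spec, 7)
    return record, truth


@pytest.fixture(scope="session")
def rep_panel():
    return rp.default_rep_panel()
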