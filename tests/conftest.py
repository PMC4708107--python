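import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from cytolex.dictionary import CellLineRecord, build_lexicon


@pytest.fixture(scope="session")
def gos3_records() -> list[CellLineRecord]:
    """Three-record lexicon around the GOS-3 worked example."""
    return [
        CellLineRecord(
            accession="CVCL_2050",
            primary_name="GOS-3",
            synonyms={"GOS3"},
            xrefs={"CLDB": "cl5278"},
            species={"Homo sapiens"},
        ),
        CellLineRecord(accession="CVCL_0004", primary_name="K562", has_mutation_data=True),
        CellLineRecord(accession="CVCL_0030", primary_name="HeLa", synonyms={"He La"}),
    ]


@pytest.fixture(scope="session")
def gos3_lexicon(gos3_records):
    return build_lexicon(gos3_records)


@pytest.fixture(scope="session")
def bench():
    """Default synthetic benchmark (shared: training the CRF grids is the
    expensive part of the suite)."""
    from cytolex.synthetic import benchmark

    return benchmark(seed=42)
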