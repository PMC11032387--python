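import pytest
from hypothesis import HealthCheck, settings

from tablemine.gene_registry import GeneRecord, build_registry

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_registry():
    """A hand-built registry with known synonyms and a planted ambiguity."""
    records = [
        GeneRecord("TP53", ["P53", "LFS1"], 7157, "tumor protein p53"),
        GeneRecord("STAT3", ["APRF"], 6774, "signal transducer"),
        GeneRecord("MAPK1", ["ERK2", "P42MAPK"], 5594, "kinase"),
        GeneRecord("EGFR", ["ERBB1", "HER1"], 1956, "receptor"),
        GeneRecord("BRCA1", ["IRIS"], 672, "repair"),
        # X1 is claimed by two genes -> ambiguous, resolves to neither
        GeneRecord("AMBA", ["X1"], 90001, ""),
        GeneRecord("AMBB", ["X1"], 90002, ""),
    ]
    return build_registry(records)
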