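import pytest
from hypothesis import settings

from assaydesign import Assay, DiseaseModel, ExtensionScenario

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def chip() -> Assay:
    return Assay(name="chip-CNV", hit_rate=0.12, price=1.0)


@pytest.fixture
def wes() -> Assay:
    return Assay(name="WES", hit_rate=0.27, price=4.0)


@pytest.fixture
def two_mutation_disease() -> DiseaseModel:
    return DiseaseModel(complexity=2)


@pytest.fixture
def crs_extension() -> ExtensionScenario:
    """Four WES trios in hand; budget for one more WES trio; candidate extra
    assay is chip genotyping all four (additive hit rates, no overlap)."""
    return ExtensionScenario(n=4, base_hit_rate=0.27, augmented_hit_rate=0.39,
                             complexity=2, price_A=4.0, price_B=1.0,
                             budget=4.0)
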