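import numpy as np
import pytest

from isomix import ConsumerRecord, SourceSummary, TEFSpec


@pytest.fixture
def two_sources() -> tuple[SourceSummary, SourceSummary]:
    """The dry-season main-channel source pair: algal biofilm vs the pooled
    leaf-litter/phytoplankton pathway (separated by ~8 permil in d13C)."""
    return (
        SourceSummary(
            source_name="algal biofilm",
            means={"d13C": -23.3, "d15N": 1.77},
            sds={"d13C": 2.42, "d15N": 1.48},
            n=4,
        ),
        SourceSummary(
            source_name="CPOM + seston 53-250 um",
            means={"d13C": -31.1, "d15N": 2.73},
            sds={"d13C": 1.07, "d15N": 1.80},
            n=8,
        ),
    )


@pytest.fixture
def omnivore_tef() -> TEFSpec:
    return TEFSpec(
        guild="omnivore", means={"d13C": 0.6, "d15N": 4.8}, sds={"d13C": 1.3, "d15N": 1.7}
    )


def make_consumer(
    record_id="c1",
    species_code="sp01",
    site_id="site1",
    habitat="main_channel",
    guild="omnivore",
    standard_length=100.0,
    d13C=-25.0,
    d15N=7.0,
    **kw,
) -> ConsumerRecord:
    return ConsumerRecord(
        record_id=record_id,
        species_code=species_code,
        site_id=site_id,
        habitat=habitat,
        guild=guild,
        standard_length=standard_length,
        d13C=d13C,
        d15N=d15N,
        **kw,
    )


@pytest.fixture
def consumer_factory():
    return make_consumer


@pytest.fixture
def rng():
    return np.random.default_rng(42)
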