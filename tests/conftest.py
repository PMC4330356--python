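import pytest

from remethyl.genome import LocusClass
from remethyl.reporting import RunConfig, run_pipeline

#: Down-scaled genome used by the unit-level pipeline fixtures.
SMALL_COUNTS = {
    LocusClass.IMPRINTED_GDMD: 4,
    LocusClass.GDMD_LIKE: 6,
    LocusClass.RE_LINE: 20,
    LocusClass.RE_SINE: 20,
    LocusClass.RE_IAP: 10,
    LocusClass.RE_SATELLITE: 8,
    LocusClass.GENIC_BODY: 25,
    LocusClass.INTERGENIC: 20,
    LocusClass.CGI_PROMOTER_UNMETH: 5,
}


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    return RunConfig(
        chromosomes=(("chr1", 400_000),),
        class_counts=dict(SMALL_COUNTS),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_pipeline(small_config):
    """One shared end-to-end run on the down-scaled genome."""
    return run_pipeline(small_config)
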