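import pytest

from srnaspike import synth as sy
from srnaspike.io import SpikeInSheet


@pytest.fixture(scope="session")
def default_sheet() -> SpikeInSheet:
    """8 random genome-independent sets over 4 decades (the standard mix)."""
    return sy.random_spikein_sheet(seed=1)


@pytest.fixture(scope="session")
def small_sheet() -> SpikeInSheet:
    return SpikeInSheet(
        set_ids=["s1", "s2", "s3"],
        cores=["ACGUACGUACGUA", "GGAUCCGGAUCCG", "UUCGAAUUCGAAU"],
        molecules_per_ug=[1e6, 1e4, 1e2],
    )


@pytest.fixture(scope="session")
def small_truth(default_sheet):
    """A compact planted genome shared by read-level tests."""
    return sy.make_genome(
        n_mirna=5,
        n_tasirna=2,
        n_transposon=3,
        size_bp=20_000,
        seed=7,
        spikein_sheet=default_sheet,
        sirna_species_per_te=8,
    )
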