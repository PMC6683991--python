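import pytest

from repshare.simulate import SimConfig, simulate_repertoires
from repshare.types import ClonotypeRecord, SampleMeta, Tissue


def rec(cdr3="CASSF", count=1, sample="S1", **kwargs) -> ClonotypeRecord:
    return ClonotypeRecord(sample_id=sample, cdr3_aa=cdr3, read_count=count,
                           **kwargs)


@pytest.fixture
def three_records():
    """The canonical collapse example: CASSF 4+3 reads, CASSL 9 reads."""
    return [rec("CASSF", 4), rec("CASSF", 3), rec("CASSL", 9)]


@pytest.fixture
def meta_two_donors():
    def m(sid, ind, tp=63):
        return SampleMeta(sample_id=sid, individual_id=ind, timepoint_days=tp,
                          tissue=Tissue.blood, population="cTfh", group="GLA-SE")
    return m


@pytest.fixture(scope="session")
def sim_cohort():
    """One default synthetic cohort, shared across tests (read-only)."""
    return simulate_repertoires(SimConfig(seed=11))
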