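import pytest

from clonofocus import (
    RearrangementRecord,
    SampleMeta,
    SimParams,
    aggregate_clonotypes,
    simulate_subject,
)

RESIDUES = "ADEFGHIKLMNPQRSTVWY"


def cdr3_for(i: int, width: int = 4) -> str:
    """Deterministic valid CDR3 for an integer index (distinct per index)."""
    digits = []
    for _ in range(width):
        digits.append(RESIDUES[i % len(RESIDUES)])
        i //= len(RESIDUES)
    return "CASS" + "".join(digits) + "F"


def make_table(counts, meta=None, cdr3s=None):
    """Clonotype table with the given template counts (distinct CDR3s)."""
    if cdr3s is None:
        cdr3s = [cdr3_for(i) for i in range(len(counts))]
    records = [
        RearrangementRecord(cdr3_aa=c3, templates=c) for c3, c in zip(cdr3s, counts)
    ]
    return aggregate_clonotypes(records, meta or SampleMeta(sample_id="t"))


@pytest.fixture
def meta_brain():
    return SampleMeta(sample_id="s1", subject_id="subj", compartment="brain")


@pytest.fixture
def meta_blood():
    return SampleMeta(sample_id="s2", subject_id="subj", compartment="blood")


@pytest.fixture(scope="session")
def small_subject():
    """A small simulated subject reused across tests (cheap, deterministic)."""
    params = SimParams(
        seed=7, n_background_clones=1500, n_expanded=5, expanded_mass=0.2,
        public_pool_size=100, public_spike_rate=0.1,
        brain_enrichment=5.0, n_brain_enriched=10, depth=20_000,
    )
    return simulate_subject(params), params
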