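import numpy as np
import pytest

from m6afoot import (
    CalibrationTable,
    MethylatedRead,
    ReferenceGenome,
    SimConfig,
)
from m6afoot.simulate import simulate_genome


@pytest.fixture(scope="session")
def tiny_genome() -> ReferenceGenome:
    return ReferenceGenome({"chrI": "AATTGGCCAA", "chrII": "CACAC"})


@pytest.fixture(scope="session")
def sim_genome():
    """A 100-kb random genome at 60% AT with gene annotation."""
    cfg = SimConfig(seed=101, genome_length=100_000)
    return simulate_genome(cfg)


@pytest.fixture(scope="session")
def identity_table() -> CalibrationTable:
    return CalibrationTable.identity(25)


def make_read(genome, chrom, start, end, m6a=(), quality=99.0, molecule_id="m0"):
    return MethylatedRead.from_m6a_set(
        molecule_id, chrom, start, end, quality, m6a, genome
    )
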