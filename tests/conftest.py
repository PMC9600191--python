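import numpy as np
import pytest

from csfgi import (
    CNAProfile,
    SimulationConfig,
    VariantRecord,
    VariantTable,
    simulate_cohort,
)
from csfgi.synthetic import diploid_segments


def make_table(afs, compartment="leukocyte", patient_id="P001", sample_id=None,
               depth=100, chrom="chr1"):
    """Variant table with one SNV per AF value at consecutive positions."""
    records = []
    for i, af in enumerate(afs):
        alt_depth = int(round(af * depth))
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=100 + i,
                ref="A",
                alt="G",
                kind="SNV",
                alt_depth=alt_depth,
                total_depth=depth,
                af=alt_depth / depth,
            )
        )
    table = VariantTable(
        sample_id=sample_id or f"{patient_id}_{compartment}",
        patient_id=patient_id,
        compartment=compartment,
        records=records,
    )
    table.validate()
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_patients=10, n_plasma=9, n_tissue=2, rng_seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def diploid_profile(small_config):
    return CNAProfile(
        segments=diploid_segments(small_config.resolved_genome()),
        tumor_fraction=0.0,
    )
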