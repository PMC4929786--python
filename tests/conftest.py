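import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cultenrich.io_formats import AnalysisConfig, OtuTable, SampleMetadata
from cultenrich import synthetic

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def tiny_table():
    """Hand-built 3-sample x 4-OTU table with known cultured calls.

    With the 10-read floor: O1 cultured on M1/anaerobic, O2 on M2/aerobic
    (exactly 10 reads), O4 on M1/anaerobic; O3 never (9 reads is below the
    floor, and absent elsewhere).
    """
    counts = np.array(
        [
            [900, 50, 50, 0],  # fecal
            [100, 9, 0, 12],  # plate M1 anaerobic
            [0, 10, 9, 5],  # plate M2 aerobic
        ]
    )
    return OtuTable(["F", "P1", "P2"], ["O1", "O2", "O3", "O4"], counts)


@pytest.fixture
def tiny_metadata():
    return [
        SampleMetadata("F", "culture_independent", "D1", "", "none", "fresh"),
        SampleMetadata("P1", "plate_pool", "D1", "M1", "anaerobic", "fresh"),
        SampleMetadata("P2", "plate_pool", "D1", "M2", "aerobic", "fresh"),
    ]


@pytest.fixture(scope="session")
def small_experiment():
    """One seeded donor experiment reused by downstream-consistency tests."""
    conditions = synthetic.default_conditions(n_media=6)
    community = synthetic.generate_community(120, seed=42)
    culturability = synthetic.generate_culturability(
        community, conditions, frac_culturable=0.7, selectivity=3.0, seed=43
    )
    return synthetic.build_experiment(
        community,
        culturability,
        donor="D1",
        independent_depth=60_000,
        plate_depth=30_000,
        seed=44,
        taxonomy=synthetic.assign_synthetic_taxonomy(community.otu_ids, seed=45),
    )
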