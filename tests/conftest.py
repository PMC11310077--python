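import numpy as np
import pytest

from paleodiv import chronology, pollen_io, resampling
from paleodiv.synthetic_data import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    return generate_world(WorldConfig(n_regions=2, records_per_region=4, seed=7))


@pytest.fixture(scope="session")
def filtered_records(small_world):
    recs = pollen_io.apply_harmonization(
        small_world.records, small_world.harmonization
    )
    recs = [pollen_io.assign_region(r, small_world.region_map) for r in recs]
    kept, reports = chronology.filter_records(recs, small_world.curves)
    return kept


@pytest.fixture(scope="session")
def small_datasets(small_world, filtered_records):
    return list(
        resampling.run_resamples(
            filtered_records, small_world.curves, R=3, master_seed=11
        )
    )
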