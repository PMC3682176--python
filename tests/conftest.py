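import numpy as np
import pytest

import longicv as L
from longicv.iq_data import IQRecord, IQTable


@pytest.fixture(scope="session")
def table1():
    """The packaged 33-subject reference behavioural table."""
    return L.load_reference_table()


@pytest.fixture(scope="session")
def tiny_table():
    """4-subject hand table with known change scores (2, -1, 0, 3 for VIQ)."""
    return IQTable(
        (
            IQRecord(1, 100, 100, 102, 101),
            IQRecord(2, 110, 105, 109, 105),
            IQRecord(3, 95, 98, 95, 100),
            IQRecord(4, 120, 110, 123, 108),
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """8-subject cohort on an 8^3 grid with strong disjoint planted effects."""
    table = L.simulate_iq(8, seed=11)
    truth = L.make_ground_truth(
        shape=(8, 8, 8), region_radius_vox=1.2, seed=1, noise_sd=1.0
    )
    truth = L.with_calibrated_slopes(truth, table, 0.7)
    volumes = L.simulate_volumes(table, truth, seed=12)
    return table, truth, volumes


@pytest.fixture(scope="session")
def loo_result(strong_cohort):
    """Full LOO run on the strong cohort (shared across test modules)."""
    table, truth, volumes = strong_cohort
    cfg = L.RunConfig(n_perm=120, seed=17)
    return L.loo_run(table, volumes, cfg), table, truth


@pytest.fixture(scope="session")
def split_result(strong_cohort):
    """6-repeat split-half run on the strong cohort."""
    from longicv.synthetic_cohort import search_mask_around_truth

    table, truth, volumes = strong_cohort
    cfg = L.RunConfig(n_perm=120, seed=17, repeats=6)
    mask = search_mask_around_truth(truth, margin_vox=3)
    return L.split_half_run(table, volumes, cfg, search_mask=mask), table, truth


@pytest.fixture(scope="session")
def strong_cohort():
    """33-subject cohort on a 16^3 grid, planted peak R^2 = 0.8 per measure."""
    table = L.simulate_iq(33, seed=7)
    truth = L.make_ground_truth(
        shape=(16, 16, 16), region_radius_vox=1.8, seed=3, noise_sd=1.0
    )
    truth = L.with_calibrated_slopes(truth, table, 0.8)
    volumes = L.simulate_volumes(table, truth, seed=8)
    return table, truth, volumes
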