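import math

import pytest

import desertscan as ds


@pytest.fixture(scope="session")
def geometry_cohort():
    """Small geometry-mode cohort shared by read-only tests."""
    return ds.generate_geometry_cohort(ds.GeneratorConfig(n_tracts=200, grid_shape=(20, 10), seed=7))


@pytest.fixture(scope="session")
def label_table():
    """Moderate label-mode table with all covariate effects active."""
    cfg = ds.GeneratorConfig(
        n_tracts=20000, grid_shape=(200, 100), blocks_per_tract=1,
        true_log_odds=ds.DEFAULT_TRUE_LOG_ODDS, seed=11,
    )
    return ds.generate_label_table(cfg)


@pytest.fixture()
def simple_tract():
    def make(**overrides):
        base = dict(
            tract_id="99000000000", population=4000, area=1.0,
            prop_poverty=0.10, median_income=60000.0, msa_median_income=65000.0,
            race_props={"White": 0.6, "Black": 0.2, "Hispanic": 0.1},
            prop_age65=0.15, prop_female=0.51, prop_lt_hs=0.25,
            prop_uninsured=0.08, prop_amb_disability=0.07,
            vehicles_owned=2500, ddi=20.0, ddi_infa=18.0, ddi_se=12.0,
            rri=1.0, x=0.5, y=0.5,
        )
        base.update(overrides)
        return ds.Tract(**base)

    return make


@pytest.fixture()
def access_for():
    """AccessSummary with explicit per-block distances and populations."""
    def make(tract_id="99000000000", dists=(0.2,), pops=(100,)):
        return ds.AccessSummary(
            tract_id=tract_id,
            nearest_distance_by_block={f"b{i}": d for i, d in enumerate(dists)},
            population_by_block={f"b{i}": p for i, p in enumerate(pops)},
        )

    return make


@pytest.fixture(scope="session")
def recovery_design():
    return ds.DesignSpec(
        outcome="desert",
        predictors=(("ddi_category", "categorical"),),
        reference_levels={"ddi_category": "low"},
    )


@pytest.fixture(scope="session")
def recovery_config():
    """Label-mode generating model with only digital-divide effects."""
    return ds.GeneratorConfig(
        n_tracts=50000, grid_shape=(250, 200), blocks_per_tract=1,
        true_log_odds={
            "intercept": -4.2,
            "ddi:moderate": math.log(2.84),
            "ddi:high": math.log(6.94),
        },
        seed=0,
    )
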