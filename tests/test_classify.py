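"""Desert classification rules and their boundary conventions."""

import numpy as np
import pytest

import desertscan as ds
from desertscan.exceptions import DataError, MissingDataError


class TestUrbanicity:
    @pytest.mark.parametrize(
        "population, area, expected",
        [
            (6000, 1.0, "urban"),
            (5000, 1.0, "suburban"),   # boundary: inclusive 1,000-5,000 band
            (1000, 1.0, "suburban"),
            (999, 1.0, "rural"),
            (5001, 1.0, "urban"),
            (2000, 4.0, "rural"),      # density 500/sq mi
        ],
    )
    def test_density_thresholds(self, population, area, expected):
        assert ds.classify_urbanicity(population, area) == expected

    def test_nonpositive_area_rejected(self):
        with pytest.raises(DataError):
            ds.classify_urbanicity(100, 0.0)


class TestLowIncome:
    @pytest.mark.parametrize(
        "poverty, income, msa, expected",
        [
            (0.20, 65000, 65000, True),    # >=20% poverty, inclusive
            (0.05, 51999, 65000, True),    # < 80% of MSA median, strict
            (0.19, 52000, 65000, False),   # both boundaries fail
            (0.05, 52000.0, 65000, False),  # exactly 80% is not below
        ],
    )
    def test_either_arm(self, simple_tract, poverty, income, msa, expected):
        t = simple_tract(prop_poverty=poverty, median_income=income, msa_median_income=msa)
        assert ds.low_income_flag(t) is expected

    def test_missing_income_raises_for_exclusion(self, simple_tract):
        t = simple_tract(median_income=None)
        with pytest.raises(MissingDataError):
            ds.low_income_flag(t)


class TestLowAccess:
    def test_urban_radius_one_mile(self, simple_tract, access_for):
        t = simple_tract(population=6000)  # urban at area 1
        access = access_for(dists=(1.5, 0.3), pops=(34, 66))
        flag, radius = ds.low_access_flag(t, access)
        assert flag is True and radius == 1.0

    def test_rural_below_threshold(self, simple_tract, access_for):
        t = simple_tract(population=500, vehicles_owned=5000)
        access = access_for(dists=(12.0, 0.5), pops=(32, 68))
        flag, radius = ds.low_access_flag(t, access)
        assert flag is False and radius == 10.0

    def test_vehicle_exception_uses_half_mile(self, simple_tract, access_for):
        t = simple_tract(population=2000, vehicles_owned=99)  # suburban
        access = access_for(dists=(0.8, 0.1), pops=(40, 60))  # 40% beyond 0.5 mi
        flag, radius = ds.low_access_flag(t, access)
        assert flag is True and radius == 0.5

    def test_vehicle_exception_needs_under_100_cars(self, simple_tract, access_for):
        t = simple_tract(population=2000, vehicles_owned=100)
        access = access_for(dists=(0.8, 0.1), pops=(40, 60))
        flag, _ = ds.low_access_flag(t, access)
        assert flag is False

    def test_exact_third_triggers(self, simple_tract, access_for):
        t = simple_tract(population=6000)
        access = access_for(dists=(2.0, 0.2, 0.2), pops=(1, 1, 1))  # exactly 1/3 beyond
        flag, _ = ds.low_access_flag(t, access)
        assert flag is True


class TestDesertDefinition:
    @pytest.mark.parametrize(
        "low_income, mode, expected",
        [(True, "primary", True), (False, "primary", False), (False, "distance_only", True)],
    )
    def test_income_requirement_by_mode(self, simple_tract, access_for, low_income, mode, expected):
        # urban tract (radius 1 mile) with its whole population beyond 2 miles
        t = simple_tract(prop_poverty=0.30 if low_income else 0.05, population=6000)
        access = access_for(dists=(2.0,), pops=(100,))
        a = ds.classify_desert(t, access, mode=mode)
        assert a.desert is expected
        assert a.desert_distance_only is True

    def test_access_required_in_both_modes(self, simple_tract, access_for):
        t = simple_tract(prop_poverty=0.30, population=6000)
        access = access_for(dists=(0.1,), pops=(100,))
        for mode in ("primary", "distance_only"):
            assert ds.classify_desert(t, access, mode=mode).desert is False

    def test_adding_pharmacies_never_creates_deserts(self):
        # monotonicity: distances can only shrink when pharmacies are added
        cfg = ds.GeneratorConfig(n_tracts=100, grid_shape=(10, 10), seed=21)
        cohort = ds.generate_geometry_cohort(cfg)
        before = ds.classify_cohort(cohort.tracts, cohort.blocks, cohort.pharmacies)
        extra = [
            ds.Pharmacy(pharmacy_id=f"X{i}", x=float(i % 10) + 0.5, y=float(i // 10) + 0.5)
            for i in range(50)
        ]
        after = ds.classify_cohort(
            cohort.tracts, cohort.blocks, list(cohort.pharmacies) + extra
        )
        b = {a.tract_id: a.desert for a in before.assessments}
        for a in after.assessments:
            if a.desert:
                assert b[a.tract_id], "a new pharmacy created a desert"

    def test_raising_income_never_creates_deserts(self, simple_tract, access_for):
        access = access_for(dists=(2.0,), pops=(100,))
        lo = simple_tract(population=6000, prop_poverty=0.05, median_income=50000.0)
        hi = simple_tract(population=6000, prop_poverty=0.05, median_income=90000.0)
        a_lo = ds.classify_desert(lo, access)
        a_hi = ds.classify_desert(hi, access)
        assert not (a_hi.desert and not a_lo.desert)


class TestSegregation:
    @pytest.mark.parametrize(
        "props, expected",
        [
            ({"Black": 0.51}, "Black"),
            ({"Hispanic": 0.50}, "Integrated"),  # strict majority required
            ({"White": 0.40, "Black": 0.35, "Hispanic": 0.25}, "Integrated"),
            ({"AIAN": 0.9}, "AIAN"),
        ],
    )
    def test_majority_rule(self, props, expected):
        assert ds.classify_segregation(props) == expected

    def test_invalid_sum_rejected(self):
        with pytest.raises(DataError):
            ds.classify_segregation({"White": 0.8, "Black": 0.4})

    def test_symmetric_dirichlet_is_exchangeable(self):
        # with a symmetric generating distribution no group is favoured
        rng = np.random.default_rng(5)
        draws = rng.dirichlet(np.full(5, 0.4), size=4000)
        counts = {g: 0 for g in ("White", "Black", "Hispanic", "Asian", "AIAN")}
        for row in draws:
            cat = ds.classify_segregation(dict(zip(counts, row)))
            if cat != "Integrated":
                counts[cat] += 1
        values = np.array(list(counts.values()))
        assert values.min() > 0
        assert values.max() < 2.0 * values.min()  # loose exchangeability check


class TestDdiCategories:
    def test_one_to_hundred_quartiles(self):
        values = list(range(1, 101))
        cats = ds.categorize_ddi(values)
        assert all(c == "low" for c in cats[:24])
        assert all(c == "moderate" for c in cats[24:74])
        assert all(c == "high" for c in cats[74:])

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(DataError):
            ds.categorize_ddi([5.0] * 100)
        with pytest.raises(DataError):
            ds.categorize_ddi([1.0, 2.0, 3.0])

    def test_rank_preserving_transform_invariance(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 100, 500)
        assert ds.categorize_ddi(values) == ds.categorize_ddi(np.sqrt(values) + 7.0)


class TestRedlining:
    @pytest.mark.parametrize(
        "rri, expected",
        [
            (0.5, "low"),
            (0.7, "neutral"),   # lower bound inclusive
            (1.2999, "neutral"),
            (1.3, "high"),      # printed as >= 1.3
            (None, "missing"),
            (float("nan"), "missing"),
        ],
    )
    def test_bands(self, rri, expected):
        assert ds.categorize_redlining(rri) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(DataError):
            ds.categorize_redlining(-0.2)


class TestCohortClassification:
    def test_matches_generator_oracle(self, geometry_cohort):
        result = ds.classify_cohort(
            geometry_cohort.tracts, geometry_cohort.blocks, geometry_cohort.pharmacies
        )
        truth = geometry_cohort.truth["per_tract"]
        for a in result.assessments:
            assert truth[a.tract_id]["desert"] == a.desert

    def test_missing_income_tracts_excluded_and_counted(self):
        cfg = ds.GeneratorConfig(
            n_tracts=200, grid_shape=(20, 10), seed=9,
            covariate_spec={"missing_income_rate": 0.1},
        )
        cohort = ds.generate_geometry_cohort(cfg)
        result = ds.classify_cohort(cohort.tracts, cohort.blocks, cohort.pharmacies)
        n_missing = sum(1 for t in cohort.tracts if t.median_income is None)
        assert n_missing > 0
        assert len(result.excluded) == n_missing
        assert len(result.assessments) + len(result.excluded) == 200
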