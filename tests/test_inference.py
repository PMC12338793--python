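"""Logistic fits, VIF, E-values, spatial weights and Moran's I."""

import math

import numpy as np
import pandas as pd
import pytest

import desertscan as ds
from desertscan.exceptions import DataError


def two_by_two_frame(a, b, c, d):
    """Outcome/exposure frame for the 2x2 table (a,b exposed; c,d unexposed)."""
    return pd.DataFrame(
        {
            "desert": [1] * a + [0] * b + [1] * c + [0] * d,
            "exposed": [1] * (a + b) + [0] * (c + d),
        }
    )


BINARY_DESIGN = ds.DesignSpec(outcome="desert", predictors=(("exposed", "binary"),))


class TestLogisticFit:
    def test_two_by_two_closed_form(self):
        df = two_by_two_frame(10, 90, 5, 195)
        res = ds.fit_logistic(BINARY_DESIGN, df)
        orv = res.or_estimates["exposed"][0]
        assert orv == pytest.approx((10 * 195) / (90 * 5), rel=1e-6)
        assert res.convergence

    def test_ci_ordering_and_coefficients(self):
        df = two_by_two_frame(20, 80, 10, 190)
        res = ds.fit_logistic(BINARY_DESIGN, df)
        orv, lo, hi, p = res.or_estimates["exposed"]
        assert lo <= orv <= hi
        assert 0 <= p <= 1
        assert math.exp(res.coefficients["exposed"]) == pytest.approx(orv)

    def test_perfect_separation_flagged_not_raised(self):
        df = pd.DataFrame({"desert": [0] * 50 + [1] * 50, "exposed": [0] * 50 + [1] * 50})
        res = ds.fit_logistic(BINARY_DESIGN, df)
        assert res.convergence is False
        assert res.diagnostic != ""

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"desert": [0] * 20, "exposed": [0, 1] * 10})
        with pytest.raises(DataError):
            ds.fit_logistic(BINARY_DESIGN, df)

    def test_missing_reference_level_rejected(self, label_table):
        bad = ds.DesignSpec(
            outcome="desert",
            predictors=(("ddi_category", "categorical"),),
            reference_levels={"ddi_category": "nonexistent"},
        )
        with pytest.raises(DataError, match="reference level"):
            ds.fit_logistic(bad, label_table)

    def test_null_coefficient_ci_coverage(self):
        # exposure independent of outcome: the CI should cover OR=1 ~95% of the time
        rng_covered = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "desert": (rng.random(2000) < 0.10).astype(int),
                    "exposed": (rng.random(2000) < 0.4).astype(int),
                }
            )
            res = ds.fit_logistic(BINARY_DESIGN, df)
            _, lo, hi, _ = res.or_estimates["exposed"]
            rng_covered += lo <= 1.0 <= hi
        assert rng_covered / n_rep >= 0.85

    def test_recovers_generating_coefficients(self, label_table):
        res = ds.fit_logistic(ds.DEFAULT_DESIGN, label_table)
        assert res.convergence
        assert res.or_estimates["ddi_category[high]"][0] == pytest.approx(6.94, rel=0.15)
        assert res.or_estimates["redlining_category[low]"][0] == pytest.approx(0.64, rel=0.25)


class TestVif:
    def test_orthogonal_predictors(self):
        n = 400
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        out = ds.compute_vif(pd.DataFrame({"x1": x1, "x2": x2}))
        assert out["x1"] == pytest.approx(1.0, abs=1e-9)
        assert out["x2"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_column_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        out = ds.compute_vif(pd.DataFrame({"a": x, "b": x}))
        assert math.isinf(out["a"]) and math.isinf(out["b"])

    def test_known_correlation_closed_form(self):
        rho = 0.9
        rng = np.random.default_rng(2)
        n = 200_000
        x1 = rng.normal(size=n)
        x2 = rho * x1 + math.sqrt(1 - rho**2) * rng.normal(size=n)
        out = ds.compute_vif(pd.DataFrame({"x1": x1, "x2": x2}))
        assert out["x1"] == pytest.approx(1 / (1 - rho**2), rel=0.02)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(500, 3)), columns=["a", "b", "c"])
        df["b"] += 0.7 * df["a"]
        base = ds.compute_vif(df)
        df2 = df.assign(a=5.0 * df["a"] - 11.0)
        scaled = ds.compute_vif(df2)
        for k in base:
            assert scaled[k] == pytest.approx(base[k], rel=1e-6)

    def test_constant_column_rejected(self):
        with pytest.raises(DataError):
            ds.compute_vif(pd.DataFrame({"a": [1.0] * 10, "b": list(range(10))}))


class TestEvalues:
    def test_null_or_needs_no_confounding(self):
        assert ds.evalue_for_or(1.0)[0] == 1.0

    def test_ci_crossing_one_gives_one(self):
        _, e_ci = ds.evalue_for_or(1.5, 0.9)
        assert e_ci == 1.0
        _, e_ci = ds.evalue_for_or(0.7, 1.1)
        assert e_ci == 1.0

    def test_formula_values(self):
        # frozen from E = RR + sqrt(RR*(RR-1)), RR = sqrt(OR), floor at 2 dp
        assert ds.evalue_for_or(4.0)[0] == 3.41  # RR=2 -> 2+sqrt(2) = 3.4142
        assert ds.evalue_for_or(0.25)[0] == 3.41  # protective symmetry
        e, e_ci = ds.evalue_for_or(6.94, 5.82)
        assert (e, e_ci) == (4.70, 4.25)

    def test_nonpositive_rejected(self):
        with pytest.raises(DataError):
            ds.evalue_for_or(0.0)


class TestWeights:
    def test_rook_two_by_two(self):
        w = ds.build_weights(grid_shape=(2, 2), scheme="rook")
        assert all(len(nb) == 2 for nb in w.neighbors)

    def test_queen_corner_has_three(self):
        w = ds.build_weights(grid_shape=(3, 3), scheme="queen")
        assert len(w.neighbors[0]) == 3
        assert len(w.neighbors[4]) == 8

    def test_knn_collinear_tie_break_to_lower_index(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        w = ds.build_weights(coords=coords, scheme="knn", k=1)
        assert list(w.neighbors[1]) == [0]
        assert list(w.neighbors[2]) == [1]

    def test_row_standardized_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        w = ds.build_weights(coords=rng.normal(size=(30, 2)), scheme="knn", k=5)
        for wi in w.weights:
            assert wi.sum() == pytest.approx(1.0)

    def test_no_self_neighbors(self):
        w = ds.build_weights(grid_shape=(4, 4), scheme="queen")
        for i, nb in enumerate(w.neighbors):
            assert i not in nb


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        rows = cols = 8
        w = ds.build_weights(grid_shape=(rows, cols), scheme="rook")
        x = np.array([(r + c) % 2 for r in range(rows) for c in range(cols)], dtype=float)
        i_obs, expected, p = ds.morans_i(x, w, n_perm=99, seed=1)
        assert i_obs == pytest.approx(-1.0)
        assert expected == pytest.approx(-1.0 / (rows * cols - 1))
        assert p <= 0.05

    def test_iid_values_near_null_expectation(self):
        n = 2500
        w = ds.build_weights(grid_shape=(50, 50), scheme="rook")
        rng = np.random.default_rng(7)
        i_obs, expected, _ = ds.morans_i(rng.normal(size=n), w, n_perm=0)
        assert abs(i_obs - expected) < 0.05

    def test_two_block_pattern_matches_double_sum(self):
        rows, cols = 4, 6
        w = ds.build_weights(grid_shape=(rows, cols), scheme="rook")
        x = np.array([1.0 if c < cols // 2 else 5.0 for _ in range(rows) for c in range(cols)])
        i_obs, _, _ = ds.morans_i(x, w, n_perm=0)
        # direct double-sum evaluation
        z = x - x.mean()
        num = sum(
            wi * z[i] * z[j]
            for i, (nbs, ws) in enumerate(zip(w.neighbors, w.weights))
            for j, wi in zip(nbs, ws)
        )
        expected = (len(x) / w.total_weight) * num / (z @ z)
        assert i_obs == pytest.approx(expected, rel=1e-12)

    def test_constant_vector_rejected(self):
        w = ds.build_weights(grid_shape=(3, 3), scheme="rook")
        with pytest.raises(DataError):
            ds.morans_i(np.ones(9), w, n_perm=0)

    def test_permutation_p_uniform_under_null(self):
        w = ds.build_weights(grid_shape=(6, 6), scheme="rook")
        rng = np.random.default_rng(9)
        ps = [
            ds.morans_i(rng.normal(size=36), w, n_perm=99, seed=s)[2]
            for s in range(40)
        ]
        assert 0.2 < np.mean(ps) < 0.8  # not systematically extreme


class TestFullAnalysis:
    def test_analyze_produces_all_components(self, label_table):
        n = len(label_table)
        coords = np.column_stack(
            [np.arange(n) % 100, np.arange(n) // 100]
        ).astype(float)
        sub = label_table.iloc[:5000]
        res = ds.analyze_associations(
            sub, ds.DEFAULT_DESIGN, coords=coords[:5000], n_perm=49, seed=3
        )
        assert res.convergence
        assert set(res.evalues) == set(res.or_estimates)
        assert all(v >= 1.0 for v in res.vif.values())
        assert all(e >= 1.0 for e, _ in res.evalues.values())
        i_obs, expected, p = res.morans_i
        assert expected == pytest.approx(-1.0 / (5000 - 1))
        assert i_obs > expected  # smoothed covariates induce positive autocorrelation
        assert p <= 0.10
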