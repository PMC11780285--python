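import numpy as np
import pandas as pd
import pytest

from conftest import make_cohort
from weightpatterns._grid import POST_BASELINE
from weightpatterns.cohort import generate_cohort
from weightpatterns.mi import (EstimationError, ImputationSpec, PooledEstimate,
                               estimate_all, impute, pool_mean, pool_proportion)
from weightpatterns.params import SimulationParams


class TestPoolMean:
    def test_hand_example(self):
        """Rubin's rules on means (5, 6) with per-dataset se 0.2."""
        est = pool_mean([(5.0, 0.2), (6.0, 0.2)])
        assert est.q_bar == pytest.approx(5.5)
        assert est.W == pytest.approx(0.04)
        assert est.B == pytest.approx(0.5)
        assert est.T == pytest.approx(0.79)
        assert est.se == pytest.approx(np.sqrt(0.79))

    def test_degenerate_identical_datasets(self):
        est = pool_mean([(4.2, 0.3)] * 10)
        assert est.B == 0.0
        assert est.se == pytest.approx(0.3)

    def test_negation_symmetry(self):
        pairs = [(5.0, 0.2), (6.5, 0.25), (5.8, 0.22)]
        a = pool_mean(pairs)
        b = pool_mean([(-q, s) for q, s in pairs])
        assert b.q_bar == pytest.approx(-a.q_bar)
        assert b.se == pytest.approx(a.se)

    def test_too_few_datasets(self):
        with pytest.raises(ValueError):
            pool_mean([(5.0, 0.2)])

    def test_rubin_algebra(self):
        """T >= W always; se strictly increases with B at fixed W, m."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            pairs = [(rng.normal(), abs(rng.normal()) + 0.01)
                     for _ in range(5)]
            est = pool_mean(pairs)
            assert est.T >= est.W
        base = PooledEstimate("x", 0.0, W=1.0, B=0.5, m=10)
        bigger = PooledEstimate("x", 0.0, W=1.0, B=0.8, m=10)
        assert bigger.se > base.se

    def test_invalid_variances_rejected(self):
        with pytest.raises(ValueError):
            PooledEstimate("x", 0.0, W=-0.1, B=0.0, m=5)


class TestPoolProportion:
    def test_closed_form(self):
        est = pool_proportion([(0.5, 100)] * 3)
        assert est.q_bar == pytest.approx(0.5)
        assert est.se == pytest.approx(0.05)

    def test_degenerate_proportions(self):
        est = pool_proportion([(0.0, 50), (1.0, 50)])
        assert est.W == 0.0
        assert est.q_bar == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pool_proportion([(1.2, 50), (0.5, 50)])

    def test_logit_pooling_close_to_linear_away_from_bounds(self):
        pairs = [(0.45, 400), (0.5, 400), (0.55, 400)]
        lin = pool_proportion(pairs)
        logit = pool_proportion(pairs, logit=True)
        assert logit.q_bar == pytest.approx(lin.q_bar, abs=0.01)


def _masked_cohort(n=500, seed=3):
    params = SimulationParams(n_members=n, seed=seed, ineligible_fracs={})
    return generate_cohort(params)


class TestImpute:
    def test_no_missing_returns_input(self):
        cohort = make_cohort(
            [{"member_id": f"A{i}", "sex": "female" if i % 2 else "male"}
             for i in range(30)],
            weight_rows={f"A{i}": (90.0, 88.0 - i * 0.1, 87.0, 86.5, 86.0)
                         for i in range(30)})
        completed = impute(cohort, ImputationSpec(m=3, seed=1))
        for d in completed:
            pd.testing.assert_frame_equal(d, cohort.weights)

    def test_deterministic_given_seed(self):
        cohort = _masked_cohort()
        spec = ImputationSpec(m=3, seed=9)
        a = impute(cohort, spec)
        b = impute(cohort, spec)
        for da, db in zip(a, b):
            pd.testing.assert_frame_equal(da, db)

    def test_observed_cells_never_overwritten(self):
        cohort = _masked_cohort()
        for d in impute(cohort, ImputationSpec(m=2, seed=4)):
            obs = cohort.weights.notna()
            assert np.array_equal(d[obs].to_numpy(float),
                                  cohort.weights[obs].to_numpy(float),
                                  equal_nan=True)
            assert d.notna().all().all()

    def test_too_few_observed_rows_named_error(self):
        rows = [{"member_id": f"B{i}"} for i in range(40)]
        weights = {f"B{i}": (90.0, 88.0, None, None, None) for i in range(40)}
        # leave only 3 members observed at 6 months: fewer than predictors
        for i in range(3):
            weights[f"B{i}"] = (90.0, 88.0, 87.0, None, None)
        cohort = make_cohort(rows, weight_rows=weights)
        with pytest.raises(EstimationError, match="m6"):
            impute(cohort, ImputationSpec(m=2, seed=1))

    def test_single_level_categorical_warns(self):
        cohort = make_cohort(
            [{"member_id": f"C{i}", "sex": "female",
              "start_weight_kg": 85.0 + i} for i in range(60)],
            weight_rows={f"C{i}": (85.0 + i, 83.0 + i,
                                   None if i % 2 else 82.0 + i,
                                   82.0 + i, 81.0 + i) for i in range(60)})
        with pytest.warns(UserWarning, match="single level"):
            impute(cohort, ImputationSpec(m=2, seed=2))

    def test_chronology_enforced(self):
        with pytest.raises(ValueError):
            ImputationSpec(m=2, response_order=("m6", "w12", "m9", "m12"))


class TestEstimateAll:
    def test_structure_and_no_missing_equivalence(self):
        rng = np.random.default_rng(5)
        rows, weights = [], {}
        for i in range(60):
            mid = f"D{i}"
            rows.append({"member_id": mid,
                         "sex": "female" if i % 3 else "male"})
            w = 90.0 + rng.normal(0, 5)
            traj = w - np.cumsum(rng.uniform(0, 2, size=4))
            weights[mid] = (w, *traj)
        cohort = make_cohort(rows, weight_rows=weights)
        table = estimate_all(cohort, ImputationSpec(m=3, seed=6))
        # 4 time points x 4 estimands x 3 strata
        assert len(table) == 48
        assert set(table["stratum"]) == {"total", "female", "male"}
        # with nothing missing, pooled means equal complete-data means exactly
        for tp in POST_BASELINE:
            loss = (cohort.weights["baseline"] - cohort.weights[tp]).mean()
            row = table[(table.estimand == "mean_loss_kg")
                        & (table.stratum == "total") & (table.time_point == tp)]
            assert row["q_bar"].iloc[0] == pytest.approx(loss)
            assert row["B"].iloc[0] == 0.0

    def test_single_sex_stratum_warns_and_omits(self):
        cohort = make_cohort(
            [{"member_id": f"E{i}", "sex": "female"} for i in range(25)],
            weight_rows={f"E{i}": (90.0, 89.0, 88.0, 87.0, 86.0)
                         for i in range(25)})
        with pytest.warns(UserWarning, match="male"):
            table = estimate_all(cohort, ImputationSpec(m=2, seed=3))
        assert set(table["stratum"]) == {"total", "female"}

    def test_matches_complete_case_module_without_missingness(self):
        """Cross-module oracle: on fully observed data the pooled table
        equals the estimation module's complete-case table."""
        from weightpatterns.estimation import complete_case_table
        params = SimulationParams(n_members=300, seed=8, ineligible_fracs={},
                                  dropout_hazards=(0, 0, 0, 0))
        cohort = generate_cohort(params)
        pooled = estimate_all(cohort, ImputationSpec(m=2, seed=1))
        cc = complete_case_table(cohort).set_index("time_point")
        for tp in POST_BASELINE:
            row = pooled[(pooled.estimand == "mean_loss_kg")
                         & (pooled.stratum == "total")
                         & (pooled.time_point == tp)]
            assert row["q_bar"].iloc[0] == pytest.approx(
                cc.loc[tp, "mean_loss_kg"])

    def test_more_imputations_stabilize_the_estimate(self):
        """Doubling m moves the pooled mean by less than the Monte Carlo
        standard error of the mean of per-dataset means."""
        cohort = _masked_cohort(n=800, seed=13)
        t_small = estimate_all(cohort, ImputationSpec(m=10, seed=21))
        t_big = estimate_all(cohort, ImputationSpec(m=20, seed=22))
        for tp in ("m12",):
            rs = t_small[(t_small.estimand == "mean_loss_kg")
                         & (t_small.stratum == "total")
                         & (t_small.time_point == tp)].iloc[0]
            rb = t_big[(t_big.estimand == "mean_loss_kg")
                       & (t_big.stratum == "total")
                       & (t_big.time_point == tp)].iloc[0]
            mc_se = np.sqrt(rs["B"] / rs["m"] + rb["B"] / rb["m"])
            assert abs(rs["q_bar"] - rb["q_bar"]) < 3 * mc_se
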