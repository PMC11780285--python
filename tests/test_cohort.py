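import dataclasses

import numpy as np
import pandas as pd
import pytest

from weightpatterns._grid import MAINTENANCE_BAND_KG, POST_BASELINE, TIME_POINTS
from weightpatterns.cohort import (apply_missingness, assign_patterns,
                                   generate_cohort, generate_engagement,
                                   generate_members, generate_trajectories)
from weightpatterns.io import CohortParseError, read_cohort, write_cohort
from weightpatterns.params import SimulationParams


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestGenerateMembers:
    def test_degenerate_sex_split(self):
        p = SimulationParams(n_members=10, seed=3, sex_split=1.0)
        members = generate_members(p)
        assert (members["sex"] == "female").all()

    def test_determinism(self):
        p = SimulationParams(n_members=200, seed=7)
        pd.testing.assert_frame_equal(generate_members(p), generate_members(p))

    def test_female_fraction_converges(self):
        p = SimulationParams(n_members=24035, seed=5)
        members = generate_members(p)
        frac = (members["sex"] == "female").mean()
        se = np.sqrt(p.sex_split * (1 - p.sex_split) / p.n_members)
        assert abs(frac - p.sex_split) < 3 * se

    def test_bmi_height_weight_consistent(self, clean_cohort):
        m = clean_cohort.members
        implied = m["start_weight_kg"] / m["height_m"] ** 2
        assert np.allclose(implied, m["start_bmi"], atol=0.05)

    def test_planted_ineligibles_carry_flags(self):
        fracs = {"underage": 0.1, "underweight_bmi": 0.1, "invalid_weight": 0.1,
                 "missing_start": 0.1, "employer_paid": 0.1, "overseas": 0.1,
                 "pseudo_member": 0.1}
        p = SimulationParams(n_members=2000, seed=13, ineligible_fracs=fracs)
        m = generate_members(p)
        assert (m["age_years"] < 18).sum() > 0
        assert ((m["start_bmi"] < 18.5) & (m["age_years"] >= 18)).sum() > 0
        assert m["start_weight_kg"].isna().sum() > 0
        assert m["employer_paid"].sum() > 0
        assert m["overseas"].sum() > 0
        assert m["pseudo_member"].sum() > 0


class TestAssignPatterns:
    def test_degenerate_mixture(self):
        probs = {k: 0.0 for k in SimulationParams().pattern_probs}
        probs["L|L|L|L"] = 1.0
        p = SimulationParams(n_members=50, seed=1, pattern_probs=probs)
        assert set(assign_patterns(50, p, _rng(4))) == {"L|L|L|L"}

    def test_frequency_converges(self):
        p = SimulationParams(seed=1)
        labels = assign_patterns(6602, p, _rng(0))
        target = p.pattern_probs["L|L|M|M"]
        freq = np.mean(labels == "L|L|M|M")
        se = np.sqrt(target * (1 - target) / 6602)
        assert abs(freq - target) < 3 * se

    def test_identical_rng_state_identical_labels(self):
        p = SimulationParams(seed=1)
        a = assign_patterns(100, p, _rng(9))
        b = assign_patterns(100, p, _rng(9))
        assert (a == b).all()


class TestTrajectories:
    def test_label_fidelity_exhaustive(self, clean_cohort):
        """Classifying pre-missingness series reproduces every assigned label."""
        from weightpatterns.patterns import classify_cohort
        labels = classify_cohort(clean_cohort.weights_premask)
        assert (labels == clean_cohort.assigned_patterns).all()

    def test_maintenance_pattern_respects_band(self):
        p = SimulationParams(seed=2)
        members = generate_members(
            dataclasses.replace(p, n_members=200, ineligible_fracs={}))
        labels = np.repeat("M|M|M|M", 200)
        weights, realized = generate_trajectories(members, labels, p, _rng(3))
        changes = np.diff(weights[list(TIME_POINTS)].to_numpy(), axis=1)
        assert np.all(np.abs(changes) <= MAINTENANCE_BAND_KG + 1e-12)
        assert (realized == "M|M|M|M").all()

    def test_loss_pattern_mean_positive(self):
        p = SimulationParams(seed=4)
        members = generate_members(
            dataclasses.replace(p, n_members=1000, ineligible_fracs={}))
        labels = np.repeat("L|L|M|M", 1000)
        weights, _ = generate_trajectories(members, labels, p, _rng(5))
        loss12 = weights["baseline"] - weights["m12"]
        assert loss12.mean() > 0

    def test_weights_stay_positive(self, clean_cohort):
        w = clean_cohort.weights_premask.to_numpy()
        assert np.all(w[~np.isnan(w)] > 0)
        assert np.all(w[~np.isnan(w)] < 500)


class TestEngagement:
    def _members_weights(self, n=4000, seed=6):
        p = SimulationParams(n_members=n, seed=seed, ineligible_fracs={})
        members = generate_members(p)
        labels = assign_patterns(n, p, _rng(seed + 1))
        weights, _ = generate_trajectories(members, labels, p, _rng(seed + 2))
        return p, members, labels, weights

    def test_zero_coupling_independence(self):
        p, members, labels, weights = self._members_weights()
        p0 = dataclasses.replace(p, engagement_loss_coupling=0.0)
        act = generate_engagement(members, weights, p0, _rng(10))
        total = act.groupby("member_id", observed=True)["total_activity"].sum()
        loss = (weights["baseline"] - weights["m12"]).reindex(total.index)
        r = np.corrcoef(total, loss)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(total))

    def test_zero_base_zero_coupling_all_zero(self):
        p, members, labels, weights = self._members_weights(n=100)
        p0 = dataclasses.replace(p, engagement_base_per_week=0.0,
                                 engagement_loss_coupling=0.0)
        act = generate_engagement(members, weights, p0, _rng(11))
        assert (act["total_activity"] == 0).all()

    def test_counts_nonnegative_and_total_dominates(self, clean_cohort):
        act = clean_cohort.activity
        streams = act.drop(columns=["member_id", "interval", "total_activity"])
        assert (streams.to_numpy() >= 0).all()
        assert (act["total_activity"].to_numpy()
                >= streams.max(axis=1).to_numpy()).all()


class TestMissingness:
    def test_zero_hazards_no_change(self, clean_cohort):
        p = SimulationParams(seed=1, dropout_hazards=(0, 0, 0, 0))
        out = apply_missingness(clean_cohort.weights_premask, p, _rng(12))
        pd.testing.assert_frame_equal(out, clean_cohort.weights_premask)

    def test_unit_hazard_at_first_point(self, clean_cohort):
        p = SimulationParams(seed=1, dropout_hazards=(1.0, 1.0, 1.0, 1.0))
        out = apply_missingness(clean_cohort.weights_premask, p, _rng(13))
        assert out[list(POST_BASELINE)].isna().all().all()
        assert out["baseline"].notna().all()

    def test_monotone(self, default_cohort):
        w = default_cohort.weights[list(TIME_POINTS)]
        obs = w.notna().to_numpy()
        # once missing, never observed again
        assert not np.any(~obs[:, :-1] & obs[:, 1:])

    def test_informative_hazard_hits_gainers_harder(self):
        """Members whose first observed block was a gain drop out of the
        6-month point more often than others."""
        p = SimulationParams(n_members=20000, seed=21, ineligible_fracs={})
        c = generate_cohort(p)
        pre = c.weights_premask
        gain_b1 = (pre["w12"] - pre["baseline"]) > 0
        at_risk = c.weights["w12"].notna()
        miss_m6 = c.weights["m6"].isna() & at_risk
        rate_gain = miss_m6[gain_b1 & at_risk].mean()
        rate_rest = miss_m6[~gain_b1 & at_risk].mean()
        assert rate_gain > rate_rest


class TestCohortDeterminismAndIO:
    def test_end_to_end_determinism(self):
        p = SimulationParams(n_members=300, seed=77)
        a, b = generate_cohort(p), generate_cohort(p)
        pd.testing.assert_frame_equal(a.members, b.members)
        pd.testing.assert_frame_equal(a.weights, b.weights)
        pd.testing.assert_frame_equal(a.activity, b.activity)

    def test_round_trip(self, tmp_path, default_cohort):
        write_cohort(default_cohort, tmp_path / "c")
        back = read_cohort(tmp_path / "c")
        pd.testing.assert_frame_equal(back.members, default_cohort.members,
                                      check_dtype=False)
        pd.testing.assert_frame_equal(back.weights, default_cohort.weights)
        pd.testing.assert_frame_equal(back.activity, default_cohort.activity,
                                      check_dtype=False, check_categorical=False)
        pd.testing.assert_series_equal(back.assigned_patterns,
                                       default_cohort.assigned_patterns,
                                       check_names=False)

    def test_identical_seed_identical_files(self, tmp_path):
        p = SimulationParams(n_members=150, seed=7)
        write_cohort(generate_cohort(p), tmp_path / "a")
        write_cohort(generate_cohort(p), tmp_path / "b")
        for name in ("members.csv", "weights.csv", "activity.csv"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())

    def test_nonnumeric_weight_cell_raises(self, tmp_path, default_cohort):
        write_cohort(default_cohort, tmp_path / "c")
        wfile = tmp_path / "c" / "weights.csv"
        lines = wfile.read_text().splitlines()
        parts = lines[3].split(",")
        parts[-1] = "oops"
        lines[3] = ",".join(parts)
        wfile.write_text("\n".join(lines) + "\n")
        with pytest.raises(CohortParseError, match="weight_kg"):
            read_cohort(tmp_path / "c")

    def test_empty_cohort(self, tmp_path):
        from conftest import make_cohort
        empty = make_cohort([])
        write_cohort(empty, tmp_path / "e")
        back = read_cohort(tmp_path / "e")
        assert back.n == 0
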