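"""Study design layout and synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from listeneff import design, io, synthetic
from listeneff.ratings import ordered_beta_mean


class TestDesignSpec:
    def test_study_size_reproduces_published_observation_count(self):
        spec = design.DesignSpec(
            n_group_a=24,
            n_group_b=25,
            partial_completers=(("CI01", 1), ("NH01", 1)),
        )
        assert spec.total_trials() == 8064
        sched = design.build_design(spec, seed=0)
        assert len(sched) == 8064
        full = sched[sched.participant_id == "CI02"]
        assert len(full) == 168

    def test_empty_design(self):
        spec = design.DesignSpec(n_group_a=0, n_group_b=0)
        assert len(design.build_design(spec)) == 0

    def test_single_run_schedule_composition(self):
        spec = design.DesignSpec(n_group_a=1, n_group_b=0, runs_per_participant=1)
        sched = design.build_design(spec, seed=3)
        assert len(sched) == 84
        assert (sched.trial_type == "sentence").sum() == 54
        assert (sched.trial_type == "null").sum() == 30
        # one block per condition
        assert sorted(sched.condition.unique()) == ["Easy", "Hard", "Med"]

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            design.DesignSpec(sentence_trials_per_block=20)  # 20 + 10 != 28
        with pytest.raises(ValueError):
            design.DesignSpec(n_group_a=-1)
        with pytest.raises(ValueError):
            design.DesignSpec(response_deadline=0.0)
        with pytest.raises(ValueError):
            design.DesignSpec(conditions=("Easy", "Hard"))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        na=st.integers(0, 6),
        nb=st.integers(0, 6),
        runs=st.integers(1, 3),
        partial_runs=st.integers(0, 1),
    )
    def test_row_count_is_closed_form(self, na, nb, runs, partial_runs):
        partial = (("CI01", partial_runs),) if na > 0 else ()
        spec = design.DesignSpec(
            n_group_a=na, n_group_b=nb, runs_per_participant=runs,
            partial_completers=partial,
        )
        expected = (na + nb) * runs * 84
        if partial:
            expected -= (runs - partial_runs) * 84
        assert len(design.build_design(spec, seed=na + nb)) == expected


class TestDrawParticipants:
    def test_zero_covariance_collapses_to_group_mean(self):
        truth = design.default_ground_truth(drift_log_sd=0.0, structural_log_sd=0.0)
        spec = design.DesignSpec(n_group_a=2, n_group_b=2)
        params = synthetic.draw_participants(truth, spec, seed=0)
        expect = np.exp(truth.log_mean["CI"])
        for pid in ("CI01", "CI02"):
            p = params[pid]
            assert p.v[0, 0, 0] == pytest.approx(expect[0])
            assert p.t0 == pytest.approx(expect[14])

    def test_large_sample_mean_recovers_group_log_mean(self):
        truth = design.default_ground_truth()
        spec = design.DesignSpec(n_group_a=0, n_group_b=10_000)
        params = synthetic.draw_participants(truth, spec, seed=1)
        logs = np.array(
            [np.log(params[p].t0) for p in spec.participant_ids("NH")]
        )
        se = truth.log_sd["NH"][14] / np.sqrt(len(logs))
        assert logs.mean() == pytest.approx(truth.log_mean["NH"][14], abs=3 * se)

    def test_same_seed_identical_draws(self):
        truth = design.default_ground_truth()
        spec = design.DesignSpec(n_group_a=3, n_group_b=3)
        a = synthetic.draw_participants(truth, spec, seed=9)
        b = synthetic.draw_participants(truth, spec, seed=9)
        for pid in a:
            assert np.array_equal(a[pid].v, b[pid].v)
            assert a[pid].t0 == b[pid].t0

    def test_invalid_correlation_rejected(self):
        bad = -np.eye(design.N_PARAMS)
        with pytest.raises(ValueError):
            design.GroundTruth(
                log_mean={"CI": np.zeros(15), "NH": np.zeros(15)},
                log_sd={"CI": np.ones(15) * 0.1, "NH": np.ones(15) * 0.1},
                log_corr=bad,
            )


class TestSimulateBehavior:
    def test_zero_deadline_censors_everything(self, small_trials):
        trials, params, spec, _ = small_trials
        sched = design.build_design(
            design.DesignSpec(n_group_a=1, n_group_b=1), seed=5
        )
        sim = synthetic.simulate_behavior(sched, params, deadline=0.0, seed=5)
        assert sim["missing"].all()
        assert (sim["response"] == "none").all()

    def test_missing_flag_matches_deadline_rule(self, small_trials):
        trials, _, _, _ = small_trials
        obs = trials[~trials.missing]
        assert (obs.rt_seconds > 0).all()
        assert (obs.rt_seconds <= 3.0).all()
        mis = trials[trials.missing]
        assert mis.rt_seconds.isna().all()
        assert (mis.response == "none").all()

    def test_rts_exceed_each_participants_t0(self, small_trials):
        trials, params, _, _ = small_trials
        for pid, sub in trials[~trials.missing].groupby("participant_id"):
            assert (sub.rt_seconds > params[pid].t0).all()

    def test_group_error_rate_ordering(self):
        """NH-like parameters should produce far fewer errors than CI-like
        ones (directional check against the published error rates)."""
        truth = design.default_ground_truth()
        spec = design.DesignSpec(n_group_a=8, n_group_b=8)
        sched = design.build_design(spec, seed=21)
        params = synthetic.draw_participants(truth, spec, seed=22)
        sim = synthetic.simulate_behavior(sched, params, deadline=3.0, seed=23)
        obs = sim[~sim.missing]
        err = obs.groupby("group")["correct"].apply(
            lambda s: 1.0 - s.astype(bool).mean()
        )
        assert err["CI"] > 3 * err["NH"]

    def test_race_outcome_rates_match_choice_probability(self, table_params):
        from listeneff import lba

        n = 100_000
        choice, rt = lba.simulate_race(table_params, "Easy", "sentence", n, seed=2)
        p = lba.choice_probability("correct", table_params, "Easy", "sentence")
        se = np.sqrt(p * (1 - p) / n)
        assert (choice == 0).mean() == pytest.approx(p, abs=3 * se)

    def test_reproducible(self, small_trials):
        trials, params, spec, truth = small_trials
        sched = design.build_design(spec, seed=11)
        again = synthetic.simulate_behavior(sched, params, deadline=3.0, seed=13)
        pd.testing.assert_frame_equal(trials, again)


class TestSimulateRatings:
    def test_boundary_mass_at_extreme_predictor(self):
        truth = design.default_ground_truth()
        for key in truth.rating_cell_effects:
            truth.rating_cell_effects[key] = -40.0
        spec = design.DesignSpec(n_group_a=2, n_group_b=2)
        truth.rating_intercept_sd = {g: 0.0 for g in spec.groups}
        ratings = synthetic.simulate_ratings(spec, truth, seed=0)
        assert (ratings.rating == 0.0).all()

    def test_unordered_cutpoints_rejected(self):
        truth = design.default_ground_truth()
        truth.rating_cutpoints = (2.0, -2.0)
        spec = design.DesignSpec(n_group_a=1, n_group_b=1)
        with pytest.raises(ValueError):
            synthetic.simulate_ratings(spec, truth, seed=0)

    def test_sample_mean_matches_analytic_mixture_mean(self):
        truth = design.default_ground_truth()
        truth.rating_intercept_sd = {g: 0.0 for g in ("CI", "NH")}
        spec = design.DesignSpec(n_group_a=10_000, n_group_b=0)
        ratings = synthetic.simulate_ratings(spec, truth, seed=4)
        cell = ratings[(ratings.condition == "Hard") & (ratings.question == "EF")]
        eta = truth.rating_cell_effects[("CI", "EF", "Hard")]
        c1, c2 = truth.rating_cutpoints
        expected = float(
            ordered_beta_mean(eta, c1, c2, truth.rating_precision)
        )
        se = cell.rating.std() / np.sqrt(len(cell))
        assert cell.rating.mean() == pytest.approx(expected, abs=3 * se)

    def test_monotone_effects_give_monotone_means(self):
        truth = design.default_ground_truth()
        spec = design.DesignSpec(n_group_a=200, n_group_b=0)
        ratings = synthetic.simulate_ratings(spec, truth, seed=6)
        ef = ratings[ratings.question == "EF"]
        means = ef.groupby("condition")["rating"].mean()
        assert means["Easy"] < means["Med"] < means["Hard"]


class TestSimulateScores:
    def _eff(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(3.0, 1.0, n), index=[f"P{i}" for i in range(n)])

    def test_zero_target_gives_near_zero_correlation(self):
        eff = self._eff(1000)
        out = synthetic.simulate_scores(
            eff, {"X": 0.0}, {"X": (0, 100)}, seed=1, clip=False
        )
        r = np.corrcoef(eff, out.score)[0, 1]
        assert abs(r) < 3 / np.sqrt(1000)

    def test_perfect_target_without_clipping(self):
        eff = self._eff(50)
        out = synthetic.simulate_scores(
            eff, {"X": 1.0}, {"X": (0, 10)}, seed=2, clip=False
        )
        assert np.corrcoef(eff, out.score)[0, 1] == pytest.approx(1.0)

    def test_long_run_mean_correlation_near_target(self):
        """At n=24 per replicate, the average realised correlation over
        many replicates approaches the 0.4 target (no clipping)."""
        rs = []
        for rep in range(1000):
            eff = self._eff(24, seed=rep)
            out = synthetic.simulate_scores(
                eff, {"X": 0.4}, {"X": (0, 100)}, seed=10_000 + rep, clip=False
            )
            rs.append(np.corrcoef(eff, out.score)[0, 1])
        assert np.mean(rs) == pytest.approx(0.4, abs=0.02)

    def test_impossible_correlation_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_scores(
                self._eff(10), {"X": 1.5}, {"X": (0, 1)}, seed=0
            )


class TestCsvRoundTrips:
    def test_trials_round_trip(self, small_trials, tmp_path):
        trials, _, _, _ = small_trials
        path = tmp_path / "trials.csv"
        io.write_trials(trials, path)
        back = io.read_trials(path)
        # header contract: exact leading column order
        header = open(path).readline().strip().split(",")
        assert header[: len(design.TRIAL_COLUMNS)] == design.TRIAL_COLUMNS
        for col in ("participant_id", "condition", "trial_type", "response"):
            assert list(back[col]) == list(trials[col])
        np.testing.assert_allclose(
            back.rt_seconds.to_numpy(dtype=float),
            trials.rt_seconds.to_numpy(dtype=float),
        )
        assert list(back.missing) == list(trials.missing)

    def test_ratings_and_scores_round_trip(self, tmp_path):
        truth = design.default_ground_truth()
        spec = design.DesignSpec(n_group_a=2, n_group_b=2)
        ratings = synthetic.simulate_ratings(spec, truth, seed=0)
        io.write_ratings(ratings, tmp_path / "r.csv")
        back = io.read_ratings(tmp_path / "r.csv")
        np.testing.assert_allclose(back.rating, ratings.rating)

        eff = pd.Series([1.0, 2.0, 3.0], index=["CI01", "CI02", "CI03"])
        scores = synthetic.simulate_scores(
            eff, {"SSQ12": 0.4}, {"SSQ12": (0, 10)}, seed=1, group="CI"
        )
        io.write_scores(scores, tmp_path / "s.csv")
        back = io.read_scores(tmp_path / "s.csv")
        np.testing.assert_allclose(back.score, scores.score)

    def test_config_round_trip(self, tmp_path):
        truth = design.default_ground_truth()
        spec = design.DesignSpec(partial_completers=(("CI01", 1),))
        io.dump_config(spec, truth, 123, tmp_path / "cfg.yaml")
        spec2, truth2, seed = io.load_config(tmp_path / "cfg.yaml")
        assert seed == 123
        assert spec2 == spec
        for g in ("CI", "NH"):
            np.testing.assert_allclose(truth2.log_mean[g], truth.log_mean[g])
        assert truth2.rating_cell_effects == truth.rating_cell_effects
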