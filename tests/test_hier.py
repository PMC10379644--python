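"""Hierarchical model assembly, diagnostics, and sampler contracts.

Full-scale parameter recovery lives in the acceptance suite; here the
model is exercised on small instances.
"""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from listeneff import design, hier, lba, synthetic
from listeneff.design import N_PARAMS, PARAM_NAMES


@pytest.fixture(scope="module")
def tiny_fit(small_trials):
    trials, _, _, _ = small_trials
    model = hier.build_model(trials)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = hier.sample_posterior(
            model, chains=2, warmup=150, iters=80, thin=2, seed=5
        )
    return model, draws


class TestBuildModel:
    def test_fifteen_free_parameters_per_participant(self, small_trials):
        trials, _, _, _ = small_trials
        model = hier.build_model(trials)
        assert model.spec.n_free_per_participant == 15
        assert len(model.spec.param_names()) == 15
        # 12 drifts + A, k, t0
        drift_names = [n for n in PARAM_NAMES if n.startswith("v_")]
        assert len(drift_names) == 12
        assert set(PARAM_NAMES) - set(drift_names) == {"A", "k", "t0"}

    def test_empty_cell_rejected(self, small_trials):
        trials, _, _, _ = small_trials
        broken = trials[
            ~(
                (trials.group == "CI")
                & (trials.condition == "Hard")
                & (trials.trial_type == "null")
            )
        ]
        with pytest.raises(ValueError, match="empty cell"):
            hier.build_model(broken)

    def test_unknown_labels_rejected(self, small_trials):
        trials, _, _, _ = small_trials
        bad = trials.copy()
        bad.loc[bad.index[0], "condition"] = "Impossible"
        with pytest.raises(ValueError, match="unknown labels"):
            hier.build_model(bad)

    def test_single_participant_likelihood_matches_lba_core(self, small_trials):
        """With the hierarchy degenerate (one participant, fixed point),
        the model's likelihood is the plain trial-level LBA likelihood."""
        trials, params, _, _ = small_trials
        one = trials[trials.participant_id == "CI01"].reset_index(drop=True)
        model = hier.build_model(one)
        p = params["CI01"]
        theta = np.concatenate(
            [np.log(p.v.ravel()), [np.log(p.A), np.log(p.k), np.log(p.t0)]]
        )
        n_mis = model.n_missing
        latents = np.full(n_mis, 3.4)
        got = float(model.participant_loglik(theta[None, :], latents).sum())
        expect = lba.log_likelihood(one, p, latents if n_mis else None)
        assert got == pytest.approx(expect, rel=1e-9)

    def test_log_density_matches_hand_assembled_oracle(self, small_trials):
        """Joint log density equals independently assembled prior +
        likelihood (within 1e-8)."""
        trials, params, spec, _ = small_trials
        model = hier.build_model(trials)
        rng = np.random.default_rng(0)
        theta = np.column_stack(
            [
                rng.normal(0.8, 0.1, model.n_participants)
                for _ in range(12)
            ]
            + [
                rng.normal(0.0, 0.05, model.n_participants),
                rng.normal(0.7, 0.05, model.n_participants),
                np.minimum(rng.normal(-1.6, 0.05, model.n_participants),
                           model.log_t0_max - 0.1),
            ]
        )
        mu = {g: rng.normal(0.5, 0.1, N_PARAMS) for g in model.groups}
        cov = {g: np.diag(rng.uniform(0.02, 0.05, N_PARAMS)) for g in model.groups}
        latents = np.full(model.n_missing, 3.5)
        got = model.log_density(theta, mu, cov, latents)

        # independent assembly
        expect = 0.0
        for gi, g in enumerate(model.groups):
            mem = model.group_index == gi
            expect += stats.multivariate_normal.logpdf(
                theta[mem], mean=mu[g], cov=cov[g]
            ).sum()
            expect += stats.norm.logpdf(
                mu[g], model.priors.mean_loc(), model.priors.mean_scale()
            ).sum()
            expect += stats.invwishart.logpdf(
                cov[g], df=model.priors.iw_df, scale=model.priors.iw_scale()
            )
        for i, pid in enumerate(model.participant_order):
            sub = trials[trials.participant_id == pid]
            p = synthetic.params_from_vector(np.exp(theta[i]))
            n_mis = int(sub.missing.sum())
            expect += lba.log_likelihood(
                sub, p, np.full(n_mis, 3.5) if n_mis else None
            )
        assert got == pytest.approx(expect, abs=1e-8)


class TestRhat:
    def test_constant_chains_flagged_as_nan(self):
        assert np.isnan(hier.rhat(np.ones((3, 50))))

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            hier.rhat(np.ones((1, 100)))
        with pytest.raises(ValueError):
            hier.rhat(np.ones((2, 3)))

    def test_same_distribution_converges(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((4, 10_000))
        assert hier.rhat(draws) < 1.01

    def test_shifted_chain_detected(self):
        rng = np.random.default_rng(2)
        draws = rng.standard_normal((2, 2000))
        draws[1] += 5.0
        assert hier.rhat(draws) > 1.2


class TestSampler:
    def test_retained_draw_count_contract(self, tiny_fit):
        _, draws = tiny_fit
        assert draws.n_draws == draws.chains * draws.iters
        for g in draws.groups:
            assert draws.mu[g].shape == (2, 80, N_PARAMS)
            assert draws.flat_theta(g).shape[0] == draws.n_draws

    def test_rhat_reported_for_group_level_parameters(self, tiny_fit):
        _, draws = tiny_fit
        for g in draws.groups:
            for name in PARAM_NAMES:
                assert f"mu[{g},{name}]" in draws.rhat

    def test_seed_reproducibility(self, small_trials):
        trials, _, _, _ = small_trials
        model = hier.build_model(trials)
        kw = dict(chains=1, warmup=30, iters=10, thin=1, seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = hier.sample_posterior(model, **kw)
            b = hier.sample_posterior(model, **kw)
        for g in a.groups:
            assert np.array_equal(a.mu[g], b.mu[g])
            assert np.array_equal(a.theta[g], b.theta[g])

    def test_nonconvergence_warning_lists_parameters(self, small_trials):
        trials, _, _, _ = small_trials
        model = hier.build_model(trials)
        with pytest.warns(RuntimeWarning, match="R-hat outside"):
            hier.sample_posterior(model, chains=2, warmup=10, iters=10,
                                  thin=1, seed=1)

    def test_draw_persistence_round_trip(self, tiny_fit, tmp_path):
        _, draws = tiny_fit
        draws.to_files(tmp_path / "d.csv", tmp_path / "d.json")
        tidy = pd.read_csv(tmp_path / "d.csv")
        assert list(tidy.columns) == ["chain", "iter", "parameter", "value"]
        import json

        meta = json.loads((tmp_path / "d.json").read_text())
        assert meta["chains"] == 2 and "rhat" in meta

    def test_centered_and_noncentered_target_same_posterior(self):
        """The two parameterizations (diagonal covariance in both) produce
        matching group-mean marginals on a compact instance.

        With effective sample sizes of a few hundred per sampler at a
        runtime that fits the suite budget, the null distribution of the
        two-sample KS statistic alone reaches ~0.1, so the check combines
        a noise-sized KS bound with agreement of each marginal's mean and
        spread (both well-powered at this ESS).
        """
        truth = design.default_ground_truth()
        spec = design.DesignSpec(n_group_a=3, n_group_b=0, runs_per_participant=1)
        sched = design.build_design(spec, seed=31)
        params = synthetic.draw_participants(truth, spec, seed=32)
        trials = synthetic.simulate_behavior(sched, params, deadline=3.0, seed=33)
        out = {}
        for mode, thin in (("centered", 3), ("noncentered", 2)):
            ms = hier.ModelSpec(parameterization=mode, covariance="diagonal")
            model = hier.build_model(trials, ms)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                draws = hier.sample_posterior(
                    model, chains=2, warmup=400, iters=1400, thin=thin, seed=34,
                )
            out[mode] = draws.flat_mu("CI")
        from listeneff.design import N_PARAMS

        for j in range(N_PARAMS):
            a, b = out["centered"][:, j], out["noncentered"][:, j]
            ks = stats.ks_2samp(a, b)
            assert ks.statistic < 0.12, f"coord {j}: KS={ks.statistic:.3f}"
            pooled = np.sqrt(a.var() + b.var())
            assert abs(a.mean() - b.mean()) < 0.3 * pooled, f"coord {j} means"
            ratio = a.std() / b.std()
            assert 0.75 < ratio < 1.33, f"coord {j} spread ratio {ratio:.2f}"


class TestPosteriorPredictive:
    def test_cell_rt_discrepancy_small_on_refit(self, tiny_fit, small_trials):
        trials, _, _, _ = small_trials
        _, draws = tiny_fit
        pp = hier.posterior_predictive(draws, trials, n_draws=25, seed=3)
        assert len(pp) == 12  # 2 groups x 3 conditions x 2 types
        assert np.all(np.abs(pp["rt_discrepancy"]) < 0.10)

    def test_error_rate_ordering_between_groups(self, tiny_fit, small_trials):
        trials, _, _, _ = small_trials
        _, draws = tiny_fit
        pp = hier.posterior_predictive(draws, trials, n_draws=25, seed=4)
        sent = pp[pp.trial_type == "sentence"]
        ci = sent[sent.group == "CI"]["predicted_error_rate"].mean()
        nh = sent[sent.group == "NH"]["predicted_error_rate"].mean()
        assert ci > nh
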