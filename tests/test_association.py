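"""Plausible-values correlations, population-rho posterior, LMG shares."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from listeneff import association
from listeneff.design import N_PARAMS


class _FakeDraws:
    def __init__(self, theta_by_group, participants):
        self.groups = list(theta_by_group)
        self._theta = theta_by_group
        self.participants = participants

    def flat_theta(self, group):
        return self._theta[group]


class TestIndividualEfficiency:
    def _theta(self, vdiff_by_cond, n_draws=3, n_p=2):
        """Log-scale individual draws with sentence vDiff fixed per
        condition and v_incorrect = 1."""
        th = np.zeros((n_draws, n_p, N_PARAMS))
        for ci, vd in enumerate(vdiff_by_cond):
            th[:, :, ci * 2] = np.log(vd + 1.0)
            th[:, :, 6 + ci * 2] = np.log(1.0)
        return th

    def test_equal_conditions_pass_through(self):
        th = self._theta([2.0, 2.0, 2.0])
        draws = _FakeDraws({"CI": th}, {"CI": ["CI01", "CI02"]})
        eff = association.individual_efficiency(draws)["CI"]
        assert np.allclose(eff, 2.0)

    def test_condition_permutation_invariance(self):
        a = self._theta([1.0, 2.0, 3.0])
        b = self._theta([3.0, 1.0, 2.0])
        da = _FakeDraws({"CI": a}, {"CI": ["CI01", "CI02"]})
        db = _FakeDraws({"CI": b}, {"CI": ["CI01", "CI02"]})
        assert np.allclose(
            association.individual_efficiency(da)["CI"],
            association.individual_efficiency(db)["CI"],
        )

    def test_matches_hand_computation_on_toy_table(self):
        # 3 draws x 2 participants; hand-build distinct values
        th = np.zeros((3, 2, N_PARAMS))
        vals = {}
        rng = np.random.default_rng(0)
        for d in range(3):
            for p in range(2):
                vdiffs = []
                for ci in range(3):
                    vc = rng.uniform(2, 4)
                    vi = rng.uniform(0.2, 1.0)
                    th[d, p, ci * 2] = np.log(vc)
                    th[d, p, 6 + ci * 2] = np.log(vi)
                    vdiffs.append(vc - vi)
                vals[(d, p)] = np.mean(vdiffs)
        draws = _FakeDraws({"NH": th}, {"NH": ["NH01", "NH02"]})
        eff = association.individual_efficiency(draws)["NH"]
        for (d, p), v in vals.items():
            assert eff[d, p] == pytest.approx(v)


class TestPlausibleCorrelations:
    def test_scores_equal_to_draw_values_give_unit_r(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=8)
        eff = np.tile(base, (100, 1))
        r = association.plausible_correlations(eff, base)
        assert np.allclose(r, 1.0)

    def test_independent_scores_center_on_zero(self):
        rng = np.random.default_rng(2)
        n_p, n_draws = 24, 400
        eff = rng.normal(size=(n_draws, n_p))
        scores = rng.normal(size=n_p)
        r = association.plausible_correlations(eff, scores)
        assert abs(r.mean()) < 3 / np.sqrt(n_p)

    def test_constant_scores_rejected(self):
        eff = np.random.default_rng(0).normal(size=(10, 6))
        with pytest.raises(ValueError):
            association.plausible_correlations(eff, np.ones(6))

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            association.plausible_correlations(np.ones((5, 3)), np.arange(3))

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(3)
        eff = rng.normal(size=(20, 10))
        s = rng.normal(size=10)
        r = association.plausible_correlations(eff, s)
        expect = [np.corrcoef(eff[d], s)[0, 1] for d in range(20)]
        assert np.allclose(r, expect)


class TestPopulationRhoPosterior:
    def test_zero_r_large_n_is_symmetric_and_tight(self):
        post = association.population_rho_posterior(np.zeros(50), n=200)
        assert post.mean == pytest.approx(0.0, abs=0.01)
        assert post.p_positive == pytest.approx(0.5, abs=0.02)
        assert post.cri[0] < 0 < post.cri[1]
        assert post.cri[1] - post.cri[0] < 0.35

    def test_degenerate_unit_r_piles_at_one(self):
        post = association.population_rho_posterior(np.ones(10), n=24)
        mass_high = np.trapezoid(
            post.pdf[post.grid > 0.9], post.grid[post.grid > 0.9]
        )
        assert mass_high > 0.99

    def test_single_r_posterior_mean_matches_simulation_oracle(self):
        """Simulation-consistency check: simulate r at candidate rho values,
        weight candidates by a kernel match to the observed r, and compare
        the implied posterior mean (uniform prior over candidates)."""
        r_obs, n = 0.5, 24
        post = association.population_rho_posterior([r_obs], n=n)
        rng = np.random.default_rng(4)
        cand = np.linspace(-0.95, 0.95, 39)
        weights = []
        for rho in cand:
            cov = [[1, rho], [rho, 1]]
            rs = np.array([
                np.corrcoef(rng.multivariate_normal([0, 0], cov, size=n).T)[0, 1]
                for _ in range(400)
            ])
            # kernel density of observed r under this rho
            weights.append(np.mean(np.abs(rs - r_obs) < 0.05))
        weights = np.array(weights) / np.sum(weights)
        oracle_mean = float(np.sum(cand * weights))
        assert post.mean == pytest.approx(oracle_mean, abs=0.02)

    def test_fisher_z_approximation_agrees(self):
        r_obs, n = 0.4, 30
        post = association.population_rho_posterior([r_obs], n=n)
        z = np.arctanh(post.grid[1:-1])
        approx = stats.norm.pdf(z, np.arctanh(r_obs), 1 / np.sqrt(n - 3)) / (
            1 - post.grid[1:-1] ** 2
        )
        approx /= np.trapezoid(approx, post.grid[1:-1])
        mean_approx = np.trapezoid(post.grid[1:-1] * approx, post.grid[1:-1])
        assert post.mean == pytest.approx(mean_approx, abs=0.03)

    def test_grid_refinement_stability(self):
        r = np.random.default_rng(5).uniform(-0.3, 0.5, size=40)
        a = association.population_rho_posterior(r, n=24, grid_size=2001)
        b = association.population_rho_posterior(r, n=24, grid_size=4001)
        assert abs(a.mean - b.mean) < 1e-3
        assert np.trapezoid(a.pdf, a.grid) == pytest.approx(1.0, abs=1e-8)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            association.population_rho_posterior([0.5], n=3)


class TestReliabilityFlag:
    def test_cri_excluding_zero_is_reliable(self):
        post = association.population_rho_posterior(np.full(20, 0.8), n=40)
        flag, certainty = association.reliability_flag(post)
        assert flag and certainty > 0.99

    def test_certainty_clause(self):
        """A CrI that brushes zero still flags when directional certainty
        exceeds 90% (the published SSQ12 case: CrI [-0.07, 0.64] with
        95.4% certainty)."""
        post = association.population_rho_posterior(np.full(20, 0.33), n=24)
        assert post.cri[0] < 0 < post.cri[1]
        assert post.p_positive > 0.90
        flag, _ = association.reliability_flag(post)
        assert flag

    def test_weak_posterior_not_reliable(self):
        post = association.population_rho_posterior(np.full(20, 0.05), n=24)
        flag, certainty = association.reliability_flag(post)
        assert not flag and certainty <= 0.90


def _r2(X, y):
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    return 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))


def _lmg_oracle(X, y):
    p = X.shape[1]
    shares = np.zeros(p)
    perms = list(itertools.permutations(range(p)))
    for perm in perms:
        prev = []
        for j in perm:
            before = _r2(X[:, prev], y) if prev else 0.0
            prev.append(j)
            shares[j] += _r2(X[:, prev], y) - before
    return shares / len(perms)


class TestRelativeImportance:
    def test_single_predictor_share_is_simple_r2(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        out = association.relative_importance(x[:, None], y)
        assert out.iloc[0, 0] == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_orthogonal_predictors_split_into_squared_correlations(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        rng = np.random.default_rng(7)
        y = 0.8 * x1 + 0.3 * x2 + rng.normal(size=n)
        out = association.relative_importance(np.column_stack([x1, x2]), y)
        assert out.iloc[0, 0] == pytest.approx(np.corrcoef(x1, y)[0, 1] ** 2, abs=1e-10)
        assert out.iloc[0, 1] == pytest.approx(np.corrcoef(x2, y)[0, 1] ** 2, abs=1e-10)

    def test_five_predictor_shares_sum_to_full_r2(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 5))
        Y = rng.normal(size=(7, 40))
        out = association.relative_importance(X, Y)
        sums = out[[c for c in out.columns if c != "r2_full"]].sum(axis=1)
        assert np.allclose(sums, out["r2_full"], atol=1e-10)

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(25, 4))
        y = X @ np.array([0.5, -0.2, 0.0, 0.9]) + rng.normal(size=25)
        out = association.relative_importance(X, y)
        oracle = _lmg_oracle(X, y)
        assert np.allclose(out.iloc[0, :4].to_numpy(), oracle, atol=1e-10)

    def test_permutation_symmetry_of_columns(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        a = association.relative_importance(X, y)
        b = association.relative_importance(X[:, ::-1], y)
        assert np.allclose(a.iloc[0, :3].to_numpy(), b.iloc[0, :3].to_numpy()[::-1])

    def test_collinear_rejected(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError):
            association.relative_importance(X, np.random.default_rng(0).normal(size=10))

    def test_too_many_predictors_rejected(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError):
            association.relative_importance(rng.normal(size=(20, 9)), rng.normal(size=20))


class TestEndToEndRecords:
    def test_records_and_missing_participant_error(self):
        rng = np.random.default_rng(12)
        n_p, n_draws = 10, 60
        pids = [f"CI{i:02d}" for i in range(1, n_p + 1)]
        theta = np.zeros((n_draws, n_p, N_PARAMS))
        base = rng.normal(3.0, 0.5, size=n_p)
        for ci in range(3):
            theta[:, :, ci * 2] = np.log(base + 1.0) + 0.05 * rng.normal(
                size=(n_draws, n_p)
            )
            theta[:, :, 6 + ci * 2] = 0.0
        draws = _FakeDraws({"CI": theta}, {"CI": pids})
        scores = pd.DataFrame(
            {
                "participant_id": pids,
                "group": "CI",
                "instrument": "SSQ12",
                "score": rng.normal(5, 2, size=n_p),
            }
        )
        records = association.plausible_correlation_analysis(draws, scores, "CI")
        assert len(records) == 1
        rec = records[0]
        assert set(rec) >= {
            "instrument", "r_mean", "rho_mean", "rho_cri_low",
            "rho_cri_high", "certainty", "reliable",
        }
        with pytest.raises(ValueError):
            association.plausible_correlation_analysis(
                draws, scores[scores.participant_id != "CI05"], "CI"
            )
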