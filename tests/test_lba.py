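"""First-passage mathematics of the linear ballistic accumulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.special import ndtr

from listeneff import lba


def _valid_params(draw_scale=1.0):
    return st.tuples(
        st.floats(0.2, 3.0),  # A
        st.floats(0.1, 3.0),  # k
        st.floats(-1.0, 5.0),  # v
    )


class TestSingleAccumulator:
    def test_no_mass_before_start(self):
        assert lba.lba_pdf(-1.0, 1.0, 2.0, 2.0) == 0.0
        assert lba.lba_pdf(0.0, 1.0, 2.0, 2.0) == 0.0
        assert lba.lba_cdf(0.0, 1.0, 2.0, 2.0) == 0.0

    @pytest.mark.parametrize(
        "A,b,v,s,t",
        [
            (1.0, 2.0, 2.0, 1.0, 1.0),
            (0.5, 1.7, 3.5, 1.0, 0.4),
            (2.0, 3.0, 1.0, 1.0, 2.5),
            (1.0, 3.26, 4.64, 1.0, 0.7),
        ],
    )
    def test_pdf_is_derivative_of_cdf(self, A, b, v, s, t):
        h = 1e-5
        fd = (lba.lba_cdf(t + h, A, b, v, s) - lba.lba_cdf(t - h, A, b, v, s)) / (
            2 * h
        )
        assert lba.lba_pdf(t, A, b, v, s) == pytest.approx(fd, abs=1e-6)

    def test_total_finish_probability_matches_positive_drift_mass(self):
        # the accumulator finishes iff its sampled drift is positive (plus
        # negligible start-point corrections at these settings)
        total, _ = integrate.quad(
            lambda t: lba.lba_pdf(t, 1.0, 2.0, 3.0), 0, 200, limit=200
        )
        assert total == pytest.approx(1.0 - ndtr(-3.0), abs=1e-4)
        assert lba.lba_cdf(1e7, 1.0, 2.0, 3.0) == pytest.approx(
            1.0 - ndtr(-3.0), abs=1e-6
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(_valid_params())
    def test_cdf_monotone_and_bounded(self, params):
        A, k, v = params
        grid = np.linspace(1e-6, 30.0, 1000)
        F = lba.lba_cdf(grid, A, A + k, v)
        assert np.all(np.diff(F) >= -1e-12)
        assert np.all((F >= 0) & (F <= 1))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            lba.lba_pdf(1.0, -1.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            lba.lba_cdf(1.0, 2.0, 1.0, 1.0)  # b < A


class TestDefectiveDensity:
    def test_zero_at_or_below_nondecision_time(self, table_params):
        assert lba.defective_density(
            table_params.t0, "correct", table_params, "Easy", "sentence"
        ) == 0.0
        assert lba.defective_density(
            table_params.t0 / 2, "correct", table_params, "Easy", "sentence"
        ) == 0.0

    def test_unknown_choice_rejected(self, table_params):
        with pytest.raises(ValueError):
            lba.defective_density(1.0, "maybe", table_params, "Easy", "sentence")

    def test_equal_accumulators_are_symmetric(self):
        v = np.full((2, 3, 2), 2.5)
        p = lba.LBAParams(A=1.0, k=1.5, t0=0.2, v=v)
        for t in (0.5, 1.0, 2.0):
            assert lba.defective_density(
                t, "correct", p, "Med", "null"
            ) == pytest.approx(
                lba.defective_density(t, "incorrect", p, "Med", "null")
            )

    def test_choices_integrate_to_finish_probability(self, table_params):
        total = 0.0
        for choice in ("correct", "incorrect"):
            for lo, hi in ((table_params.t0, 50.0), (50.0, np.inf)):
                val, _ = integrate.quad(
                    lambda t, c=choice: lba.defective_density(
                        t, c, table_params, "Easy", "sentence"
                    ),
                    lo,
                    hi,
                    limit=300,
                )
                total += val
        nofinish = lba.no_finish_probability(table_params, "Easy", "sentence")
        assert total == pytest.approx(1.0 - nofinish, abs=1e-4)


class TestChoiceProbability:
    def test_symmetry_for_identical_accumulators(self):
        p = lba.LBAParams(A=1.0, k=1.5, t0=0.2, v=np.full((2, 3, 2), 2.0))
        pc = lba.choice_probability("correct", p, "Easy", "sentence")
        pi = lba.choice_probability("incorrect", p, "Easy", "sentence")
        assert pc == pytest.approx(pi, abs=1e-8)

    def test_dominant_drift_wins_nearly_always(self):
        v = np.full((2, 3, 2), 0.1)
        v[0] = 5.0
        p = lba.LBAParams(A=1.0, k=1.5, t0=0.2, v=v)
        assert lba.choice_probability("correct", p, "Hard", "null") > 0.99

    def test_partition_of_unity(self, ci_params):
        pc = lba.choice_probability("correct", ci_params, "Hard", "sentence")
        pi = lba.choice_probability("incorrect", ci_params, "Hard", "sentence")
        nf = lba.no_finish_probability(ci_params, "Hard", "sentence")
        assert pc + pi + nf == pytest.approx(1.0, abs=1e-6)


class TestRaceSimulator:
    def test_empty_race(self, table_params):
        choice, rt = lba.simulate_race(table_params, "Easy", "sentence", 0, seed=0)
        assert choice.size == 0 and rt.size == 0

    def test_rts_exceed_nondecision_time(self, table_params):
        _, rt = lba.simulate_race(table_params, "Easy", "sentence", 2000, seed=1)
        assert np.all(rt > table_params.t0)

    def test_deterministic_under_seed(self, table_params):
        a = lba.simulate_race(table_params, "Med", "null", 500, seed=42)
        b = lba.simulate_race(table_params, "Med", "null", 500, seed=42)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_choice_rates_match_quadrature(self, ci_params):
        n = 100_000
        choice, _ = lba.simulate_race(ci_params, "Hard", "sentence", n, seed=7)
        p_quad = lba.choice_probability("correct", ci_params, "Hard", "sentence")
        se = np.sqrt(p_quad * (1 - p_quad) / n)
        assert (choice == 0).mean() == pytest.approx(p_quad, abs=3 * se)

    def test_rt_distribution_matches_closed_form(self, table_params):
        n = 100_000
        choice, rt = lba.simulate_race(table_params, "Easy", "sentence", n, seed=9)
        sel = choice == 0
        hist, edges = np.histogram(
            rt[sel] - 0.0, bins=60, range=(table_params.t0, 3.5), density=False
        )
        emp = hist / n
        centers = (edges[:-1] + edges[1:]) / 2
        width = edges[1] - edges[0]
        model = (
            lba.defective_density(centers, "correct", table_params, "Easy", "sentence")
            * width
        )
        tv = 0.5 * np.abs(emp - model).sum()
        assert tv < 0.02


class TestLogLikelihood:
    def _trials(self, rts, correct, missing=None, cond="Easy", ttype="sentence"):
        import pandas as pd

        n = len(rts)
        missing = [False] * n if missing is None else missing
        return pd.DataFrame(
            {
                "condition": [cond] * n,
                "trial_type": [ttype] * n,
                "rt_seconds": rts,
                "correct": correct,
                "missing": missing,
            }
        )

    def test_additivity_over_trials(self, table_params):
        t1 = self._trials([0.8], [True])
        t2 = self._trials([1.2], [False])
        both = self._trials([0.8, 1.2], [True, False])
        ll = lba.log_likelihood(both, table_params)
        assert ll == pytest.approx(
            lba.log_likelihood(t1, table_params)
            + lba.log_likelihood(t2, table_params)
        )

    def test_support_violation_flags_minus_inf(self, table_params):
        bad = self._trials([table_params.t0 / 2], [True])
        with pytest.warns(RuntimeWarning):
            assert lba.log_likelihood(bad, table_params) == -np.inf

    def test_missing_trials_need_latents_beyond_deadline(self, table_params):
        t = self._trials([np.nan], [None], missing=[True])
        with pytest.raises(ValueError):
            lba.log_likelihood(t, table_params)  # no latent supplied
        with pytest.raises(ValueError):
            lba.log_likelihood(t, table_params, [2.0])  # below deadline
        ll = lba.log_likelihood(t, table_params, [3.4])
        assert np.isfinite(ll)

    def test_matches_defective_density_directly(self, table_params):
        t = self._trials([0.9], [True], cond="Med", ttype="null")
        ll = lba.log_likelihood(t, table_params)
        dens = lba.defective_density(0.9, "correct", table_params, "Med", "null")
        assert ll == pytest.approx(np.log(dens))

    def test_generative_parameters_beat_perturbed(self, table_params):
        """The generative likelihood should dominate a drift-shifted
        alternative in nearly every replicate (consistency property)."""
        import pandas as pd

        wins = 0
        n_rep = 20
        v_shift = table_params.v.copy() + 1.0
        shifted = lba.LBAParams(
            A=table_params.A, k=table_params.k, t0=table_params.t0, v=v_shift
        )
        rng = np.random.default_rng(3)
        for rep in range(n_rep):
            choice, rt = lba.simulate_race(
                table_params, "Easy", "sentence", 5000, seed=rng.integers(2**31)
            )
            ok = (choice >= 0) & (rt <= 3.0)
            trials = self._trials(list(rt[ok]), list(choice[ok] == 0))
            if lba.log_likelihood(trials, table_params) >= lba.log_likelihood(
                trials, shifted
            ):
                wins += 1
        assert wins >= int(0.95 * n_rep)

    def test_fast_kernel_matches_reference(self):
        rng = np.random.default_rng(5)
        n = 2000
        rt = rng.uniform(0.25, 2.9, n)
        w = rng.integers(0, 2, n)
        vc = rng.uniform(0.5, 6.0, n)
        vi = rng.uniform(0.1, 2.0, n)
        ref = lba.trial_log_likelihood(rt, w, vc, vi, 1.0, 3.2, 0.2)
        fast = lba.trial_log_likelihood_fast(
            rt, w, vc, vi, np.full(n, 1.0), np.full(n, 3.2), np.full(n, 0.2)
        )
        # agreement wherever the density is not vanishingly small; in the
        # extreme tail both forms lose precision to cancellation
        body = ref > -25
        assert np.allclose(ref[body], fast[body], atol=1e-6)
        assert np.all(np.abs(ref - fast) < 1.0)
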