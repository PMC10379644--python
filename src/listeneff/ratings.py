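"""Ordered-beta regression for bounded ratings and unequal-variance
Gaussian group models.

Visual-analog ratings live on a closed [0, 1] scale and routinely pile up
at the endpoints.  Ordered beta regression handles this with a three-part
mixture driven by a single latent logistic scale: ordered cutpoints
``c1 < c2`` split the scale into a point mass at 0, a continuous
beta-distributed interior, and a point mass at 1,

    P(y = 0)      = 1 - logistic(eta - c1)
    P(0 < y < 1)  = logistic(eta - c1) - logistic(eta - c2)
    P(y = 1)      = logistic(eta - c2)
    y | interior  ~ Beta(mu * phi, (1 - mu) * phi),  mu = logistic(eta)

The rating model regresses the linear predictor on group x condition cell
means plus participant random intercepts with group-specific SDs.  Age and
momentary-fatigue outcomes use an unequal-variance Gaussian group model
instead, which is fully conjugate and sampled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .samplers import AdaptiveBlock, metropolis_accept

__all__ = [
    "ordered_beta_component_probs",
    "ordered_beta_loglik",
    "ordered_beta_mean",
    "ordered_beta_rvs",
    "fit_rating_model",
    "RatingFit",
    "fit_gaussian_unequal",
    "GaussianGroupFit",
    "QUESTIONNAIRE_RANGES",
    "to_unit_interval",
    "from_unit_interval",
]

#: Published score ranges used to rescale questionnaire totals onto [0, 1].
#: FAS is built from 10 items scored 1-5, so its constructed range is
#: 10-40 (the floor of 10 matters for the rescaling).
QUESTIONNAIRE_RANGES = {
    "EAS": (0.0, 60.0),
    "FAS": (10.0, 40.0),
    "HHQ": (0.0, 100.0),
    "SSQ12": (0.0, 10.0),
}


def to_unit_interval(score, instrument: str):
    lo, hi = QUESTIONNAIRE_RANGES[instrument]
    return (np.asarray(score, dtype=float) - lo) / (hi - lo)


def from_unit_interval(value, instrument: str):
    lo, hi = QUESTIONNAIRE_RANGES[instrument]
    return lo + np.asarray(value, dtype=float) * (hi - lo)


def _validate_ob(c1, c2, phi) -> None:
    if not c1 < c2:
        raise ValueError(f"cutpoints must be ordered: c1={c1} >= c2={c2}")
    if not phi > 0:
        raise ValueError(f"precision phi must be > 0, got {phi}")


def ordered_beta_component_probs(eta, c1, c2):
    """(P(y=0), P(0<y<1), P(y=1)) for linear predictor ``eta``."""
    _validate_ob(c1, c2, 1.0)
    eta = np.asarray(eta, dtype=float)
    p0 = special.expit(c1 - eta)
    p1 = special.expit(eta - c2)
    pm = special.expit(eta - c1) - p1
    return p0, pm, p1


def ordered_beta_loglik(y, eta, c1, c2, phi):
    """Log density/mass of the ordered-beta model, vectorised over ``y``."""
    _validate_ob(c1, c2, phi)
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("ratings must lie in [0, 1]")
    eta = np.broadcast_to(np.asarray(eta, dtype=float), y.shape)
    p0, pm, p1 = ordered_beta_component_probs(eta, c1, c2)
    mu = special.expit(eta)
    tiny = 1e-300
    out = np.empty(y.shape)
    at0 = y == 0.0
    at1 = y == 1.0
    mid = ~(at0 | at1)
    out[at0] = np.log(np.clip(p0[at0], tiny, None))
    out[at1] = np.log(np.clip(p1[at1], tiny, None))
    if mid.any():
        a = mu[mid] * phi
        b = (1.0 - mu[mid]) * phi
        out[mid] = np.log(np.clip(pm[mid], tiny, None)) + stats.beta.logpdf(
            y[mid], a, b
        )
    return out if out.ndim else float(out)


def ordered_beta_mean(eta, c1, c2, phi):
    """Analytic mean of the three-part mixture: ``P(y=1) + P(mid) * mu``."""
    _validate_ob(c1, c2, phi)
    p0, pm, p1 = ordered_beta_component_probs(eta, c1, c2)
    return p1 + pm * special.expit(np.asarray(eta, dtype=float))


def ordered_beta_rvs(eta, c1, c2, phi, rng=None):
    """Draw ratings from the ordered-beta model (vectorised over ``eta``)."""
    _validate_ob(c1, c2, phi)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    p0, pm, p1 = ordered_beta_component_probs(eta, c1, c2)
    u = rng.random(eta.shape)
    mu = special.expit(eta)
    y = np.empty(eta.shape)
    at0 = u < p0
    at1 = u >= p0 + pm
    mid = ~(at0 | at1)
    y[at0] = 0.0
    y[at1] = 1.0
    if mid.any():
        y[mid] = rng.beta(mu[mid] * phi, (1.0 - mu[mid]) * phi)
    return y if y.size > 1 else float(y[0])


# ---------------------------------------------------------------------------
# Bayesian rating-model fit
# ---------------------------------------------------------------------------

_PRIOR_BETA_SD = 5.0
_PRIOR_CUT_SD = 5.0
_PRIOR_PHI_RATE = 0.1
_PRIOR_TAU_SCALE = 1.0


@dataclass
class RatingFit:
    """Posterior draws of an ordered-beta rating model.

    ``cell_means`` has shape (chains, iters, n_cells): predicted means on
    the [0, 1] response scale per group x condition cell (population-level
    random intercept at zero).
    """

    cells: list[tuple[str, str]]  # (group, condition)
    beta: np.ndarray  # (chains, iters, n_cells)
    cutpoints: np.ndarray  # (chains, iters, 2)
    phi: np.ndarray  # (chains, iters)
    tau: np.ndarray  # (chains, iters, n_groups)
    groups: list[str]
    cell_means: np.ndarray  # (chains, iters, n_cells)

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        from .metrics import hdi

        rows = []
        flat = self.cell_means.reshape(-1, self.cell_means.shape[-1])
        for j, (g, cond) in enumerate(self.cells):
            lo, hi = hdi(flat[:, j], mass=mass)
            rows.append(
                {
                    "group": g,
                    "condition": cond,
                    "mean": float(flat[:, j].mean()),
                    "cri_low": lo,
                    "cri_high": hi,
                }
            )
        return pd.DataFrame(rows)

    def rhat(self) -> dict[str, float]:
        from .hier import rhat as _rhat

        out = {}
        for j, (g, cond) in enumerate(self.cells):
            out[f"cell_mean[{g},{cond}]"] = _rhat(self.cell_means[:, :, j])
        out["phi"] = _rhat(self.phi)
        return out


def fit_rating_model(
    ratings: pd.DataFrame,
    *,
    chains: int = 4,
    warmup: int = 500,
    iters: int = 500,
    thin: int = 3,
    seed=None,
) -> RatingFit:
    """Fit the ordered-beta cell-means model with participant random
    intercepts (group-specific SD) by blocked adaptive MCMC.

    ``ratings`` must carry columns participant_id, group, condition and
    rating for a single question; every group x condition cell must be
    observed.
    """
    required = {"participant_id", "group", "condition", "rating"}
    if not required.issubset(ratings.columns):
        raise ValueError(f"ratings table must have columns {sorted(required)}")
    if "question" in ratings.columns and ratings["question"].nunique() > 1:
        raise ValueError("fit one question at a time")
    y = ratings["rating"].to_numpy(dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("ratings must lie in [0, 1]")

    groups = sorted(ratings["group"].unique())
    conditions = list(pd.unique(ratings["condition"]))
    cells = [(g, c) for g in groups for c in conditions]
    cell_of = {gc: j for j, gc in enumerate(cells)}
    cell_idx = np.array(
        [cell_of[(g, c)] for g, c in zip(ratings["group"], ratings["condition"])]
    )
    counts = np.bincount(cell_idx, minlength=len(cells))
    if np.any(counts == 0):
        empty = [cells[j] for j in np.where(counts == 0)[0]]
        raise ValueError(f"empty group x condition cells: {empty}")
    pids = list(pd.unique(ratings["participant_id"]))
    pid_of = {p: i for i, p in enumerate(pids)}
    p_idx = np.array([pid_of[p] for p in ratings["participant_id"]])
    pgroup = np.array(
        [groups.index(ratings["group"].iloc[np.argmax(p_idx == i)]) for i in range(len(pids))]
    )

    n_cells, n_p = len(cells), len(pids)
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    chain_seeds = ss.spawn(chains)

    all_beta = np.empty((chains, iters, n_cells))
    all_cut = np.empty((chains, iters, 2))
    all_phi = np.empty((chains, iters))
    all_tau = np.empty((chains, iters, len(groups)))

    for ch in range(chains):
        rng = np.random.default_rng(chain_seeds[ch])
        # crude data-driven initialisation, jittered per chain
        cellmeans = np.array(
            [np.clip(y[cell_idx == j].mean(), 0.02, 0.98) for j in range(n_cells)]
        )
        beta = special.logit(cellmeans) + 0.1 * rng.standard_normal(n_cells)
        u = np.zeros(n_p)
        c1, c2 = -3.0 + 0.2 * rng.standard_normal(), 3.0 + 0.2 * rng.standard_normal()
        logphi = np.log(5.0) + 0.1 * rng.standard_normal()
        tau = np.full(len(groups), 0.5)

        ab_beta = AdaptiveBlock(n_cells, 1, init_scale=0.3)
        ab_u = AdaptiveBlock(n_p, 1, init_scale=0.3)
        ab_shape = AdaptiveBlock(1, 3, init_scale=0.15)
        ab_tau = AdaptiveBlock(len(groups), 1, init_scale=0.3)

        def obs_loglik(beta_, u_, c1_, c2_, phi_):
            eta = beta_[cell_idx] + u_[p_idx]
            return ordered_beta_loglik(y, eta, c1_, c2_, phi_)

        def sweep(warmup_phase: bool):
            nonlocal beta, u, c1, c2, logphi, tau
            phi = np.exp(logphi)
            # cell effects: conditionally independent given u
            prop = ab_beta.propose(beta[:, None], rng)[:, 0]
            ll_old = np.bincount(
                cell_idx, weights=obs_loglik(beta, u, c1, c2, phi), minlength=n_cells
            )
            ll_new = np.bincount(
                cell_idx, weights=obs_loglik(prop, u, c1, c2, phi), minlength=n_cells
            )
            lp_old = ll_old - 0.5 * (beta / _PRIOR_BETA_SD) ** 2
            lp_new = ll_new - 0.5 * (prop / _PRIOR_BETA_SD) ** 2
            acc = metropolis_accept(lp_new, lp_old, rng)
            beta = np.where(acc, prop, beta)
            if warmup_phase:
                ab_beta.adapt(acc)
                ab_beta.observe(beta[:, None])
            # participant intercepts: conditionally independent given beta
            propu = ab_u.propose(u[:, None], rng)[:, 0]
            llu_old = np.bincount(
                p_idx, weights=obs_loglik(beta, u, c1, c2, phi), minlength=n_p
            )
            llu_new = np.bincount(
                p_idx, weights=obs_loglik(beta, propu, c1, c2, phi), minlength=n_p
            )
            tau_p = tau[pgroup]
            lpu_old = llu_old - 0.5 * (u / tau_p) ** 2
            lpu_new = llu_new - 0.5 * (propu / tau_p) ** 2
            accu = metropolis_accept(lpu_new, lpu_old, rng)
            u = np.where(accu, propu, u)
            if warmup_phase:
                ab_u.adapt(accu)
                ab_u.observe(u[:, None])
            # cutpoints and precision
            cur = np.array([[c1, c2, logphi]])
            props = ab_shape.propose(cur, rng)[0]
            c1n, c2n, logphin = props
            if c1n < c2n:
                lp_old_s = (
                    obs_loglik(beta, u, c1, c2, phi).sum()
                    - 0.5 * (c1 / _PRIOR_CUT_SD) ** 2
                    - 0.5 * (c2 / _PRIOR_CUT_SD) ** 2
                    - _PRIOR_PHI_RATE * phi
                    + logphi
                )
                phin = np.exp(logphin)
                lp_new_s = (
                    obs_loglik(beta, u, c1n, c2n, phin).sum()
                    - 0.5 * (c1n / _PRIOR_CUT_SD) ** 2
                    - 0.5 * (c2n / _PRIOR_CUT_SD) ** 2
                    - _PRIOR_PHI_RATE * phin
                    + logphin
                )
                acc_s = metropolis_accept(
                    np.array([lp_new_s]), np.array([lp_old_s]), rng
                )
                if acc_s[0]:
                    c1, c2, logphi = c1n, c2n, logphin
            else:
                acc_s = np.array([False])
            if warmup_phase:
                ab_shape.adapt(acc_s)
                ab_shape.observe(np.array([[c1, c2, logphi]]))
            # group intercept SDs: half-normal prior, log-scale RWM
            logtau = np.log(tau)
            propt = ab_tau.propose(logtau[:, None], rng)[:, 0]
            taun = np.exp(propt)

            def tau_logp(t):
                out = np.empty(len(groups))
                for gi in range(len(groups)):
                    ug = u[pgroup == gi]
                    out[gi] = (
                        -len(ug) * np.log(t[gi])
                        - 0.5 * np.sum((ug / t[gi]) ** 2)
                        - 0.5 * (t[gi] / _PRIOR_TAU_SCALE) ** 2
                        + np.log(t[gi])  # Jacobian of the log transform
                    )
                return out

            acct = metropolis_accept(tau_logp(taun), tau_logp(tau), rng)
            tau = np.where(acct, taun, tau)
            if warmup_phase:
                ab_tau.adapt(acct)
                ab_tau.observe(np.log(tau)[:, None])

        for _ in range(warmup):
            sweep(True)
        for ab in (ab_beta, ab_u, ab_shape, ab_tau):
            ab.freeze()
        for it in range(iters):
            for _ in range(thin):
                sweep(False)
            all_beta[ch, it] = beta
            all_cut[ch, it] = (c1, c2)
            all_phi[ch, it] = np.exp(logphi)
            all_tau[ch, it] = tau

    cell_means = np.empty_like(all_beta)
    for j in range(n_cells):
        cell_means[:, :, j] = ordered_beta_mean_vec(
            all_beta[:, :, j], all_cut[:, :, 0], all_cut[:, :, 1], all_phi
        )
    return RatingFit(
        cells=cells,
        beta=all_beta,
        cutpoints=all_cut,
        phi=all_phi,
        tau=all_tau,
        groups=groups,
        cell_means=cell_means,
    )


def ordered_beta_mean_vec(eta, c1, c2, phi):
    """Elementwise ordered-beta mean for array-valued parameters."""
    p0 = special.expit(c1 - eta)
    p1 = special.expit(eta - c2)
    pm = special.expit(eta - c1) - p1
    return p1 + pm * special.expit(eta)


# ---------------------------------------------------------------------------
# Unequal-variance Gaussian group model (exact conjugate sampling)
# ---------------------------------------------------------------------------


@dataclass
class GaussianGroupFit:
    groups: list[str]
    mu: dict[str, np.ndarray]
    sigma: dict[str, np.ndarray]

    def difference(self) -> np.ndarray:
        """Per-draw difference of group means, first group minus second."""
        a, b = self.groups[:2]
        return self.mu[a] - self.mu[b]

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        from .metrics import hdi

        rows = []
        for g in self.groups:
            lo, hi = hdi(self.mu[g], mass=mass)
            slo, shi = hdi(self.sigma[g], mass=mass)
            rows.append(
                {
                    "group": g,
                    "mean": float(self.mu[g].mean()),
                    "mean_cri_low": lo,
                    "mean_cri_high": hi,
                    "sd": float(self.sigma[g].mean()),
                    "sd_cri_low": slo,
                    "sd_cri_high": shi,
                }
            )
        return pd.DataFrame(rows)


def fit_gaussian_unequal(
    outcome, group, n_draws: int = 8000, seed=None
) -> GaussianGroupFit:
    """Bayesian Gaussian group model with unequal group variances.

    Under the noninformative prior ``p(mu, sigma^2) ~ 1/sigma^2`` (flat on
    the mean) the posterior is conjugate: ``sigma^2`` is scaled
    inverse-chi-squared on n-1 degrees of freedom and ``mu | sigma^2`` is
    normal, so draws are exact Monte Carlo rather than MCMC.
    """
    outcome = np.asarray(outcome, dtype=float)
    group = np.asarray(group)
    rng = np.random.default_rng(seed)
    groups = sorted(pd.unique(group).tolist())
    mu, sigma = {}, {}
    for g in groups:
        x = outcome[group == g]
        n = len(x)
        if n < 2:
            raise ValueError(f"group {g!r} needs at least 2 observations")
        s2 = x.var(ddof=1)
        sig2 = (n - 1) * s2 / rng.chisquare(n - 1, size=n_draws)
        mu[g] = rng.normal(x.mean(), np.sqrt(sig2 / n))
        sigma[g] = np.sqrt(sig2)
    return GaussianGroupFit(groups=groups, mu=mu, sigma=sigma)
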