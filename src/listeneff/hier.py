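"""Hierarchical Bayesian estimation of the LBA.

Individual 15-dimensional log-parameter vectors (12 drift means plus A, k,
t0, all log-transformed, which keeps every accumulator parameter positive
and the incorrect-response drift identified even at near-ceiling accuracy)
are modelled as multivariate normal within each group; group mean vectors
and covariance matrices are free parameters.
Deadline-censored trials contribute a chance-accuracy likelihood term at a
latent RT above the deadline, sampled alongside the model parameters.

Sampling is blocked Metropolis-within-Gibbs:

* per-participant drift-cell blocks (2 accumulators per condition x trial
  type cell), a structural block (log A, log k, log t0) and a full 15-dim
  joint block move by adaptive Gaussian random walk, vectorised across
  participants (the blocks are conditionally independent given the group
  level);
* group means are conjugate multivariate-normal draws and group covariances
  conjugate inverse-Wishart draws (exact Gibbs);
* dedicated moves traverse the model's soft ridges: a common rescale of
  (A, k, drifts), a t0 shift with exact-Jacobian decision-time
  compensation, group-level translations of weakly identified subspaces,
  a conditional-prior refresh of the incorrect drifts, and a
  deviation-rescale (expansion) move for the structural hierarchy (see
  docs/methods.md);
* latent missing RTs move on a log-offset scale above the deadline.

A non-centered parameterization (individual vectors expressed as
``mu + sigma * xi`` with standard-normal ``xi``) is available with a
diagonal covariance for cross-checking that both parameterizations target
the same posterior.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from . import lba
from .design import N_DRIFTS, N_PARAMS, PARAM_NAMES
from .labels import CONDITIONS, TRIAL_TYPES
from .samplers import AdaptiveBlock, metropolis_accept

__all__ = [
    "Priors",
    "ModelSpec",
    "HierLBAModel",
    "PosteriorDraws",
    "build_model",
    "sample_posterior",
    "rhat",
    "posterior_predictive",
]

DRIFT = slice(0, N_DRIFTS)
STRUCT = slice(N_DRIFTS, N_PARAMS)

RHAT_LOW, RHAT_HIGH = 0.99, 1.01


@dataclass
class Priors:
    """Weakly informative defaults, recovery-validated; all configurable.

    All fifteen parameters enter the individual-level multivariate normal
    on the log scale.  Log-drift means take accumulator-specific normal
    priors: the correct-response accumulator centres on a median rate of
    ``e^1 ~ 2.7`` evidence units/s while the incorrect one centres on
    ``e^-0.5 ~ 0.6``, reflecting that error-evidence accumulation is slow
    in tasks performed well above chance (both with unit log-scale SD, so
    rates from ~0.2 to ~8 stay in easy reach).  ``N(0, 1)`` on log A,
    log k, log t0 spans the sub-second geometry typical of speeded
    two-choice tasks.  The group covariance takes an inverse-Wishart prior
    (conjugate under the centered parameterization); in
    diagonal-covariance mode each variance takes an inverse-gamma prior
    with the same prior mean.
    """

    drift_loc_correct: float = 1.0
    drift_loc_incorrect: float = -0.5
    drift_scale: float = 1.0
    structural_loc: float = 0.0
    structural_scale: float = 1.0
    iw_df: float = N_PARAMS + 3.0
    drift_var_mean: float = 0.04
    structural_var_mean: float = 0.04
    ig_shape: float = 2.5

    def mean_loc(self) -> np.ndarray:
        half = N_DRIFTS // 2
        return np.array(
            [self.drift_loc_correct] * half
            + [self.drift_loc_incorrect] * half
            + [self.structural_loc] * 3
        )

    def mean_scale(self) -> np.ndarray:
        return np.array([self.drift_scale] * N_DRIFTS + [self.structural_scale] * 3)

    def var_mean(self) -> np.ndarray:
        return np.array(
            [self.drift_var_mean] * N_DRIFTS + [self.structural_var_mean] * 3
        )

    def iw_scale(self) -> np.ndarray:
        # E[Sigma] = scale / (df - p - 1)
        return np.diag(self.var_mean()) * (self.iw_df - N_PARAMS - 1)

    def ig_scale(self) -> np.ndarray:
        return (self.ig_shape - 1.0) * self.var_mean()


@dataclass
class ModelSpec:
    """Structure of the hierarchical LBA.

    Twelve drift means (2 accumulators x 3 conditions x 2 trial types) plus
    A, k, t0 give exactly 15 free parameters per participant.  The
    structural parameters are hierarchical within group by default; with
    ``structural_hierarchical=False`` they collapse to a single shared
    value per group.
    """

    conditions: tuple[str, ...] = CONDITIONS
    trial_types: tuple[str, ...] = TRIAL_TYPES
    parameterization: str = "centered"
    covariance: str = "full"  # or "diagonal"
    structural_hierarchical: bool = True
    deadline: float = 3.0
    latent_cap: float = 10.0

    def __post_init__(self) -> None:
        if self.parameterization not in ("centered", "noncentered"):
            raise ValueError("parameterization must be centered or noncentered")
        if self.covariance not in ("full", "diagonal"):
            raise ValueError("covariance must be full or diagonal")
        if self.parameterization == "noncentered" and self.covariance == "full":
            raise ValueError(
                "the non-centered parameterization is provided with a "
                "diagonal covariance only"
            )
        if len(self.conditions) != 3:
            raise ValueError("exactly three conditions are required")

    @property
    def n_free_per_participant(self) -> int:
        return N_PARAMS

    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES


def _drift_flat_index(acc: int, cond: int, ttype: int) -> int:
    return acc * (len(CONDITIONS) * len(TRIAL_TYPES)) + cond * len(TRIAL_TYPES) + ttype


class HierLBAModel:
    """Prepared data + spec + priors; see :func:`build_model`."""

    def __init__(self, trials: pd.DataFrame, spec: ModelSpec, priors: Priors):
        self.spec = spec
        self.priors = priors
        self.groups = sorted(trials["group"].unique())
        self.participants: dict[str, list[str]] = {
            g: sorted(trials.loc[trials["group"] == g, "participant_id"].unique())
            for g in self.groups
        }
        order = [p for g in self.groups for p in self.participants[g]]
        self.participant_order = order
        self.group_of = {
            p: g for g in self.groups for p in self.participants[g]
        }
        pid_index = {p: i for i, p in enumerate(order)}
        self.n_participants = len(order)
        self.group_index = np.array(
            [self.groups.index(self.group_of[p]) for p in order]
        )

        bad_cond = set(trials["condition"]) - set(spec.conditions)
        bad_type = set(trials["trial_type"]) - set(spec.trial_types)
        if bad_cond or bad_type:
            raise ValueError(
                f"unknown labels: conditions {sorted(bad_cond)}, "
                f"trial types {sorted(bad_type)}"
            )

        cond_idx = np.array(
            [spec.conditions.index(c) for c in trials["condition"]]
        )
        type_idx = np.array(
            [spec.trial_types.index(t) for t in trials["trial_type"]]
        )
        # every group x condition x trial-type cell must carry data
        for g in self.groups:
            for ci, c in enumerate(spec.conditions):
                for ti, t in enumerate(spec.trial_types):
                    m = (
                        (trials["group"] == g).to_numpy()
                        & (cond_idx == ci)
                        & (type_idx == ti)
                        & (~trials["missing"].to_numpy().astype(bool))
                    )
                    if not m.any():
                        raise ValueError(
                            f"empty cell: group={g}, condition={c}, trial_type={t}"
                        )

        missing = trials["missing"].to_numpy().astype(bool)
        obs = ~missing
        self.obs_p = np.array(
            [pid_index[p] for p in trials.loc[obs, "participant_id"]]
        )
        oc, ot = cond_idx[obs], type_idx[obs]
        self.obs_vc_idx = _drift_flat_index(0, 0, 0) + oc * len(TRIAL_TYPES) + ot
        self.obs_vi_idx = self.obs_vc_idx + len(CONDITIONS) * len(TRIAL_TYPES)
        self.obs_cell = oc * len(TRIAL_TYPES) + ot
        self.obs_winner = np.where(
            trials.loc[obs, "correct"].to_numpy().astype(bool), 0, 1
        )
        self.obs_rt = trials.loc[obs, "rt_seconds"].to_numpy(dtype=float)
        if np.any(~np.isfinite(self.obs_rt)) or np.any(self.obs_rt <= 0):
            raise ValueError("observed trials must have finite positive RTs")

        self.mis_p = np.array(
            [pid_index[p] for p in trials.loc[missing, "participant_id"]],
            dtype=int,
        )
        mc, mt = cond_idx[missing], type_idx[missing]
        self.mis_cell = mc * len(TRIAL_TYPES) + mt
        self.mis_vc_idx = mc * len(TRIAL_TYPES) + mt
        self.mis_vi_idx = self.mis_vc_idx + N_DRIFTS // 2
        self.n_missing = int(missing.sum())

        self.obs_p = self.obs_p.astype(np.int64)
        self.obs_vc_idx = self.obs_vc_idx.astype(np.int64)
        self.obs_vi_idx = self.obs_vi_idx.astype(np.int64)
        self.obs_winner = self.obs_winner.astype(np.int64)
        self.mis_p = self.mis_p.astype(np.int64)
        self.mis_vc_idx = np.asarray(self.mis_vc_idx, dtype=np.int64)
        self.mis_vi_idx = np.asarray(self.mis_vi_idx, dtype=np.int64)
        self._all_obs_idx = np.arange(len(self.obs_rt), dtype=np.int64)
        self._all_mis_idx = np.arange(self.n_missing, dtype=np.int64)

        # t0 must stay below each participant's fastest observed response
        min_rt = np.full(self.n_participants, np.inf)
        np.minimum.at(min_rt, self.obs_p, self.obs_rt)
        self.log_t0_max = np.log(np.clip(min_rt - 1e-3, 1e-3, None))

    # -- likelihood ---------------------------------------------------------

    def _theta_to_natural(self, theta: np.ndarray):
        """Log model scale -> natural-scale arrays. theta: (n_p, 15)."""
        drifts = np.ascontiguousarray(np.exp(theta[:, DRIFT]))
        A = np.ascontiguousarray(np.exp(theta[:, N_DRIFTS]))
        k = np.exp(theta[:, N_DRIFTS + 1])
        t0 = np.exp(theta[:, N_DRIFTS + 2])
        return drifts, A, A + k, t0

    def obs_loglik(self, theta: np.ndarray, subset=None) -> np.ndarray:
        """Per-participant summed log-likelihood of (a subset of) observed
        trials under model-scale ``theta`` (n_p, 15).

        Uses the fused gather/density/reduce kernel (sv = 1, the model's
        scaling constraint) when numba is available; the numpy reference
        path otherwise.  Equality of the two paths with the lba-module
        densities is covered by tests.
        """
        drifts, A, b, t0 = self._theta_to_natural(theta)
        idx = self._all_obs_idx if subset is None else subset
        if lba.HAVE_NUMBA:
            out = np.zeros(self.n_participants)
            lba._obs_ll_sums(
                drifts, A, b, t0, self.obs_p, self.obs_vc_idx,
                self.obs_vi_idx, self.obs_winner, self.obs_rt, idx, out,
            )
            return out
        p = self.obs_p[idx]
        ll = lba.trial_log_likelihood(
            self.obs_rt[idx],
            self.obs_winner[idx],
            drifts[p, self.obs_vc_idx[idx]],
            drifts[p, self.obs_vi_idx[idx]],
            A[p],
            b[p],
            t0[p],
        )
        return np.bincount(p, weights=ll, minlength=self.n_participants)

    def mis_loglik(self, theta: np.ndarray, latents: np.ndarray, subset=None):
        """Per-participant chance-accuracy terms of (a subset of) missing
        trials at their latent RTs."""
        if self.n_missing == 0:
            return np.zeros(self.n_participants)
        drifts, A, b, t0 = self._theta_to_natural(theta)
        idx = self._all_mis_idx if subset is None else subset
        if lba.HAVE_NUMBA:
            out = np.zeros(self.n_participants)
            lba._mis_ll_sums(
                drifts, A, b, t0, self.mis_p, self.mis_vc_idx,
                self.mis_vi_idx, latents, idx, out,
            )
            return out
        p = self.mis_p[idx]
        ll = lba.missing_log_likelihood(
            latents[idx],
            drifts[p, self.mis_vc_idx[idx]],
            drifts[p, self.mis_vi_idx[idx]],
            A[p],
            b[p],
            t0[p],
        )
        return np.bincount(p, weights=ll, minlength=self.n_participants)

    def participant_loglik(self, theta: np.ndarray, latents=None) -> np.ndarray:
        latents = np.empty(0) if latents is None else latents
        out = self.obs_loglik(theta)
        if self.n_missing:
            out = out + self.mis_loglik(theta, latents)
        return out

    def mis_loglik_per_trial(self, theta: np.ndarray, latents: np.ndarray):
        drifts, A, b, t0 = self._theta_to_natural(theta)
        p = self.mis_p
        return lba.missing_log_likelihood_fast(
            latents, drifts[p, self.mis_vc_idx], drifts[p, self.mis_vi_idx],
            A[p], b[p], t0[p],
        )

    # -- joint log density (oracle-checkable) -------------------------------

    def log_density(self, theta: np.ndarray, mu: dict, cov: dict,
                    latents=None) -> float:
        """Joint unnormalised log density of (theta, mu, Sigma, latents).

        ``theta`` is (n_p, 15) on the model scale, ``mu[g]`` a 15-vector,
        ``cov[g]`` a 15x15 covariance.  Latent RTs enter through the
        chance-accuracy likelihood only (their density on the natural
        scale).  Used by tests as an independently assemblable oracle.
        """
        lp = float(np.sum(self.participant_loglik(theta, latents)))
        loc, scale = self.priors.mean_loc(), self.priors.mean_scale()
        for gi, g in enumerate(self.groups):
            member = self.group_index == gi
            lp += float(
                stats.multivariate_normal.logpdf(
                    theta[member], mean=mu[g], cov=cov[g]
                ).sum()
            )
            lp += float(stats.norm.logpdf(mu[g], loc, scale).sum())
            lp += float(
                stats.invwishart.logpdf(
                    cov[g], df=self.priors.iw_df, scale=self.priors.iw_scale()
                )
            )
        return lp


def build_model(
    trials: pd.DataFrame, spec: ModelSpec | None = None, priors: Priors | None = None
) -> HierLBAModel:
    """Validate trials and assemble the hierarchical LBA model."""
    return HierLBAModel(trials, spec or ModelSpec(), priors or Priors())


# ---------------------------------------------------------------------------
# Posterior container and diagnostics
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Labelled MCMC draws with chain metadata and convergence diagnostics.

    Group-level arrays are on the model (log) scale for all 15 parameters.
    ``theta[g]`` holds the individual-level draws, shape
    (chains, iters, n_participants_in_group, 15).
    """

    groups: list[str]
    participants: dict[str, list[str]]
    mu: dict[str, np.ndarray]  # (chains, iters, 15)
    sigma: dict[str, np.ndarray]  # (chains, iters, 15) marginal SDs
    theta: dict[str, np.ndarray]  # (chains, iters, n_pg, 15)
    chains: int
    warmup: int
    iters: int
    thin: int
    seed: object
    rhat: dict[str, float] = field(default_factory=dict)
    sampler_info: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.chains * self.iters

    def flat_mu(self, group: str) -> np.ndarray:
        """(n_draws, 15) group-mean draws."""
        return self.mu[group].reshape(-1, N_PARAMS)

    def flat_theta(self, group: str) -> np.ndarray:
        """(n_draws, n_pg, 15) individual draws."""
        a = self.theta[group]
        return a.reshape(-1, a.shape[2], N_PARAMS)

    def check_convergence(self) -> list[str]:
        """Names of parameters whose R-hat falls outside [0.99, 1.01]."""
        bad = [
            name
            for name, r in self.rhat.items()
            if not (RHAT_LOW <= r <= RHAT_HIGH)
        ]
        if bad:
            warnings.warn(
                f"R-hat outside [{RHAT_LOW}, {RHAT_HIGH}] for: {', '.join(bad)}",
                RuntimeWarning,
                stacklevel=2,
            )
        return bad

    def to_files(self, draws_csv, sidecar_json, include_individual=False) -> None:
        """Persist tidy draws (chain, iter, parameter, value) + JSON sidecar."""
        rows = []
        for g in self.groups:
            for j, name in enumerate(PARAM_NAMES):
                for ch in range(self.chains):
                    for it in range(self.iters):
                        rows.append(
                            (ch, it, f"mu[{g},{name}]", self.mu[g][ch, it, j])
                        )
                        rows.append(
                            (ch, it, f"sigma[{g},{name}]", self.sigma[g][ch, it, j])
                        )
            if include_individual:
                for pi, pid in enumerate(self.participants[g]):
                    for j, name in enumerate(PARAM_NAMES):
                        for ch in range(self.chains):
                            for it in range(self.iters):
                                rows.append(
                                    (
                                        ch,
                                        it,
                                        f"theta[{pid},{name}]",
                                        self.theta[g][ch, it, pi, j],
                                    )
                                )
        pd.DataFrame(rows, columns=["chain", "iter", "parameter", "value"]).to_csv(
            draws_csv, index=False
        )
        with open(sidecar_json, "w") as fh:
            json.dump(
                {
                    "rhat": self.rhat,
                    "chains": self.chains,
                    "warmup": self.warmup,
                    "iters": self.iters,
                    "thin": self.thin,
                    "seed": repr(self.seed),
                    **self.sampler_info,
                },
                fh,
                indent=2,
            )


def rhat(draws: np.ndarray) -> float:
    """Rank-normalised split R-hat of draws shaped (chains, iterations).

    Returns NaN (flagging the parameter) when the draws are constant, so a
    degenerate chain is never silently reported as converged.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must be 2-D (chains, iterations)")
    if draws.shape[0] < 2:
        raise ValueError("R-hat needs at least 2 chains")
    if draws.shape[1] < 4:
        raise ValueError("R-hat needs at least 4 draws per chain")
    if np.allclose(draws, draws.flat[0]):
        return float("nan")
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(draws))


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

_CELLS = len(CONDITIONS) * len(TRIAL_TYPES)


def _initial_theta(model: HierLBAModel, rng: np.random.Generator) -> np.ndarray:
    """Crude data-independent start, jittered per chain; t0 respects the
    per-participant minimum-RT constraint."""
    theta = np.empty((model.n_participants, N_PARAMS))
    theta[:, DRIFT] = np.log(3.0) + 0.1 * rng.standard_normal(
        (model.n_participants, N_DRIFTS)
    )
    vi_cols = np.arange(N_DRIFTS // 2, N_DRIFTS)
    theta[:, vi_cols] = np.log(0.8) + 0.1 * rng.standard_normal(
        (model.n_participants, N_DRIFTS // 2)
    )
    theta[:, N_DRIFTS] = np.log(1.0) + 0.1 * rng.standard_normal(model.n_participants)
    theta[:, N_DRIFTS + 1] = np.log(2.0) + 0.1 * rng.standard_normal(
        model.n_participants
    )
    t0_init = np.minimum(np.log(0.15), model.log_t0_max - 0.5)
    theta[:, N_DRIFTS + 2] = t0_init + 0.05 * rng.standard_normal(model.n_participants)
    return theta


def sample_posterior(
    model: HierLBAModel,
    chains: int = 4,
    warmup: int = 1000,
    iters: int = 2000,
    seed=None,
    thin: int = 5,
    progress: bool = False,
) -> PosteriorDraws:
    """Run the blocked Gibbs sampler; returns ``chains x iters`` retained
    draws (8,000 at the default four chains of 2,000).

    ``thin`` internal sweeps are run per retained iteration; warmup sweeps
    adapt the random-walk proposal scales, which are then frozen.  R-hat is
    computed for every group-level parameter and a warning lists any
    outside [0.99, 1.01].
    """
    spec = model.spec
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    chain_seeds = ss.spawn(chains)
    n_p = model.n_participants
    groups = model.groups
    n_groups = len(groups)
    members = [np.where(model.group_index == gi)[0] for gi in range(n_groups)]

    mu_store = {g: np.empty((chains, iters, N_PARAMS)) for g in groups}
    sd_store = {g: np.empty((chains, iters, N_PARAMS)) for g in groups}
    th_store = {
        g: np.empty((chains, iters, len(members[gi]), N_PARAMS))
        for gi, g in enumerate(groups)
    }

    centered = spec.parameterization == "centered"
    runner = _run_chain_centered if centered else _run_chain_noncentered
    accept_rates = {}
    for ch in range(chains):
        rng = np.random.default_rng(chain_seeds[ch])
        accept_rates[f"chain_{ch}"] = runner(
            model, rng, warmup, iters, thin, members,
            lambda it, mu, sd, theta, ch=ch: _store(
                mu_store, sd_store, th_store, groups, members, ch, it, mu, sd, theta
            ),
            progress,
        )

    draws = PosteriorDraws(
        groups=groups,
        participants=model.participants,
        mu=mu_store,
        sigma=sd_store,
        theta=th_store,
        chains=chains,
        warmup=warmup,
        iters=iters,
        thin=thin,
        seed=seed,
        sampler_info={
            "parameterization": spec.parameterization,
            "covariance": spec.covariance,
            "structural_hierarchical": spec.structural_hierarchical,
            "algorithm": "blocked adaptive Metropolis-within-Gibbs",
            "acceptance_rates": accept_rates,
        },
    )
    rh = {}
    for g in groups:
        for j, name in enumerate(PARAM_NAMES):
            rh[f"mu[{g},{name}]"] = rhat(draws.mu[g][:, :, j]) if chains > 1 else float("nan")
            if spec.structural_hierarchical or j < N_DRIFTS:
                rh[f"sigma[{g},{name}]"] = (
                    rhat(draws.sigma[g][:, :, j]) if chains > 1 else float("nan")
                )
    draws.rhat = rh
    if chains > 1:
        draws.check_convergence()
    return draws


def _store(mu_store, sd_store, th_store, groups, members, ch, it, mu, sd, theta):
    for gi, g in enumerate(groups):
        mu_store[g][ch, it] = mu[gi]
        sd_store[g][ch, it] = sd[gi]
        th_store[g][ch, it] = theta[members[gi]]


def _run_chain_centered(model, rng, warmup, iters, thin, members, store, progress):
    spec, priors = model.spec, model.priors
    n_p = model.n_participants
    n_groups = len(members)
    theta = _initial_theta(model, rng)
    if not spec.structural_hierarchical:
        # shared structural parameters start at the group mean, with t0
        # safely below every member's fastest observed response
        for gi in range(n_groups):
            shared = theta[members[gi], STRUCT].mean(axis=0)
            shared[2] = min(shared[2], model.log_t0_max[members[gi]].min() - 0.5)
            theta[members[gi], STRUCT] = shared
    latents = np.full(model.n_missing, spec.deadline + 0.3)
    u_lat = np.log(latents - spec.deadline)
    u_cap = np.log(spec.latent_cap - spec.deadline)

    mu = [theta[members[gi]].mean(axis=0) for gi in range(n_groups)]
    cov = [np.diag(priors.var_mean()) for _ in range(n_groups)]
    lam = [np.linalg.inv(c) for c in cov]

    hier_struct = spec.structural_hierarchical
    diagonal = spec.covariance == "diagonal"

    # observed/missing trial indices per drift cell
    cell_obs = [np.where(model.obs_cell == c)[0] for c in range(_CELLS)]
    cell_mis = [np.where(model.mis_cell == c)[0] for c in range(_CELLS)]

    ab_cells = [
        AdaptiveBlock(n_p, 2, init_scale=0.25, full_cov=True)
        for _ in range(_CELLS)
    ]
    ab_struct = AdaptiveBlock(
        n_groups if not hier_struct else n_p, 3, init_scale=0.1, full_cov=True
    )
    ab_lat = AdaptiveBlock(max(model.n_missing, 1), 1, init_scale=0.5)
    # A shift/scale trade-off (t0 vs threshold vs drifts) makes the joint
    # posterior ridge-like across blocks; a full 15-dim correlated move per
    # participant travels along that ridge.
    ab_joint = AdaptiveBlock(n_p, N_PARAMS, init_scale=0.05, full_cov=True,
                             target_accept=0.25)
    struct_repeats = 2
    joint_repeats = 1
    # Group-shift move: translate a group's mean and every member's vector
    # by the same delta.  Individual deviations (and hence the hierarchy's
    # prior terms) are untouched, so the whole group can travel along the
    # shared likelihood ridge without fighting the pooling prior.
    ab_shift = AdaptiveBlock(n_groups, N_PARAMS, init_scale=0.03,
                             full_cov=True, target_accept=0.25)
    shift_repeats = 1
    # Scale move: with decision times (b - a)/v invariant under a common
    # rescaling of A, k and all drifts, the posterior has a near-exact
    # scaling ridge constrained only through the fixed sv = 1.  Translate
    # log A, log k and all log drifts of a group (mean + members) by the
    # same amount to traverse it.
    SCALE_COLS = np.concatenate([np.arange(N_DRIFTS), [N_DRIFTS, N_DRIFTS + 1]])
    ab_scale = AdaptiveBlock(n_groups, 1, init_scale=0.02, target_accept=0.35)
    scale_repeats = 4
    # t0-shift move: add delta seconds to every member's non-decision time
    # and rescale A, k and drifts so each member's mean decision time
    # shrinks by delta, approximately preserving the RT distribution.  The
    # deterministic compensation uses the member's fixed mean observed RT,
    # so the map is triangular with log-Jacobian sum(log(t0/(t0+delta))).
    ab_t0shift = AdaptiveBlock(n_groups, 1, init_scale=0.02, target_accept=0.35)
    t0shift_repeats = 8
    # incorrect-accumulator drift coordinates: barely constrained by the
    # data at near-ceiling accuracy (see the refresh and shift moves below)
    VI = np.arange(N_DRIFTS // 2, N_DRIFTS)
    NOT_VI = np.concatenate([np.arange(N_DRIFTS // 2), np.arange(N_DRIFTS, N_PARAMS)])
    # per-participant variants of the same two ridge moves
    ab_t0shift_i = AdaptiveBlock(n_p, 1, init_scale=0.02, target_accept=0.35)
    ab_scale_i = AdaptiveBlock(n_p, 1, init_scale=0.03, target_accept=0.35)
    indiv_ridge_repeats = 2
    # Incorrect-drift group shift: at near-ceiling accuracy the likelihood
    # hardly constrains the incorrect accumulators, so their group means
    # have wide marginals that a centered Gibbs cycle crosses only in
    # sigma/sqrt(n) steps; and what little the data say couples them to
    # (A, k, t0) through the RT tail.  Shifting mu and every member
    # together on the joint (incorrect-drift + structural) block, with a
    # full adapted covariance, jumps at the marginal scale along that
    # coupled direction.
    ab_vishift = AdaptiveBlock(n_groups, len(VI), init_scale=0.3,
                               target_accept=0.3)
    vishift_repeats = 3
    # structural-only group shift (3x3 covariance learns the A-k trade)
    ab_structshift = AdaptiveBlock(n_groups, 3, init_scale=0.05,
                                   full_cov=True, target_accept=0.3)
    structshift_repeats = 10
    # deviation-rescale (expansion) move: multiply every member's
    # structural deviation from the group mean by e^eps (one eps per
    # coordinate), Jacobian n_g * eps each.  This is the standard funnel
    # cure for centered hierarchies: the ensemble spread can change in one
    # jump instead of via n_g individual random walks.
    ab_spread = AdaptiveBlock(n_groups, 3, init_scale=0.1, target_accept=0.3)
    spread_repeats = 4
    rbar = np.full(n_p, np.nan)
    for i in range(n_p):
        sel = model.obs_p == i
        rbar[i] = model.obs_rt[sel].mean() if sel.any() else np.nan
    rbar_group = np.array([np.nanmean(rbar[members[gi]]) for gi in range(n_groups)])

    m0, s0 = priors.mean_loc(), priors.mean_scale()
    prior_prec0 = 1.0 / s0**2


    def prior_quad(th):
        """Per-participant MVN prior log-density kernel (no constant)."""
        out = np.empty(n_p)
        for gi in range(n_groups):
            d = th[members[gi]] - mu[gi]
            out[members[gi]] = -0.5 * np.einsum("ij,jk,ik->i", d, lam[gi], d)
        return out

    def full_ll(th, lat):
        return model.participant_loglik(th, lat)

    vi_stats = {"n": 0, "acc": 0}

    def ab_virefresh_track(acc):
        vi_stats["n"] += acc.size
        vi_stats["acc"] += int(acc.sum())

    # running per-participant log-likelihood cache (obs + missing terms)
    cur_ll = full_ll(theta, latents)

    def cell_ll(th, c):
        """Per-participant log-lik restricted to one drift cell (observed +
        missing trials of that cell)."""
        out = model.obs_loglik(th, subset=cell_obs[c])
        if len(cell_mis[c]):
            out = out + model.mis_loglik(th, latents, subset=cell_mis[c])
        return out

    def sweep(adapt: bool):
        nonlocal theta, u_lat, latents, mu, cov, lam, cur_ll
        # --- drift-cell blocks (2-dim, parallel across participants) ------
        for c in range(_CELLS):
            cols = np.array([c, c + N_DRIFTS // 2])
            prop = theta.copy()
            prop[:, cols] = ab_cells[c].propose(theta[:, cols], rng)
            ll_old = cell_ll(theta, c)
            ll_new = cell_ll(prop, c)
            lp_old = ll_old + prior_quad(theta)
            lp_new = ll_new + prior_quad(prop)
            acc = metropolis_accept(lp_new, lp_old, rng)
            ab_cells[c].track(acc)
            theta[acc] = prop[acc]
            cur_ll = cur_ll + np.where(acc, ll_new - ll_old, 0.0)
            if adapt:
                ab_cells[c].adapt(acc)
                ab_cells[c].observe(theta[:, cols])
        # --- incorrect-drift refresh (conditional-prior independence) ------
        if hier_struct:
            prop = theta.copy()
            for gi in range(n_groups):
                S = cov[gi]
                gain = S[np.ix_(VI, NOT_VI)] @ np.linalg.inv(
                    S[np.ix_(NOT_VI, NOT_VI)]
                )
                cond_cov = S[np.ix_(VI, VI)] - gain @ S[np.ix_(NOT_VI, VI)]
                cond_chol = np.linalg.cholesky(
                    cond_cov + 1e-12 * np.eye(len(VI))
                )
                mem = members[gi]
                cond_mean = mu[gi][VI] + (
                    theta[mem][:, NOT_VI] - mu[gi][NOT_VI]
                ) @ gain.T
                z = rng.standard_normal((len(mem), len(VI)))
                prop[np.ix_(mem, VI)] = cond_mean + z @ cond_chol.T
            ll_new = full_ll(prop, latents)
            acc = metropolis_accept(ll_new, cur_ll, rng)
            ab_virefresh_track(acc)
            theta[acc] = prop[acc]
            cur_ll = np.where(acc, ll_new, cur_ll)
        # --- structural block ---------------------------------------------
        if hier_struct:
            for _ in range(struct_repeats):
                prop = theta.copy()
                prop[:, STRUCT] = ab_struct.propose(theta[:, STRUCT], rng)
                ok_t0 = prop[:, N_DRIFTS + 2] < model.log_t0_max
                ll_new = full_ll(prop, latents)
                lp_old = cur_ll + prior_quad(theta)
                lp_new = np.where(ok_t0, ll_new + prior_quad(prop), -np.inf)
                acc = metropolis_accept(lp_new, lp_old, rng)
                ab_struct.track(acc)
                theta[acc] = prop[acc]
                cur_ll = np.where(acc, ll_new, cur_ll)
                if adapt:
                    ab_struct.adapt(acc)
                    ab_struct.observe(theta[:, STRUCT])
        else:
            # one shared structural vector per group
            cur = np.stack([theta[members[gi][0], STRUCT] for gi in range(n_groups)])
            props = ab_struct.propose(cur, rng)
            acc_flags = np.zeros(n_groups, dtype=bool)
            for gi in range(n_groups):
                prop = theta.copy()
                prop[members[gi], STRUCT] = props[gi]
                if not np.all(props[gi][2] < model.log_t0_max[members[gi]]):
                    continue
                ll_new = full_ll(prop, latents)
                lp_old = float(cur_ll[members[gi]].sum()) + float(
                    stats.norm.logpdf(cur[gi], m0[STRUCT], s0[STRUCT]).sum()
                )
                lp_new = float(ll_new[members[gi]].sum()) + float(
                    stats.norm.logpdf(props[gi], m0[STRUCT], s0[STRUCT]).sum()
                )
                acc = metropolis_accept(np.array([lp_new]), np.array([lp_old]), rng)
                if acc[0]:
                    acc_flags[gi] = True
                    theta[members[gi], STRUCT] = props[gi]
                    cur_ll[members[gi]] = ll_new[members[gi]]
            if adapt:
                ab_struct.adapt(acc_flags)
                ab_struct.observe(
                    np.stack([theta[members[gi][0], STRUCT] for gi in range(n_groups)])
                )
        # --- joint 15-dim participant move ---------------------------------
        if hier_struct:
            for _ in range(joint_repeats):
                prop = ab_joint.propose(theta, rng)
                ok_t0 = prop[:, N_DRIFTS + 2] < model.log_t0_max
                ll_new = full_ll(prop, latents)
                lp_old = cur_ll + prior_quad(theta)
                lp_new = np.where(ok_t0, ll_new + prior_quad(prop), -np.inf)
                acc = metropolis_accept(lp_new, lp_old, rng)
                ab_joint.track(acc)
                theta[acc] = prop[acc]
                cur_ll = np.where(acc, ll_new, cur_ll)
                if adapt:
                    ab_joint.adapt(acc)
                    ab_joint.observe(theta)
        # --- group-shift move ----------------------------------------------
        if hier_struct:
            for _ in range(shift_repeats):
                mu_mat = np.stack(mu)
                prop_mu = ab_shift.propose(mu_mat, rng)
                delta = prop_mu - mu_mat
                prop = theta.copy()
                for gi in range(n_groups):
                    prop[members[gi]] += delta[gi]
                ll_new = full_ll(prop, latents)
                acc_shift = np.zeros(n_groups, dtype=bool)
                for gi in range(n_groups):
                    mem = members[gi]
                    if np.any(prop[mem, N_DRIFTS + 2] >= model.log_t0_max[mem]):
                        continue
                    lp_old = float(cur_ll[mem].sum()) + float(
                        np.sum(-0.5 * ((mu_mat[gi] - m0) / s0) ** 2)
                    )
                    lp_new = float(ll_new[mem].sum()) + float(
                        np.sum(-0.5 * ((prop_mu[gi] - m0) / s0) ** 2)
                    )
                    a = metropolis_accept(np.array([lp_new]), np.array([lp_old]), rng)
                    if a[0]:
                        acc_shift[gi] = True
                        theta[mem] = prop[mem]
                        mu[gi] = prop_mu[gi]
                        cur_ll[mem] = ll_new[mem]
                ab_shift.track(acc_shift)
                if adapt:
                    ab_shift.adapt(acc_shift)
                    ab_shift.observe(np.stack(mu))
        # --- group scale move ----------------------------------------------
        if hier_struct:
            for _ in range(scale_repeats):
                deltas = ab_scale.propose(np.zeros((n_groups, 1)), rng)[:, 0]
                prop = theta.copy()
                prop_mu_list = [m.copy() for m in mu]
                for gi in range(n_groups):
                    prop[np.ix_(members[gi], SCALE_COLS)] += deltas[gi]
                    prop_mu_list[gi][SCALE_COLS] += deltas[gi]
                ll_new = full_ll(prop, latents)
                acc_scale = np.zeros(n_groups, dtype=bool)
                for gi in range(n_groups):
                    mem = members[gi]
                    lp_old = float(cur_ll[mem].sum()) + float(
                        np.sum(-0.5 * ((mu[gi] - m0) / s0) ** 2)
                    )
                    lp_new = float(ll_new[mem].sum()) + float(
                        np.sum(-0.5 * ((prop_mu_list[gi] - m0) / s0) ** 2)
                    )
                    a = metropolis_accept(np.array([lp_new]), np.array([lp_old]), rng)
                    if a[0]:
                        acc_scale[gi] = True
                        theta[mem] = prop[mem]
                        mu[gi] = prop_mu_list[gi]
                        cur_ll[mem] = ll_new[mem]
                ab_scale.track(acc_scale)
                if adapt:
                    ab_scale.adapt(acc_scale)
        # --- group t0-shift move --------------------------------------------
        if hier_struct:
            for _ in range(t0shift_repeats):
                deltas = ab_t0shift.propose(np.zeros((n_groups, 1)), rng)[:, 0]
                prop = theta.copy()
                prop_mu_list = [m.copy() for m in mu]
                log_jac = np.zeros(n_groups)
                feasible = np.ones(n_groups, dtype=bool)
                for gi in range(n_groups):
                    mem = members[gi]
                    d = deltas[gi]
                    t0_m = np.exp(theta[mem, N_DRIFTS + 2])
                    new_t0 = t0_m + d
                    c = (rbar[mem] - t0_m - d) / (rbar[mem] - t0_m)
                    t0_mu = np.exp(mu[gi][N_DRIFTS + 2])
                    c_mu = (rbar_group[gi] - t0_mu - d) / (rbar_group[gi] - t0_mu)
                    if (
                        np.any(new_t0 <= 5e-3)
                        or np.any(c <= 0.2)
                        or t0_mu + d <= 5e-3
                        or c_mu <= 0.2
                        or np.any(np.log(new_t0) >= model.log_t0_max[mem])
                    ):
                        feasible[gi] = False
                        continue
                    prop[mem, N_DRIFTS + 2] = np.log(new_t0)
                    prop[np.ix_(mem, SCALE_COLS)] += np.log(c)[:, None]
                    prop_mu_list[gi][N_DRIFTS + 2] = np.log(t0_mu + d)
                    prop_mu_list[gi][SCALE_COLS] += np.log(c_mu)
                    log_jac[gi] = float(np.sum(np.log(t0_m / new_t0))) + float(
                        np.log(t0_mu / (t0_mu + d))
                    )
                ll_new = full_ll(prop, latents)
                acc_t0 = np.zeros(n_groups, dtype=bool)
                for gi in range(n_groups):
                    if not feasible[gi]:
                        continue
                    mem = members[gi]
                    dq_old = theta[mem] - mu[gi]
                    dq_new = prop[mem] - prop_mu_list[gi]
                    quad_old = -0.5 * np.einsum(
                        "ij,jk,ik->i", dq_old, lam[gi], dq_old
                    ).sum()
                    quad_new = -0.5 * np.einsum(
                        "ij,jk,ik->i", dq_new, lam[gi], dq_new
                    ).sum()
                    lp_old = float(cur_ll[mem].sum()) + quad_old + float(
                        np.sum(-0.5 * ((mu[gi] - m0) / s0) ** 2)
                    )
                    lp_new = (
                        float(ll_new[mem].sum())
                        + quad_new
                        + float(np.sum(-0.5 * ((prop_mu_list[gi] - m0) / s0) ** 2))
                        + log_jac[gi]
                    )
                    a = metropolis_accept(np.array([lp_new]), np.array([lp_old]), rng)
                    if a[0]:
                        acc_t0[gi] = True
                        theta[mem] = prop[mem]
                        mu[gi] = prop_mu_list[gi]
                        cur_ll[mem] = ll_new[mem]
                ab_t0shift.track(acc_t0)
                if adapt:
                    ab_t0shift.adapt(acc_t0)
        # --- incorrect-drift group shift ------------------------------------
        if hier_struct:
            for _ in range(vishift_repeats):
                cur_vi = np.stack([m[VI] for m in mu])
                prop_vi = ab_vishift.propose(cur_vi, rng)
                delta_vi = prop_vi - cur_vi
                prop = theta.copy()
                for gi in range(n_groups):
                    prop[np.ix_(members[gi], VI)] += delta_vi[gi]
                ll_new = full_ll(prop, latents)
                acc_vi = np.zeros(n_groups, dtype=bool)
                for gi in range(n_groups):
                    mem = members[gi]
                    lp_old = float(cur_ll[mem].sum()) + float(
                        np.sum(-0.5 * ((cur_vi[gi] - m0[VI]) / s0[VI]) ** 2)
                    )
                    lp_new = float(ll_new[mem].sum()) + float(
                        np.sum(-0.5 * ((prop_vi[gi] - m0[VI]) / s0[VI]) ** 2)
                    )
                    a = metropolis_accept(np.array([lp_new]), np.array([lp_old]), rng)
                    if a[0]:
                        acc_vi[gi] = True
                        theta[mem] = prop[mem]
                        mu[gi][VI] = prop_vi[gi]
                        cur_ll[mem] = ll_new[mem]
                ab_vishift.track(acc_vi)
                if adapt:
                    ab_vishift.adapt(acc_vi)
                    ab_vishift.observe(np.stack([m[VI] for m in mu]))
        # --- structural-only group shift ------------------------------------
        if hier_struct:
            for _ in range(structshift_repeats):
                cur_st = np.stack([m[STRUCT] for m in mu])
                prop_st = ab_structshift.propose(cur_st, rng)
                delta_st = prop_st - cur_st
                prop = theta.copy()
                for gi in range(n_groups):
                    prop[members[gi], STRUCT] += delta_st[gi]
                ll_new = full_ll(prop, latents)
                acc_st = np.zeros(n_groups, dtype=bool)
                for gi in range(n_groups):
                    mem = members[gi]
                    if np.any(prop[mem, N_DRIFTS + 2] >= model.log_t0_max[mem]):
                        continue
                    lp_old = float(cur_ll[mem].sum()) + float(
                        np.sum(-0.5 * ((cur_st[gi] - m0[STRUCT]) / s0[STRUCT]) ** 2)
                    )
                    lp_new = float(ll_new[mem].sum()) + float(
                        np.sum(-0.5 * ((prop_st[gi] - m0[STRUCT]) / s0[STRUCT]) ** 2)
                    )
                    a = metropolis_accept(np.array([lp_new]), np.array([lp_old]), rng)
                    if a[0]:
                        acc_st[gi] = True
                        theta[mem] = prop[mem]
                        mu[gi][STRUCT] = prop_st[gi]
                        cur_ll[mem] = ll_new[mem]
                ab_structshift.track(acc_st)
                if adapt:
                    ab_structshift.adapt(acc_st)
                    ab_structshift.observe(np.stack([m[STRUCT] for m in mu]))
        # --- structural deviation-rescale (expansion) -----------------------
        if hier_struct:
            for _ in range(spread_repeats):
                eps = ab_spread.propose(np.zeros((n_groups, 3)), rng)
                prop = theta.copy()
                for gi in range(n_groups):
                    mem = members[gi]
                    dev = theta[mem, STRUCT] - mu[gi][STRUCT]
                    prop[mem, STRUCT] = mu[gi][STRUCT] + dev * np.exp(eps[gi])
                ll_new = full_ll(prop, latents)
                pq_old = prior_quad(theta)
                pq_new = prior_quad(prop)
                acc_sp = np.zeros(n_groups, dtype=bool)
                for gi in range(n_groups):
                    mem = members[gi]
                    if np.any(prop[mem, N_DRIFTS + 2] >= model.log_t0_max[mem]):
                        continue
                    lp_old = float(cur_ll[mem].sum()) + float(pq_old[mem].sum())
                    lp_new = (
                        float(ll_new[mem].sum())
                        + float(pq_new[mem].sum())
                        + len(mem) * float(eps[gi].sum())
                    )
                    a = metropolis_accept(np.array([lp_new]), np.array([lp_old]), rng)
                    if a[0]:
                        acc_sp[gi] = True
                        theta[mem] = prop[mem]
                        cur_ll[mem] = ll_new[mem]
                ab_spread.track(acc_sp)
                if adapt:
                    ab_spread.adapt(acc_sp)
        # --- per-participant ridge moves ------------------------------------
        if hier_struct:
            for _ in range(indiv_ridge_repeats):
                # t0 shift with decision-time compensation, per participant
                d = ab_t0shift_i.propose(np.zeros((n_p, 1)), rng)[:, 0]
                t0_m = np.exp(theta[:, N_DRIFTS + 2])
                new_t0 = t0_m + d
                c = (rbar - t0_m - d) / (rbar - t0_m)
                ok = (
                    (new_t0 > 5e-3)
                    & (c > 0.2)
                    & (np.log(np.clip(new_t0, 1e-9, None)) < model.log_t0_max)
                )
                prop = theta.copy()
                safe_t0 = np.where(ok, new_t0, t0_m)
                safe_c = np.where(ok, c, 1.0)
                prop[:, N_DRIFTS + 2] = np.log(safe_t0)
                prop[:, SCALE_COLS] += np.log(safe_c)[:, None]
                ll_new = full_ll(prop, latents)
                lp_old = cur_ll + prior_quad(theta)
                lp_new = np.where(
                    ok,
                    ll_new + prior_quad(prop) + np.log(t0_m / safe_t0),
                    -np.inf,
                )
                acc = metropolis_accept(lp_new, lp_old, rng)
                ab_t0shift_i.track(acc)
                theta[acc] = prop[acc]
                cur_ll = np.where(acc, ll_new, cur_ll)
                if adapt:
                    ab_t0shift_i.adapt(acc)
                # common scale of A, k and drifts, per participant
                d = ab_scale_i.propose(np.zeros((n_p, 1)), rng)[:, 0]
                prop = theta.copy()
                prop[:, SCALE_COLS] += d[:, None]
                ll_new = full_ll(prop, latents)
                lp_old = cur_ll + prior_quad(theta)
                lp_new = ll_new + prior_quad(prop)
                acc = metropolis_accept(lp_new, lp_old, rng)
                ab_scale_i.track(acc)
                theta[acc] = prop[acc]
                cur_ll = np.where(acc, ll_new, cur_ll)
                if adapt:
                    ab_scale_i.adapt(acc)
        # --- latent missing RTs --------------------------------------------
        if model.n_missing:
            prop_u = ab_lat.propose(u_lat[:, None], rng)[:, 0]
            ok = prop_u <= u_cap
            prop_t = spec.deadline + np.exp(prop_u)
            ll_t_old = model.mis_loglik_per_trial(theta, latents)
            ll_t_new = model.mis_loglik_per_trial(theta, prop_t)
            acc = metropolis_accept(
                np.where(ok, ll_t_new + prop_u, -np.inf), ll_t_old + u_lat, rng
            )
            u_lat = np.where(acc, prop_u, u_lat)
            latents = spec.deadline + np.exp(u_lat)
            cur_ll = cur_ll + np.bincount(
                model.mis_p,
                weights=np.where(acc, ll_t_new - ll_t_old, 0.0),
                minlength=n_p,
            )
            if adapt:
                ab_lat.adapt(acc)
                ab_lat.observe(u_lat[:, None])
        # --- conjugate group-level updates ---------------------------------
        active = slice(0, N_PARAMS) if hier_struct else DRIFT
        dim = N_PARAMS if hier_struct else N_DRIFTS
        for gi in range(n_groups):
            th_g = theta[members[gi]][:, active]
            n_g = len(th_g)
            lam_a = lam[gi][:dim, :dim]
            # mean: conjugate MVN
            prec = np.diag(prior_prec0[active]) + n_g * lam_a
            rhs = prior_prec0[active] * m0[active] + lam_a @ th_g.sum(axis=0)
            cho = linalg.cho_factor(prec)
            mean = linalg.cho_solve(cho, rhs)
            z = rng.standard_normal(dim)
            mu_g = mean + linalg.solve_triangular(
                np.linalg.cholesky(prec), z, lower=True, trans="T"
            )
            mu[gi][active] = mu_g
            if not hier_struct:
                mu[gi][STRUCT] = theta[members[gi][0], STRUCT]
            # covariance: conjugate inverse-Wishart / inverse-gamma
            d = th_g - mu_g
            if diagonal:
                a_n = priors.ig_shape + n_g / 2.0
                b_n = priors.ig_scale()[active] + 0.5 * np.sum(d**2, axis=0)
                var = b_n / rng.gamma(a_n, 1.0, size=dim)
                cov_g = np.diag(var)
            else:
                scale_n = priors.iw_scale()[:dim, :dim] + d.T @ d
                df_n = priors.iw_df + n_g
                cov_g = stats.invwishart.rvs(
                    df=df_n, scale=scale_n, random_state=rng
                )
            cov[gi] = np.zeros((N_PARAMS, N_PARAMS))
            cov[gi][:dim, :dim] = cov_g
            if not hier_struct:
                cov[gi][STRUCT, STRUCT] = np.eye(3) * 1e-12
            lam[gi] = np.zeros((N_PARAMS, N_PARAMS))
            lam[gi][:dim, :dim] = np.linalg.inv(cov_g)

    all_blocks = [*ab_cells, ab_struct, ab_lat, ab_joint, ab_shift, ab_scale,
                  ab_t0shift, ab_t0shift_i, ab_scale_i, ab_vishift,
                  ab_structshift, ab_spread]
    resync_every = 200  # guard against cache drift
    sweep_count = 0
    # each warmup iteration runs the same number of internal sweeps as a
    # retained sampling iteration would (capped), so longer thinning also
    # buys longer adaptation
    warmup_thin = max(1, min(thin, 24) // 8)
    # drop the moment estimates mid-warmup so the proposal shapes are
    # re-learned from the post-transient trajectory
    resets = {warmup // 2}
    for w in range(warmup):
        for _ in range(warmup_thin):
            sweep(True)
            sweep_count += 1
            if sweep_count % resync_every == 0:
                cur_ll = full_ll(theta, latents)
        if w in resets:
            for ab in all_blocks:
                ab.reset_moments()
    for ab in all_blocks:
        ab.freeze()
    for it in range(iters):
        for _ in range(thin):
            sweep(False)
            sweep_count += 1
            if sweep_count % resync_every == 0:
                cur_ll = full_ll(theta, latents)
        sd = [np.sqrt(np.clip(np.diag(c), 0, None)) for c in cov]
        store(it, mu, sd, theta)
    return {
        "cells": float(np.mean([b.acceptance_rate for b in ab_cells])),
        "vi_refresh": vi_stats["acc"] / max(vi_stats["n"], 1),
        "struct": ab_struct.acceptance_rate,
        "joint": ab_joint.acceptance_rate,
        "shift": ab_shift.acceptance_rate,
        "scale": ab_scale.acceptance_rate,
        "t0shift": ab_t0shift.acceptance_rate,
        "t0shift_i": ab_t0shift_i.acceptance_rate,
        "scale_i": ab_scale_i.acceptance_rate,
        "vi_shift": ab_vishift.acceptance_rate,
        "struct_shift": ab_structshift.acceptance_rate,
        "spread": ab_spread.acceptance_rate,
        "latents": ab_lat.acceptance_rate,
    }


def _run_chain_noncentered(model, rng, warmup, iters, thin, members, store, progress):
    """Non-centered variant: theta_i = mu_g + sigma_g * xi_i with diagonal
    covariance.  Standardised deviations xi, group means and log-scales
    move by coordinate-wise adaptive random walk (each coordinate update
    is vectorised across participants / groups), which mixes the small
    instances this variant exists to cross-check.
    """
    spec, priors = model.spec, model.priors
    n_p = model.n_participants
    n_groups = len(members)
    m0, s0 = priors.mean_loc(), priors.mean_scale()
    group_of = model.group_index

    theta0 = _initial_theta(model, rng)
    mu = np.stack([theta0[members[gi]].mean(axis=0) for gi in range(n_groups)])
    sigma = np.stack([np.sqrt(priors.var_mean()) for _ in range(n_groups)])
    xi = np.zeros((n_p, N_PARAMS))
    for gi in range(n_groups):
        xi[members[gi]] = (theta0[members[gi]] - mu[gi]) / sigma[gi]

    latents = np.full(model.n_missing, spec.deadline + 0.3)
    u_lat = np.log(latents - spec.deadline)
    u_cap = np.log(spec.latent_cap - spec.deadline)

    def current_theta():
        return mu[group_of] + sigma[group_of] * xi

    ab_xi = AdaptiveBlock(n_p * N_PARAMS, 1, init_scale=0.3)
    ab_mu = AdaptiveBlock(n_groups * N_PARAMS, 1, init_scale=0.1)
    ab_ls = AdaptiveBlock(n_groups * N_PARAMS, 1, init_scale=0.1)
    ab_lat = AdaptiveBlock(max(model.n_missing, 1), 1, init_scale=0.5)

    def ig_logpdf_vec(var):
        a, b = priors.ig_shape, priors.ig_scale()
        return -(a + 1.0) * np.log(var) - b[None, :] / var

    def sweep(adapt: bool):
        nonlocal xi, mu, sigma, u_lat, latents
        # xi: one coordinate at a time, vectorised over participants
        for c in range(N_PARAMS):
            cur = xi[:, c]
            # per-(participant, coord) adaptive scales live in a flat block
            sl = slice(c * n_p, (c + 1) * n_p)
            step = np.exp(ab_xi.log_scale[sl]) * ab_xi._sd[sl, 0]
            prop_c = cur + step * rng.standard_normal(n_p)
            prop_xi = xi.copy()
            prop_xi[:, c] = prop_c
            th = current_theta()
            prop_th = mu[group_of] + sigma[group_of] * prop_xi
            ok = prop_th[:, N_DRIFTS + 2] < model.log_t0_max
            ll_old = model.participant_loglik(th, latents)
            ll_new = model.participant_loglik(prop_th, latents)
            lp_old = ll_old - 0.5 * cur**2
            lp_new = np.where(ok, ll_new - 0.5 * prop_c**2, -np.inf)
            acc = metropolis_accept(lp_new, lp_old, rng)
            xi[acc, c] = prop_c[acc]
            if adapt:
                ab_xi.log_scale[sl] += (1.0 / max(getattr(ab_xi, "_adapt_t", 1), 1) ** 0.6) * (
                    acc.astype(float) - ab_xi.target
                )
                ab_xi.log_scale[sl] = np.clip(ab_xi.log_scale[sl], -10, 3)
        if adapt:
            ab_xi._adapt_t = getattr(ab_xi, "_adapt_t", 0) + 1
        # group means: coordinate-wise, vectorised over groups
        for c in range(N_PARAMS):
            sl = slice(c * n_groups, (c + 1) * n_groups)
            step = np.exp(ab_mu.log_scale[sl])
            prop_c = mu[:, c] + step * rng.standard_normal(n_groups)
            prop_mu = mu.copy()
            prop_mu[:, c] = prop_c
            th = current_theta()
            prop_th = prop_mu[group_of] + sigma[group_of] * xi
            ll_old = model.participant_loglik(th, latents)
            ll_new = model.participant_loglik(prop_th, latents)
            acc = np.zeros(n_groups, dtype=bool)
            for gi in range(n_groups):
                mem = members[gi]
                if np.any(prop_th[mem, N_DRIFTS + 2] >= model.log_t0_max[mem]):
                    continue
                lp_old = float(ll_old[mem].sum()) - 0.5 * ((mu[gi, c] - m0[c]) / s0[c]) ** 2
                lp_new = float(ll_new[mem].sum()) - 0.5 * ((prop_c[gi] - m0[c]) / s0[c]) ** 2
                a = metropolis_accept(np.array([lp_new]), np.array([lp_old]), rng)
                acc[gi] = bool(a[0])
            mu[acc, c] = prop_c[acc]
            if adapt:
                ab_mu.log_scale[sl] += (1.0 / max(getattr(ab_mu, "_adapt_t", 1), 1) ** 0.6) * (
                    acc.astype(float) - ab_mu.target
                )
                ab_mu.log_scale[sl] = np.clip(ab_mu.log_scale[sl], -10, 3)
        if adapt:
            ab_mu._adapt_t = getattr(ab_mu, "_adapt_t", 0) + 1
        # group scales: coordinate-wise on the log scale
        for c in range(N_PARAMS):
            sl = slice(c * n_groups, (c + 1) * n_groups)
            step = np.exp(ab_ls.log_scale[sl])
            cur_ls = np.log(sigma[:, c])
            prop_ls = cur_ls + step * rng.standard_normal(n_groups)
            prop_sigma = sigma.copy()
            prop_sigma[:, c] = np.exp(prop_ls)
            th = current_theta()
            prop_th = mu[group_of] + prop_sigma[group_of] * xi
            ll_old = model.participant_loglik(th, latents)
            ll_new = model.participant_loglik(prop_th, latents)
            a_ig, b_ig = priors.ig_shape, priors.ig_scale()[c]
            acc = np.zeros(n_groups, dtype=bool)
            for gi in range(n_groups):
                mem = members[gi]
                if np.any(prop_th[mem, N_DRIFTS + 2] >= model.log_t0_max[mem]):
                    continue
                var_old, var_new = sigma[gi, c] ** 2, prop_sigma[gi, c] ** 2
                lp_old = (
                    float(ll_old[mem].sum())
                    - (a_ig + 1.0) * np.log(var_old)
                    - b_ig / var_old
                    + 2.0 * cur_ls[gi]
                )
                lp_new = (
                    float(ll_new[mem].sum())
                    - (a_ig + 1.0) * np.log(var_new)
                    - b_ig / var_new
                    + 2.0 * prop_ls[gi]
                )
                a = metropolis_accept(np.array([lp_new]), np.array([lp_old]), rng)
                acc[gi] = bool(a[0])
            sigma[acc, c] = prop_sigma[acc, c]
            if adapt:
                ab_ls.log_scale[sl] += (1.0 / max(getattr(ab_ls, "_adapt_t", 1), 1) ** 0.6) * (
                    acc.astype(float) - ab_ls.target
                )
                ab_ls.log_scale[sl] = np.clip(ab_ls.log_scale[sl], -10, 3)
        if adapt:
            ab_ls._adapt_t = getattr(ab_ls, "_adapt_t", 0) + 1
        # interweaving moves (theta held fixed, so no likelihood terms):
        # translate mu with compensating xi, and rescale sigma with
        # compensating xi.  These give the non-centered chain the fast
        # group-level mixing on data-rich coordinates that the centered
        # conjugate updates provide.
        for c in range(N_PARAMS):
            # conditional posterior of mu given (theta, sigma) has SD of
            # order sigma/sqrt(n); scale the compensated translation to it
            for gi in range(n_groups):
                mem = members[gi]
                step = 2.0 * sigma[gi, c] / np.sqrt(len(mem))
                delta_g = step * rng.standard_normal()
                xi_new = xi[mem, c] - delta_g / sigma[gi, c]
                lp_old = (
                    -0.5 * ((mu[gi, c] - m0[c]) / s0[c]) ** 2
                    - 0.5 * float(np.sum(xi[mem, c] ** 2))
                )
                lp_new = (
                    -0.5 * ((mu[gi, c] + delta_g - m0[c]) / s0[c]) ** 2
                    - 0.5 * float(np.sum(xi_new**2))
                )
                if metropolis_accept(np.array([lp_new]), np.array([lp_old]), rng)[0]:
                    mu[gi, c] += delta_g
                    xi[mem, c] = xi_new
        a_ig_all, b_ig_all = priors.ig_shape, priors.ig_scale()
        for c in range(N_PARAMS):
            eps = 0.3 * rng.standard_normal(n_groups)
            for gi in range(n_groups):
                mem = members[gi]
                scale = float(np.exp(eps[gi]))
                sig_new = sigma[gi, c] * scale
                xi_new = xi[mem, c] / scale
                var_old, var_new = sigma[gi, c] ** 2, sig_new**2
                lp_old = (
                    -(a_ig_all + 1.0) * np.log(var_old)
                    - b_ig_all[c] / var_old
                    - 0.5 * float(np.sum(xi[mem, c] ** 2))
                )
                # +2*eps from the log-sigma density change, -n*eps from the
                # Jacobian of rescaling the n member deviations
                lp_new = (
                    -(a_ig_all + 1.0) * np.log(var_new)
                    - b_ig_all[c] / var_new
                    - 0.5 * float(np.sum(xi_new**2))
                    + (2.0 - len(mem)) * eps[gi]
                )
                if metropolis_accept(np.array([lp_new]), np.array([lp_old]), rng)[0]:
                    sigma[gi, c] = sig_new
                    xi[mem, c] = xi_new
        # latent missing RTs
        if model.n_missing:
            th = current_theta()
            prop_u = ab_lat.propose(u_lat[:, None], rng)[:, 0]
            ok = prop_u <= u_cap
            prop_t = spec.deadline + np.exp(prop_u)
            ll_old = model.mis_loglik_per_trial(th, latents) + u_lat
            ll_new = np.where(
                ok, model.mis_loglik_per_trial(th, prop_t) + prop_u, -np.inf
            )
            acc = metropolis_accept(ll_new, ll_old, rng)
            u_lat = np.where(acc, prop_u, u_lat)
            latents = spec.deadline + np.exp(u_lat)
            if adapt:
                ab_lat.adapt(acc)
                ab_lat.observe(u_lat[:, None])

    for w in range(warmup):
        sweep(True)
    ab_lat.freeze()
    for it in range(iters):
        for _ in range(thin):
            sweep(False)
        store(it, [mu[gi] for gi in range(n_groups)],
              [sigma[gi] for gi in range(n_groups)], current_theta())
    return {}


# ---------------------------------------------------------------------------
# Posterior predictive checking
# ---------------------------------------------------------------------------


def posterior_predictive(
    draws: PosteriorDraws,
    trials: pd.DataFrame,
    n_draws: int = 100,
    seed=None,
    deadline: float = 3.0,
) -> pd.DataFrame:
    """Simulate datasets on the observed schedule from sampled posterior
    draws and summarise predicted vs. observed cell-level statistics.

    Returns one row per (group, condition, trial_type) with observed and
    predicted mean correct-RT and error rate, and their discrepancies.
    """
    from .synthetic import params_from_vector, simulate_behavior

    rng = np.random.default_rng(seed)
    total = draws.n_draws
    picks = rng.choice(total, size=min(n_draws, total), replace=False)

    obs = trials[~trials["missing"].astype(bool)]
    obs_stats = (
        obs.assign(correct=obs["correct"].astype(bool))
        .groupby(["group", "condition", "trial_type"])
        .agg(
            observed_mean_rt=("rt_seconds", lambda s: s.mean()),
            observed_error_rate=("correct", lambda s: 1.0 - s.mean()),
        )
    )

    acc = {}
    for d in picks:
        params = {}
        for g in draws.groups:
            th = draws.flat_theta(g)[d]
            for pi, pid in enumerate(draws.participants[g]):
                params[pid] = params_from_vector(np.exp(th[pi]))
        sim = simulate_behavior(
            trials, params, deadline=deadline, seed=rng.integers(2**31)
        )
        simobs = sim[~sim["missing"].astype(bool)]
        st = (
            simobs.assign(correct=simobs["correct"].astype(bool))
            .groupby(["group", "condition", "trial_type"])
            .agg(
                mean_rt=("rt_seconds", lambda s: s.mean()),
                error_rate=("correct", lambda s: 1.0 - s.mean()),
            )
        )
        for key, row in st.iterrows():
            acc.setdefault(key, []).append((row["mean_rt"], row["error_rate"]))

    rows = []
    for key, vals in acc.items():
        arr = np.array(vals)
        o = obs_stats.loc[key]
        rows.append(
            {
                "group": key[0],
                "condition": key[1],
                "trial_type": key[2],
                "observed_mean_rt": o["observed_mean_rt"],
                "predicted_mean_rt": arr[:, 0].mean(),
                "observed_error_rate": o["observed_error_rate"],
                "predicted_error_rate": arr[:, 1].mean(),
            }
        )
    out = pd.DataFrame(rows)
    out["rt_discrepancy"] = (
        out["predicted_mean_rt"] - out["observed_mean_rt"]
    ) / out["observed_mean_rt"]
    return out
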