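"""Linear ballistic accumulator (LBA) mathematics.

The LBA is a race model of two-choice decisions: each response option has an
independent accumulator that starts at a point drawn uniformly on ``[0, A]``
and gathers evidence linearly at a trial-specific rate drawn from
``Normal(v, sv)``.  The first accumulator to reach the common threshold
``b = A + k`` determines the choice; the observed response time is the
winning first-passage time plus a non-decision offset ``t0``.

This module provides the exact single-accumulator first-passage density and
CDF, the defective joint density of (choice, RT), choice probabilities by
quadrature, a race sampler, and the trial-level log-likelihood including the
chance-accuracy treatment of deadline-censored (missing) responses.

All functions are pure and vectorised over trials; no file I/O happens here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.special import ndtr

from .labels import (
    ACCUMULATORS,
    CONDITIONS,
    TRIAL_TYPES,
    accumulator_index,
    condition_index,
    trial_type_index,
)

__all__ = [
    "LBAParams",
    "lba_pdf",
    "lba_cdf",
    "defective_density",
    "choice_probability",
    "no_finish_probability",
    "simulate_race",
    "trial_log_likelihood",
    "log_likelihood",
    "DENSITY_FLOOR",
]

#: Densities are floored at this value before taking logs, to distinguish
#: harmless numerical underflow from the structural zero at t <= t0.
DENSITY_FLOOR = 1e-300

_SQRT2PI = math.sqrt(2.0 * math.pi)


def _npdf(z):
    return np.exp(-0.5 * np.square(z)) / _SQRT2PI


@dataclass
class LBAParams:
    """Parameters of a two-accumulator LBA for one participant.

    Attributes
    ----------
    A : float
        Start-point range; the start point is uniform on ``[0, A]``.
    k : float
        Threshold gap above the start-point range, so ``b = A + k > A``
        structurally.
    t0 : float
        Non-decision time in seconds (perceptual encoding + motor execution).
    v : ndarray, shape (2, n_conditions, n_trial_types)
        Drift-rate means indexed by (accumulator, condition, trial type)
        with accumulators ordered ``("correct", "incorrect")``.
    sv : float
        Between-trial drift standard deviation; fixed to 1 as the model's
        scaling constraint unless explicitly overridden.
    """

    A: float
    k: float
    t0: float
    v: np.ndarray
    sv: float = 1.0

    conditions: tuple[str, ...] = field(default=CONDITIONS, repr=False)
    trial_types: tuple[str, ...] = field(default=TRIAL_TYPES, repr=False)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        expected = (len(ACCUMULATORS), len(self.conditions), len(self.trial_types))
        if self.v.shape != expected:
            raise ValueError(f"v must have shape {expected}, got {self.v.shape}")
        if not (self.A > 0):
            raise ValueError(f"A must be > 0, got {self.A}")
        if not (self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.t0 < 0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        if not (self.sv > 0):
            raise ValueError(f"sv must be > 0, got {self.sv}")

    @property
    def b(self) -> float:
        """Decision threshold."""
        return self.A + self.k

    @property
    def response_caution(self) -> float:
        """Average evidence needed to respond, ``k + A/2``."""
        return self.k + self.A / 2.0

    def drift(self, choice: str, condition: str, trial_type: str) -> float:
        return float(
            self.v[
                accumulator_index(choice),
                self.conditions.index(condition),
                self.trial_types.index(trial_type),
            ]
        )


def _validate_single(A, b, s) -> None:
    if not np.all(np.asarray(A) > 0):
        raise ValueError("A must be > 0")
    if not np.all(np.asarray(b) >= np.asarray(A)):
        raise ValueError("b must be >= A")
    if not np.all(np.asarray(s) > 0):
        raise ValueError("s must be > 0")


def lba_pdf(t, A, b, v, s=1.0):
    """First-passage density of a single LBA accumulator at decision time t.

    ``f(t) = (1/A) [-v Phi(z1) + s phi(z1) + v Phi(z2) - s phi(z2)]`` with
    ``z1 = (b - A - t v)/(t s)`` and ``z2 = (b - t v)/(t s)``; zero for
    ``t <= 0``.  Vectorised over every argument.
    """
    _validate_single(A, b, s)
    t = np.asarray(t, dtype=float)
    pos = t > 0
    ts = np.where(pos, t, 1.0) * s
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    out = (-v * ndtr(z1) + s * _npdf(z1) + v * ndtr(z2) - s * _npdf(z2)) / A
    out = np.where(pos, np.clip(out, 0.0, None), 0.0)
    return out if out.ndim else float(out)


def lba_cdf(t, A, b, v, s=1.0):
    """First-passage CDF of a single LBA accumulator; zero for ``t <= 0``."""
    _validate_single(A, b, s)
    t = np.asarray(t, dtype=float)
    pos = t > 0
    ts = np.where(pos, t, 1.0) * s
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    out = (
        1.0
        + (b - A - t * v) / A * ndtr(z1)
        - (b - t * v) / A * ndtr(z2)
        + ts / A * (_npdf(z1) - _npdf(z2))
    )
    out = np.where(pos, np.clip(out, 0.0, 1.0), 0.0)
    return out if out.ndim else float(out)


def trial_log_likelihood(rt, winner, v_correct, v_incorrect, A, b, t0, s=1.0):
    """Vectorised log defective density of observed (choice, RT) trials.

    Parameters are broadcast over trials.  ``winner`` is 0 where the correct
    accumulator won, 1 where the incorrect one did.  Trials with
    ``rt <= t0`` get exactly ``-inf`` (structural support violation); all
    other densities are floored at :data:`DENSITY_FLOOR` before logging so
    that mere underflow never produces ``-inf``.
    """
    rt = np.asarray(rt, dtype=float)
    winner = np.asarray(winner)
    td = rt - t0
    ok = td > 0
    tds = np.where(ok, td, 1.0)
    v_win = np.where(winner == 0, v_correct, v_incorrect)
    v_lose = np.where(winner == 0, v_incorrect, v_correct)
    dens = lba_pdf(tds, A, b, v_win, s) * (1.0 - lba_cdf(tds, A, b, v_lose, s))
    logdens = np.log(np.clip(dens, DENSITY_FLOOR, None))
    return np.where(ok, logdens, -np.inf)


def missing_log_likelihood(t_latent, v_correct, v_incorrect, A, b, t0, s=1.0):
    """Chance-accuracy contribution of a deadline-censored trial.

    A late response is assumed to have been at chance, so its latent RT
    contributes ``log(0.5 g_correct(t) + 0.5 g_incorrect(t))`` where ``g``
    is the defective density of each choice.
    """
    t_latent = np.asarray(t_latent, dtype=float)
    td = t_latent - t0
    ok = td > 0
    tds = np.where(ok, td, 1.0)
    g_c = lba_pdf(tds, A, b, v_correct, s) * (1.0 - lba_cdf(tds, A, b, v_incorrect, s))
    g_i = lba_pdf(tds, A, b, v_incorrect, s) * (1.0 - lba_cdf(tds, A, b, v_correct, s))
    dens = 0.5 * g_c + 0.5 * g_i
    logdens = np.log(np.clip(dens, DENSITY_FLOOR, None))
    return np.where(ok, logdens, -np.inf)


try:  # fast scalar kernels for the sampler's hot loop
    from numba import njit as _njit

    @_njit(cache=True)
    def _ll_kernel(rt, winner, vc, vi, A, b, t0, s, chance, out):  # pragma: no cover
        inv_sqrt2 = 0.7071067811865476
        inv_sqrt2pi = 0.3989422804014327
        floor = 1e-300
        for i in range(rt.shape[0]):
            td = rt[i] - t0[i]
            if td <= 0.0:
                out[i] = -np.inf
                continue
            ts = td * s
            a = A[i]
            dens = 0.0
            for side in range(2):
                if side == 0:
                    vw, vl = (vc[i], vi[i]) if winner[i] == 0 else (vi[i], vc[i])
                else:
                    if not chance:
                        break
                    vw, vl = (vi[i], vc[i]) if winner[i] == 0 else (vc[i], vi[i])
                z1 = (b[i] - a - td * vw) / ts
                z2 = (b[i] - td * vw) / ts
                p1 = 0.5 * (1.0 + math.erf(z1 * inv_sqrt2))
                p2 = 0.5 * (1.0 + math.erf(z2 * inv_sqrt2))
                d1 = inv_sqrt2pi * math.exp(-0.5 * z1 * z1)
                d2 = inv_sqrt2pi * math.exp(-0.5 * z2 * z2)
                pdf = (-vw * p1 + s * d1 + vw * p2 - s * d2) / a
                if pdf < 0.0:
                    pdf = 0.0
                z1 = (b[i] - a - td * vl) / ts
                z2 = (b[i] - td * vl) / ts
                p1 = 0.5 * (1.0 + math.erf(z1 * inv_sqrt2))
                p2 = 0.5 * (1.0 + math.erf(z2 * inv_sqrt2))
                d1 = inv_sqrt2pi * math.exp(-0.5 * z1 * z1)
                d2 = inv_sqrt2pi * math.exp(-0.5 * z2 * z2)
                cdf = (
                    1.0
                    + (b[i] - a - td * vl) / a * p1
                    - (b[i] - td * vl) / a * p2
                    + ts / a * (d1 - d2)
                )
                if cdf < 0.0:
                    cdf = 0.0
                elif cdf > 1.0:
                    cdf = 1.0
                dens += pdf * (1.0 - cdf)
            if chance:
                dens *= 0.5
            if dens < floor:
                dens = floor
            out[i] = math.log(dens)

    @_njit(cache=True)
    def _obs_ll_sums(drifts, A, b, t0, obs_p, vc_idx, vi_idx, winner, rt,
                     idx, out):  # pragma: no cover
        """Observed-trial log defective densities summed per participant
        (fused gather + density + reduction)."""
        inv_sqrt2 = 0.7071067811865476
        inv_sqrt2pi = 0.3989422804014327
        for k in range(idx.shape[0]):
            i = idx[k]
            p = obs_p[i]
            td = rt[i] - t0[p]
            if td <= 0.0:
                out[p] = -np.inf
                continue
            if winner[i] == 0:
                vw = drifts[p, vc_idx[i]]
                vl = drifts[p, vi_idx[i]]
            else:
                vw = drifts[p, vi_idx[i]]
                vl = drifts[p, vc_idx[i]]
            a = A[p]
            bb = b[p]
            z1 = (bb - a - td * vw) / td
            z2 = (bb - td * vw) / td
            p1 = 0.5 * (1.0 + math.erf(z1 * inv_sqrt2))
            p2 = 0.5 * (1.0 + math.erf(z2 * inv_sqrt2))
            d1 = inv_sqrt2pi * math.exp(-0.5 * z1 * z1)
            d2 = inv_sqrt2pi * math.exp(-0.5 * z2 * z2)
            pdf = (-vw * p1 + d1 + vw * p2 - d2) / a
            if pdf < 0.0:
                pdf = 0.0
            z1 = (bb - a - td * vl) / td
            z2 = (bb - td * vl) / td
            p1 = 0.5 * (1.0 + math.erf(z1 * inv_sqrt2))
            p2 = 0.5 * (1.0 + math.erf(z2 * inv_sqrt2))
            d1 = inv_sqrt2pi * math.exp(-0.5 * z1 * z1)
            d2 = inv_sqrt2pi * math.exp(-0.5 * z2 * z2)
            cdf = (
                1.0
                + (bb - a - td * vl) / a * p1
                - (bb - td * vl) / a * p2
                + td / a * (d1 - d2)
            )
            if cdf < 0.0:
                cdf = 0.0
            elif cdf > 1.0:
                cdf = 1.0
            dens = pdf * (1.0 - cdf)
            if dens < 1e-300:
                dens = 1e-300
            out[p] += math.log(dens)

    @_njit(cache=True)
    def _mis_ll_sums(drifts, A, b, t0, mis_p, vc_idx, vi_idx, latents,
                     idx, out):  # pragma: no cover
        """Chance-accuracy missing-trial terms summed per participant."""
        inv_sqrt2 = 0.7071067811865476
        inv_sqrt2pi = 0.3989422804014327
        for k in range(idx.shape[0]):
            i = idx[k]
            p = mis_p[i]
            td = latents[i] - t0[p]
            if td <= 0.0:
                out[p] = -np.inf
                continue
            a = A[p]
            bb = b[p]
            dens = 0.0
            for side in range(2):
                if side == 0:
                    vw = drifts[p, vc_idx[i]]
                    vl = drifts[p, vi_idx[i]]
                else:
                    vw = drifts[p, vi_idx[i]]
                    vl = drifts[p, vc_idx[i]]
                z1 = (bb - a - td * vw) / td
                z2 = (bb - td * vw) / td
                p1 = 0.5 * (1.0 + math.erf(z1 * inv_sqrt2))
                p2 = 0.5 * (1.0 + math.erf(z2 * inv_sqrt2))
                d1 = inv_sqrt2pi * math.exp(-0.5 * z1 * z1)
                d2 = inv_sqrt2pi * math.exp(-0.5 * z2 * z2)
                pdf = (-vw * p1 + d1 + vw * p2 - d2) / a
                if pdf < 0.0:
                    pdf = 0.0
                z1 = (bb - a - td * vl) / td
                z2 = (bb - td * vl) / td
                p1 = 0.5 * (1.0 + math.erf(z1 * inv_sqrt2))
                p2 = 0.5 * (1.0 + math.erf(z2 * inv_sqrt2))
                d1 = inv_sqrt2pi * math.exp(-0.5 * z1 * z1)
                d2 = inv_sqrt2pi * math.exp(-0.5 * z2 * z2)
                cdf = (
                    1.0
                    + (bb - a - td * vl) / a * p1
                    - (bb - td * vl) / a * p2
                    + td / a * (d1 - d2)
                )
                if cdf < 0.0:
                    cdf = 0.0
                elif cdf > 1.0:
                    cdf = 1.0
                dens += pdf * (1.0 - cdf)
            dens *= 0.5
            if dens < 1e-300:
                dens = 1e-300
            out[p] += math.log(dens)

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False
    _obs_ll_sums = None
    _mis_ll_sums = None


def trial_log_likelihood_fast(rt, winner, v_correct, v_incorrect, A, b, t0, s=1.0):
    """Jitted per-trial log defective density; equals
    :func:`trial_log_likelihood` (equality covered by tests) but avoids
    numpy temporaries in the sampler's hot loop."""
    if not HAVE_NUMBA:
        return trial_log_likelihood(rt, winner, v_correct, v_incorrect, A, b, t0, s)
    n = rt.shape[0]
    out = np.empty(n)
    _ll_kernel(
        np.ascontiguousarray(rt, dtype=np.float64),
        np.ascontiguousarray(winner, dtype=np.int64),
        np.ascontiguousarray(v_correct, dtype=np.float64),
        np.ascontiguousarray(v_incorrect, dtype=np.float64),
        np.ascontiguousarray(np.broadcast_to(A, (n,)), dtype=np.float64),
        np.ascontiguousarray(np.broadcast_to(b, (n,)), dtype=np.float64),
        np.ascontiguousarray(np.broadcast_to(t0, (n,)), dtype=np.float64),
        float(s),
        False,
        out,
    )
    return out


def missing_log_likelihood_fast(t_latent, v_correct, v_incorrect, A, b, t0, s=1.0):
    """Jitted chance-accuracy term; equals :func:`missing_log_likelihood`."""
    if not HAVE_NUMBA:
        return missing_log_likelihood(t_latent, v_correct, v_incorrect, A, b, t0, s)
    n = t_latent.shape[0]
    out = np.empty(n)
    _ll_kernel(
        np.ascontiguousarray(t_latent, dtype=np.float64),
        np.zeros(n, dtype=np.int64),
        np.ascontiguousarray(v_correct, dtype=np.float64),
        np.ascontiguousarray(v_incorrect, dtype=np.float64),
        np.ascontiguousarray(np.broadcast_to(A, (n,)), dtype=np.float64),
        np.ascontiguousarray(np.broadcast_to(b, (n,)), dtype=np.float64),
        np.ascontiguousarray(np.broadcast_to(t0, (n,)), dtype=np.float64),
        float(s),
        True,
        out,
    )
    return out


def defective_density(t, choice, params: LBAParams, condition: str, trial_type: str):
    """Joint density of responding ``choice`` at observed RT ``t``.

    ``f_choice(t - t0) * (1 - F_other(t - t0))``; zero for ``t <= t0``.
    """
    ci = accumulator_index(choice)
    c = condition_index(condition) if condition in CONDITIONS else params.conditions.index(condition)
    tt = trial_type_index(trial_type) if trial_type in TRIAL_TYPES else params.trial_types.index(trial_type)
    v_win = params.v[ci, c, tt]
    v_lose = params.v[1 - ci, c, tt]
    t = np.asarray(t, dtype=float)
    td = t - params.t0
    ok = td > 0
    tds = np.where(ok, td, 1.0)
    out = lba_pdf(tds, params.A, params.b, v_win, params.sv) * (
        1.0 - lba_cdf(tds, params.A, params.b, v_lose, params.sv)
    )
    out = np.where(ok, out, 0.0)
    return out if out.ndim else float(out)


def no_finish_probability(params: LBAParams, condition: str, trial_type: str) -> float:
    """Probability that neither accumulator ever finishes.

    An accumulator with a negative sampled drift never reaches threshold, so
    this is ``Phi(-v_c/s) * Phi(-v_i/s)``.
    """
    c = params.conditions.index(condition)
    tt = params.trial_types.index(trial_type)
    v_c, v_i = params.v[0, c, tt], params.v[1, c, tt]
    return float(ndtr(-v_c / params.sv) * ndtr(-v_i / params.sv))


def choice_probability(
    choice: str,
    params: LBAParams,
    condition: str,
    trial_type: str,
    *,
    upper: float = np.inf,
) -> float:
    """P(choice) by numeric quadrature of the defective density over (t0, inf)."""
    accumulator_index(choice)  # validate label

    def integrand(t):
        return defective_density(t, choice, params, condition, trial_type)

    prob, err = integrate.quad(
        integrand, params.t0, upper, limit=200, epsabs=1e-10, epsrel=1e-8
    )
    if err > 1e-5:
        raise RuntimeError(
            f"quadrature did not converge (estimated error {err:.2e})"
        )
    return float(prob)


def simulate_race(
    params: LBAParams,
    condition: str,
    trial_type: str,
    n: int,
    seed=None,
):
    """Simulate ``n`` two-accumulator races.

    Returns
    -------
    choice : ndarray of int, shape (n,)
        0 where the correct accumulator won, 1 where the incorrect one won,
        -1 where neither finished (both sampled drifts negative).
    rt : ndarray of float, shape (n,)
        Winner finish time plus ``t0``; ``inf`` for no-finisher trials.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    c = params.conditions.index(condition)
    tt = params.trial_types.index(trial_type)
    v = params.v[:, c, tt]  # (2,)
    starts = rng.uniform(0.0, params.A, size=(n, 2))
    drifts = rng.normal(loc=v, scale=params.sv, size=(n, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        finish = np.where(drifts > 0, (params.b - starts) / drifts, np.inf)
    winner = np.argmin(finish, axis=1)
    t_win = finish[np.arange(n), winner] if n else np.empty(0)
    none_finished = ~np.isfinite(t_win)
    choice = np.where(none_finished, -1, winner).astype(int)
    rt = np.where(none_finished, np.inf, t_win + params.t0)
    return choice, rt


def log_likelihood(
    trials,
    params: LBAParams,
    latent_missing_rts=None,
    *,
    deadline: float = 3.0,
    latent_cap: float = 10.0,
):
    """Total log-likelihood of a participant's trials under ``params``.

    Parameters
    ----------
    trials : pandas.DataFrame
        Must carry columns ``condition``, ``trial_type``, ``missing`` and,
        for non-missing rows, ``correct`` (bool) and ``rt_seconds``.
    latent_missing_rts : array-like, optional
        One latent RT per missing trial (in the order missing rows appear),
        each strictly greater than ``deadline`` and at most ``latent_cap``.
        A missing trial is assumed to have been answered at chance.

    Returns
    -------
    float
        The summed log-likelihood; ``-inf`` (with a warning) if any observed
        RT violates the ``rt > t0`` support constraint.
    """
    missing = np.asarray(trials["missing"], dtype=bool)
    n_missing = int(missing.sum())
    latent = np.asarray(
        [] if latent_missing_rts is None else latent_missing_rts, dtype=float
    )
    if latent.size != n_missing:
        raise ValueError(
            f"need exactly one latent RT per missing trial "
            f"({n_missing} missing, {latent.size} latents given)"
        )
    if np.any(latent <= deadline):
        raise ValueError("latent RTs must exceed the response deadline")
    if np.any(latent > latent_cap):
        raise ValueError(f"latent RTs must not exceed the cap ({latent_cap} s)")

    cond_idx = np.array([params.conditions.index(c) for c in trials["condition"]])
    type_idx = np.array([params.trial_types.index(t) for t in trials["trial_type"]])
    v_c = params.v[0, cond_idx, type_idx]
    v_i = params.v[1, cond_idx, type_idx]

    total = 0.0
    obs = ~missing
    if obs.any():
        rt = np.asarray(trials["rt_seconds"], dtype=float)[obs]
        winner = np.where(np.asarray(trials["correct"])[obs].astype(bool), 0, 1)
        ll = trial_log_likelihood(
            rt, winner, v_c[obs], v_i[obs], params.A, params.b, params.t0, params.sv
        )
        if np.any(np.isneginf(ll)):
            warnings.warn(
                f"{int(np.isneginf(ll).sum())} observed RT(s) at or below t0; "
                "log-likelihood is -inf",
                RuntimeWarning,
                stacklevel=2,
            )
            return float("-inf")
        total += float(ll.sum())
    if n_missing:
        ll_m = missing_log_likelihood(
            latent, v_c[missing], v_i[missing], params.A, params.b, params.t0, params.sv
        )
        total += float(ll_m.sum())
    return total
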