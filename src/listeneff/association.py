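"""Plausible-values association analysis.

Each retained posterior draw of the individual-level listening-efficiency
values is treated as a plausible realisation of the latent quantity; the
Pearson correlation with an external score, computed per draw, yields a
distribution of plausible sample correlations.  Mixing the exact posterior
of the population correlation ``p(rho | r, n)`` (uniform prior on rho,
bivariate-normal sampling density of r) over those draws propagates both
sampling and estimation uncertainty into a posterior for the population
correlation, from which directional certainty and a reliability decision
are read off.

A relative-importance (LMG) decomposition attributes the multiple-R^2 of a
linear model to predictors by averaging each predictor's R^2 increment
over all orderings.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .design import N_DRIFTS
from .labels import CONDITIONS, TRIAL_TYPES
from .metrics import hdi

__all__ = [
    "individual_efficiency",
    "plausible_correlations",
    "population_rho_posterior",
    "RhoPosterior",
    "reliability_flag",
    "relative_importance",
    "plausible_correlation_analysis",
]


def individual_efficiency(draws, trial_type: str = "sentence"):
    """Per-participant, per-draw differential drift averaged across
    conditions (sentence trials by default).

    Returns ``{group: array}`` of shape (n_draws, n_participants_in_group),
    ordered as ``draws.participants[group]``.
    """
    ti = TRIAL_TYPES.index(trial_type)
    ntype = len(TRIAL_TYPES)
    out = {}
    for g in draws.groups:
        th = draws.flat_theta(g)  # (n_draws, n_p, 15) on the log scale
        vdiff = np.stack(
            [
                np.exp(th[:, :, ci * ntype + ti])
                - np.exp(th[:, :, N_DRIFTS // 2 + ci * ntype + ti])
                for ci in range(len(CONDITIONS))
            ],
            axis=-1,
        )
        out[g] = vdiff.mean(axis=-1)
    return out


def plausible_correlations(efficiency_draws: np.ndarray, scores) -> np.ndarray:
    """Pearson correlation across participants, one value per draw.

    ``efficiency_draws`` is (n_draws, n_participants); ``scores`` a
    participant-aligned vector.
    """
    e = np.asarray(efficiency_draws, dtype=float)
    s = np.asarray(scores, dtype=float)
    if e.ndim != 2 or e.shape[1] != s.size:
        raise ValueError(
            f"efficiency draws {e.shape} do not align with {s.size} scores"
        )
    if s.size < 4:
        raise ValueError("need at least 4 participants with scores")
    if np.std(s) == 0:
        raise ValueError("scores are constant; the correlation is undefined")
    sz = (s - s.mean()) / s.std()
    ez = e - e.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(ez**2, axis=1))
    if np.any(denom == 0):
        raise ValueError("some draws have constant efficiency values")
    return (ez @ sz) / denom / math.sqrt(s.size)


def _log_r_density_kernel(rho: np.ndarray, r: float, n: int) -> np.ndarray:
    """Log kernel in rho of the bivariate-normal sampling density of the
    sample correlation r at sample size n (constant-in-rho terms dropped)."""
    with np.errstate(divide="ignore"):
        out = (
            0.5 * (n - 1) * np.log1p(-rho**2)
            - (n - 1.5) * np.log1p(-rho * r)
            + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0))
        )
    return out


@dataclass
class RhoPosterior:
    """Grid representation of the population-correlation posterior."""

    grid: np.ndarray
    pdf: np.ndarray  # normalised over the grid (trapezoid rule)
    r_draws: np.ndarray
    n: int
    mean: float = field(init=False)
    cri: tuple[float, float] = field(init=False)
    p_positive: float = field(init=False)
    p_negative: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean = float(np.trapezoid(self.grid * self.pdf, self.grid))
        cdf = _grid_cdf(self.grid, self.pdf)
        self.cri = _grid_hdi(self.grid, cdf, 0.95)
        self.p_positive = float(1.0 - np.interp(0.0, self.grid, cdf))
        self.p_negative = 1.0 - self.p_positive

    @property
    def certainty(self) -> float:
        return max(self.p_positive, self.p_negative)


def _grid_cdf(x: np.ndarray, pdf: np.ndarray) -> np.ndarray:
    dx = np.diff(x)
    incr = 0.5 * (pdf[1:] + pdf[:-1]) * dx
    cdf = np.concatenate([[0.0], np.cumsum(incr)])
    return cdf / cdf[-1]


def _grid_hdi(x: np.ndarray, cdf: np.ndarray, mass: float) -> tuple[float, float]:
    """Shortest interval holding ``mass`` on a gridded CDF."""
    uppers = np.searchsorted(cdf, cdf + mass, side="left")
    valid = uppers < len(x)
    widths = np.where(valid, x[np.clip(uppers, 0, len(x) - 1)] - x, np.inf)
    i = int(np.argmin(widths))
    return float(x[i]), float(x[uppers[i]])


def population_rho_posterior(
    r_values, n: int, grid_size: int = 2001, max_draws: int = 2000
) -> RhoPosterior:
    """Posterior of the population correlation, mixed over plausible draws.

    For each plausible sample correlation ``r`` the exact posterior under a
    uniform prior on rho is evaluated on a fixed grid over (-1, 1) and
    normalised; the returned posterior is the draw-average of those.  When
    more than ``max_draws`` r values are supplied an evenly spaced,
    deterministic subsample keeps the grid mixture affordable.
    """
    if n < 4:
        raise ValueError("need at least 4 participants")
    r = np.atleast_1d(np.asarray(r_values, dtype=float))
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    r = np.clip(r, -1.0, 1.0)
    if r.size > max_draws:
        r = r[np.linspace(0, r.size - 1, max_draws).astype(int)]
    grid = np.linspace(-1.0, 1.0, grid_size)
    inner = grid[1:-1]
    mix = np.zeros(grid_size)
    for rv in r:
        if abs(rv) == 1.0:
            # degenerate draw: all mass piles at rho = rv
            k = np.zeros(grid_size)
            k[0 if rv < 0 else -1] = 1.0
            mix += k / np.trapezoid(k, grid)
            continue
        logk = _log_r_density_kernel(inner, rv, n)
        k = np.zeros(grid_size)
        k[1:-1] = np.exp(logk - logk.max())
        mix += k / np.trapezoid(k, grid)
    pdf = mix / r.size
    pdf = pdf / np.trapezoid(pdf, grid)
    return RhoPosterior(grid=grid, pdf=pdf, r_draws=np.asarray(r_values, dtype=float), n=n)


def reliability_flag(posterior: RhoPosterior, certainty_threshold: float = 0.90):
    """Decision rule: the correlation is called reliable when the 95% CrI
    excludes zero or the directional certainty exceeds the threshold."""
    lo, hi = posterior.cri
    excludes_zero = lo > 0.0 or hi < 0.0
    certain = posterior.certainty > certainty_threshold
    return bool(excludes_zero or certain), posterior.certainty


# ---------------------------------------------------------------------------
# LMG relative importance
# ---------------------------------------------------------------------------


def relative_importance(predictors, responses) -> pd.DataFrame:
    """LMG decomposition of R^2, per posterior draw.

    Each predictor's share is its R^2 increment averaged over all
    predictor orderings; shares sum to the full-model R^2.  ``predictors``
    is an (n_participants, p) table (p <= 8, full column rank after
    centering); ``responses`` is (n_draws, n_participants) or a single
    response vector.

    Returns a DataFrame with one row per draw and one column per predictor
    (plus ``r2_full``).
    """
    X = pd.DataFrame(predictors)
    names = [str(c) for c in X.columns]
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if p > 8:
        raise ValueError("at most 8 predictors (exact permutation enumeration)")
    Y = np.atleast_2d(np.asarray(responses, dtype=float))
    if Y.shape[1] != n:
        raise ValueError("responses do not align with predictor rows")
    Xc = Xv - Xv.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < p:
        raise ValueError("predictor matrix is rank-deficient (collinear columns)")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Cxx = Xc.T @ Xc
    Cxy = Yc @ Xc  # (n_draws, p)
    ssy = np.sum(Yc**2, axis=1)
    if np.any(ssy == 0):
        raise ValueError("constant response in some draw")

    # R^2 for every predictor subset, vectorised over draws
    n_draws = Y.shape[0]
    r2 = {(): np.zeros(n_draws)}
    subsets = []
    for size in range(1, p + 1):
        subsets.extend(itertools.combinations(range(p), size))
    for S in subsets:
        idx = np.array(S)
        inv = np.linalg.inv(Cxx[np.ix_(idx, idx)])
        proj = Cxy[:, idx] @ inv
        r2[S] = np.einsum("ij,ij->i", proj, Cxy[:, idx]) / ssy

    shares = np.zeros((n_draws, p))
    fact = [math.factorial(i) for i in range(p + 1)]
    for j in range(p):
        others = [i for i in range(p) if i != j]
        for size in range(0, p):
            w = fact[size] * fact[p - size - 1] / fact[p]
            for S in itertools.combinations(others, size):
                Sj = tuple(sorted(S + (j,)))
                shares[:, j] += w * (r2[Sj] - r2[S])

    out = pd.DataFrame(shares, columns=names)
    out["r2_full"] = r2[tuple(range(p))]
    return out


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def plausible_correlation_analysis(
    draws,
    scores: pd.DataFrame,
    group: str,
    orientation: dict[str, int] | None = None,
    grid_size: int = 2001,
    r_draws_dir=None,
) -> list[dict]:
    """One association record per instrument for a group.

    ``scores`` is the long score table (participant_id, group, instrument,
    score).  ``orientation`` optionally flips an instrument's sign so
    correlations are reported in the conventionally plotted direction
    (e.g. hearing-ability scales without reverse scoring).  When
    ``r_draws_dir`` is given, the per-draw plausible correlations are
    additionally written there as one CSV per (group, instrument).
    """
    orientation = orientation or {}
    eff = individual_efficiency(draws)[group]
    pids = draws.participants[group]
    sub = scores[scores["group"] == group]
    records = []
    for instrument, tab in sub.groupby("instrument"):
        s = tab.set_index("participant_id")["score"]
        missing = [p for p in pids if p not in s.index]
        if missing:
            raise ValueError(
                f"participants missing from scores for {instrument!r}: {missing}"
            )
        vals = s.loc[pids].to_numpy(dtype=float) * orientation.get(instrument, 1)
        r = plausible_correlations(eff, vals)
        if r_draws_dir is not None:
            from pathlib import Path

            out = Path(r_draws_dir)
            out.mkdir(parents=True, exist_ok=True)
            pd.DataFrame({"draw": np.arange(r.size), "r": r}).to_csv(
                out / f"r_draws_{group}_{instrument}.csv", index=False
            )
        post = population_rho_posterior(r, n=len(pids), grid_size=grid_size)
        flag, certainty = reliability_flag(post)
        r_lo, r_hi = hdi(r) if r.size >= 20 else (float("nan"), float("nan"))
        records.append(
            {
                "group": group,
                "instrument": instrument,
                "n": len(pids),
                "r_mean": float(r.mean()),
                "r_cri_low": r_lo,
                "r_cri_high": r_hi,
                "rho_mean": post.mean,
                "rho_cri_low": post.cri[0],
                "rho_cri_high": post.cri[1],
                "p_positive": post.p_positive,
                "p_negative": post.p_negative,
                "certainty": certainty,
                "reliable": flag,
            }
        )
    return records
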