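"""Synthetic data generation: behaviour, ratings, and score tables.

Every generator is a pure function of (ground truth, design, seed), so any
downstream stage can be exercised end-to-end with known generative values
and bit-reproducible outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import lba
from .design import (
    DesignSpec,
    GroundTruth,
    N_DRIFTS,
    N_PARAMS,
    PARAM_NAMES,
    TRIAL_COLUMNS,
)
from .labels import CONDITIONS, QUESTIONS, TRIAL_TYPES
from .ratings import ordered_beta_rvs

__all__ = [
    "draw_participants",
    "simulate_behavior",
    "simulate_ratings",
    "simulate_scores",
    "params_from_vector",
]


def params_from_vector(theta: np.ndarray, drift_sign=None) -> lba.LBAParams:
    """Build :class:`~listeneff.lba.LBAParams` from a natural-scale
    15-vector in :data:`~listeneff.design.PARAM_NAMES` order."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (N_PARAMS,):
        raise ValueError(f"expected a length-{N_PARAMS} parameter vector")
    v = theta[:N_DRIFTS].copy()
    if drift_sign is not None:
        v = v * np.asarray(drift_sign, dtype=float)
    v = v.reshape(2, len(CONDITIONS), len(TRIAL_TYPES))
    return lba.LBAParams(A=theta[N_DRIFTS], k=theta[N_DRIFTS + 1],
                         t0=theta[N_DRIFTS + 2], v=v)


def draw_participants(
    truth: GroundTruth, spec: DesignSpec, seed=None
) -> dict[str, lba.LBAParams]:
    """Draw per-participant LBA parameters from the group-level model.

    Individual log-parameter vectors come from the group multivariate
    normal and are exponentiated to the natural scale (so A, k, t0 and the
    drift magnitudes are positive by construction); ``drift_sign`` then
    sets the sign of each generative drift mean.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, lba.LBAParams] = {}
    for group in spec.groups:
        cov = truth.covariance(group)
        # Cholesky doubles as the positive-definiteness check (zero
        # variances are allowed via a degenerate direct construction).
        sd = truth.log_sd[group]
        if np.all(sd == 0):
            chol = np.zeros((N_PARAMS, N_PARAMS))
        else:
            try:
                chol = np.linalg.cholesky(
                    cov + 1e-12 * np.eye(N_PARAMS) * np.max(np.diag(cov))
                )
            except np.linalg.LinAlgError:
                raise ValueError(
                    f"group {group!r} log-parameter covariance is not "
                    "positive definite"
                ) from None
        for pid in spec.participant_ids(group):
            z = rng.standard_normal(N_PARAMS)
            log_theta = truth.log_mean[group] + chol @ z
            out[pid] = params_from_vector(np.exp(log_theta), truth.drift_sign)
    return out


def simulate_behavior(
    schedule: pd.DataFrame,
    params: dict[str, lba.LBAParams],
    deadline: float = 3.0,
    seed=None,
) -> pd.DataFrame:
    """Fill a trial schedule with simulated choices and RTs.

    Each trial runs the two-accumulator race; the trial is marked missing
    when no accumulator finishes or the RT exceeds the deadline.  Sentence
    trials have a 50% probe-present design, so the yes/no response is
    derived from the correct answer and the race outcome; null trials carry
    an instructed response.
    """
    if not (deadline >= 0):
        raise ValueError("deadline must be >= 0")
    rng = np.random.default_rng(seed)
    out = schedule.copy().reset_index(drop=True)
    n = len(out)
    response = np.full(n, "none", dtype=object)
    correct = np.full(n, pd.NA, dtype=object)
    rts = np.full(n, np.nan)
    missing = np.ones(n, dtype=bool)

    for pid, sub in out.groupby("participant_id", sort=False):
        p = params[pid]
        for (cond, ttype), cell in sub.groupby(
            ["condition", "trial_type"], sort=False
        ):
            idx = cell.index.to_numpy()
            choice, rt = lba.simulate_race(
                p, cond, ttype, len(idx), seed=rng.integers(2**31)
            )
            ok = (choice >= 0) & (rt <= deadline)
            is_correct = choice == 0
            # ground-truth answer: 50% probe-present for sentence trials,
            # instructed response for null trials.
            answer_yes = rng.random(len(idx)) < 0.5
            resp_yes = np.where(is_correct, answer_yes, ~answer_yes)
            response[idx[ok]] = np.where(resp_yes[ok], "yes", "no")
            correct[idx[ok]] = is_correct[ok]
            rts[idx[ok]] = rt[ok]
            missing[idx[ok]] = False

    out["response"] = response
    out["correct"] = correct
    out["rt_seconds"] = rts
    out["missing"] = missing
    return out


def simulate_ratings(
    spec: DesignSpec, truth: GroundTruth, seed=None
) -> pd.DataFrame:
    """One visual-analog rating in [0, 1] per participant x condition x
    question, drawn from the ordered-beta generative model.

    The linear predictor is the group x condition x question cell effect
    plus a participant random intercept with group-specific SD; exact 0 and
    1 responses arise from the ordered cutpoints.
    """
    c1, c2 = truth.rating_cutpoints
    if not c1 < c2:
        raise ValueError("rating cutpoints must be ordered (c1 < c2)")
    rng = np.random.default_rng(seed)
    rows = []
    for pid in spec.participant_ids():
        group = spec.group_of(pid)
        u = rng.normal(0.0, truth.rating_intercept_sd.get(group, 0.0))
        for cond in spec.conditions:
            for q in QUESTIONS:
                eta = truth.rating_cell_effects[(group, q, cond)] + u
                y = ordered_beta_rvs(
                    eta, c1, c2, truth.rating_precision, rng=rng
                )
                rows.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "condition": cond,
                        "question": q,
                        "rating": float(y),
                    }
                )
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "condition", "question", "rating"]
    )


def simulate_scores(
    efficiency: pd.Series | dict[str, float],
    target_correlations: dict[str, float],
    score_ranges: dict[str, tuple[float, float]],
    seed=None,
    *,
    group: str = "",
    clip: bool = True,
) -> pd.DataFrame:
    """Per-instrument score tables with a requested population correlation
    to the supplied individual efficiency values.

    Scores are built by the linear-Gaussian construction
    ``z = rho * std(e) + sqrt(1 - rho^2) * eps`` and affinely mapped into
    the instrument's range (centre at midrange, one-sixth of the range per
    SD).  Clipping to the range slightly attenuates the realised
    correlation; pass ``clip=False`` for exact construction.
    """
    eff = pd.Series(efficiency, dtype=float)
    e = eff.to_numpy()
    if len(e) < 2 or np.std(e) == 0:
        raise ValueError("need at least two distinct efficiency values")
    ez = (e - e.mean()) / e.std()
    rng = np.random.default_rng(seed)
    rows = []
    for instrument, rho in target_correlations.items():
        if not -1.0 <= rho <= 1.0:
            raise ValueError(
                f"target correlation for {instrument!r} must be in [-1, 1]"
            )
        lo, hi = score_ranges[instrument]
        if not hi > lo:
            raise ValueError(f"invalid range for {instrument!r}")
        eps = rng.standard_normal(len(e))
        z = rho * ez + np.sqrt(1.0 - rho**2) * eps
        scores = (lo + hi) / 2.0 + z * (hi - lo) / 6.0
        if clip:
            scores = np.clip(scores, lo, hi)
        for pid, s in zip(eff.index, scores):
            rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "instrument": instrument,
                    "score": float(s),
                }
            )
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "instrument", "score"]
    )
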