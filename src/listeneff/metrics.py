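"""Listening-efficiency metrics from posterior draws.

Listening efficiency is operationalised as the differential drift rate
``vDiff = v_correct - v_incorrect``: the net rate at which a listener
accumulates evidence toward the correct response.  This module derives
per-draw vDiff by group/condition/trial type from posterior draws, their
mean and slope across the ordered difficulty conditions, between-group
differences, highest-density intervals, and Cliff's delta effect sizes on
posterior-predicted data.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .design import N_DRIFTS, N_PARAMS, PARAM_NAMES
from .labels import CONDITIONS, TRIAL_TYPES

__all__ = [
    "differential_drift",
    "condition_contrasts",
    "group_difference",
    "hdi",
    "cliffs_delta",
    "cliffs_delta_posterior",
    "efficiency_summary",
]

_N_COND = len(CONDITIONS)
_N_TYPE = len(TRIAL_TYPES)


def _drift_cube(mu_flat: np.ndarray) -> np.ndarray:
    """(n_draws, 15) log-scale group-level draws -> natural-scale drifts
    of shape (n_draws, 2, n_cond, n_type)."""
    if mu_flat.ndim != 2 or mu_flat.shape[1] < N_DRIFTS:
        raise ValueError(
            "expected draws with at least the 12 drift coordinates; "
            f"got shape {mu_flat.shape}"
        )
    return np.exp(mu_flat[:, :N_DRIFTS]).reshape(-1, 2, _N_COND, _N_TYPE)


def differential_drift(draws) -> dict[str, np.ndarray]:
    """Per-draw ``v_correct - v_incorrect`` by group, condition, trial type.

    ``draws`` is a :class:`~listeneff.hier.PosteriorDraws` (or anything with
    ``groups`` and ``flat_mu``).  Returns ``{group: array}`` with arrays of
    shape (n_draws, n_conditions, n_trial_types); a pure per-draw
    subtraction, no aggregation.
    """
    out = {}
    for g in draws.groups:
        cube = _drift_cube(draws.flat_mu(g))
        out[g] = cube[:, 0] - cube[:, 1]
    return out


def condition_contrasts(vdiff: np.ndarray) -> dict[str, np.ndarray]:
    """Per-draw mean and slope across the three ordered conditions.

    ``vdiff`` has conditions on its second-to-last or only trailing axis of
    length 3 (shape (n_draws, 3) or (n_draws, 3, n_types)).  The slope is
    the OLS slope on equally spaced condition codes, which for three points
    reduces to (Hard - Easy) / 2.
    """
    vdiff = np.asarray(vdiff, dtype=float)
    axis = 1 if vdiff.ndim > 1 else 0
    if vdiff.shape[axis] != _N_COND:
        raise ValueError(
            f"expected exactly {_N_COND} ordered conditions on axis {axis}, "
            f"got {vdiff.shape[axis]}"
        )
    codes = np.arange(1, _N_COND + 1, dtype=float)
    xc = codes - codes.mean()
    mean = vdiff.mean(axis=axis)
    slope = np.tensordot(
        np.moveaxis(vdiff, axis, -1), xc, axes=([-1], [0])
    ) / np.sum(xc**2)
    return {"mean": mean, "slope": slope}


def group_difference(draws_a: np.ndarray, draws_b: np.ndarray, mass: float = 0.95):
    """Per-draw difference ``a - b`` with posterior mean and HDI.

    Draws must be aligned (equal counts, matching draw indexing).
    """
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"misaligned draws: {a.shape} vs {b.shape}")
    diff = a - b
    lo, hi = hdi(diff.ravel(), mass=mass)
    return diff, {"mean": float(diff.mean()), "hdi_low": lo, "hdi_high": hi}


def hdi(sample, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval: the shortest contiguous window holding
    ``ceil(mass * n)`` sorted draws; ties break toward the smallest lower
    bound.
    """
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    n = x.size
    if n < 20:
        raise ValueError(f"need at least 20 draws for an HDI, got {n}")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    m = math.ceil(mass * n)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: lowest lower bound
    return float(x[i]), float(x[i + m - 1])


def cliffs_delta(x, y) -> float:
    """Cliff's delta ``[#(x>y) - #(x<y)] / (n_x n_y)`` over all pairs.

    Computed in O(n log n) via sorted rank counts; bounded in [-1, 1] and
    antisymmetric under swapping the samples.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left").sum()  # pairs with x > y
    less = (y.size - np.searchsorted(ys, x, side="right")).sum()  # x < y
    return float((greater - less) / (x.size * y.size))


def cliffs_delta_posterior(
    values_a: np.ndarray,
    values_b: np.ndarray,
    mass: float = 0.95,
    pooled: bool = False,
):
    """Cliff's delta per posterior draw with summary over draws.

    ``values_a`` / ``values_b`` are posterior-predicted participant-level
    values, shape (n_draws, n_participants_in_group); one delta per draw
    by default.  With ``pooled=True`` all draws are pooled into one sample
    per group and a single delta is returned (as a length-1 array).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("expected aligned (n_draws, n_participants) arrays")
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("both groups must be non-empty")
    if pooled:
        d = cliffs_delta(a.ravel(), b.ravel())
        return np.array([d]), {"mean": d, "cri_low": np.nan, "cri_high": np.nan}
    deltas = np.array([cliffs_delta(a[d], b[d]) for d in range(a.shape[0])])
    lo, hi = hdi(deltas, mass=mass) if deltas.size >= 20 else (np.nan, np.nan)
    return deltas, {"mean": float(deltas.mean()), "cri_low": lo, "cri_high": hi}


def efficiency_summary(draws, mass: float = 0.95) -> pd.DataFrame:
    """Table of group-level posterior means and HDIs for t0, response
    caution, and the differential drift rates (per condition, plus mean and
    slope across conditions), with between-group differences.

    Rows follow the published layout; columns are per-group mean and CrI
    bounds plus the difference (second group minus first, i.e. NH - CI for
    the default group labels).
    """
    groups = sorted(draws.groups)
    if len(groups) != 2:
        raise ValueError("efficiency summary needs exactly two groups")
    ga, gb = groups  # alphabetical: CI, NH -> difference reported as gb - ga
    per_group: dict[str, dict[str, np.ndarray]] = {g: {} for g in groups}
    for g in groups:
        mu = draws.flat_mu(g)
        cube = _drift_cube(mu)
        vdiff = cube[:, 0] - cube[:, 1]  # (n, cond, type)
        A = np.exp(mu[:, N_DRIFTS])
        k = np.exp(mu[:, N_DRIFTS + 1])
        per_group[g]["t0"] = np.exp(mu[:, N_DRIFTS + 2])
        per_group[g]["resp_caution"] = k + A / 2.0
        for ti, ttype in enumerate(TRIAL_TYPES):
            label = ttype.capitalize()
            for ci, cond in enumerate(CONDITIONS):
                per_group[g][f"vDiff.{label}.{cond}"] = vdiff[:, ci, ti]
            contrasts = condition_contrasts(vdiff[:, :, ti])
            per_group[g][f"vDiff.{label}.Mean"] = contrasts["mean"]
            per_group[g][f"vDiff.{label}.Slope"] = contrasts["slope"]

    row_order = ["t0", "resp_caution"]
    for ttype in TRIAL_TYPES:
        label = ttype.capitalize()
        row_order += [f"vDiff.{label}.{c}" for c in CONDITIONS]
    for ttype in TRIAL_TYPES:
        label = ttype.capitalize()
        row_order += [f"vDiff.{label}.Mean", f"vDiff.{label}.Slope"]

    rows = []
    for name in row_order:
        da, db = per_group[ga][name], per_group[gb][name]
        lo_a, hi_a = hdi(da, mass)
        lo_b, hi_b = hdi(db, mass)
        _, dsum = group_difference(db, da, mass)
        rows.append(
            {
                "parameter": name,
                f"{gb}_mean": float(db.mean()),
                f"{gb}_cri_low": lo_b,
                f"{gb}_cri_high": hi_b,
                f"{ga}_mean": float(da.mean()),
                f"{ga}_cri_low": lo_a,
                f"{ga}_cri_high": hi_a,
                "diff_mean": dsum["mean"],
                "diff_cri_low": dsum["hdi_low"],
                "diff_cri_high": dsum["hdi_high"],
            }
        )
    return pd.DataFrame(rows)
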