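"""Study design: trial schedule and generative ground truth.

The emulated experiment is a speeded yes/no speech-in-noise task: two groups
(cochlear-implant users and normally-hearing controls), two runs per
participant, each run containing one block per SNR condition (Easy/Med/Hard),
each block 28 trials (18 sentence + 10 null) with a 3 s response deadline.
Sentence trials require listening; null trials are an instructed button
press, isolating task execution from the listening process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import ACCUMULATORS, CONDITIONS, GROUPS, QUESTIONS, TRIAL_TYPES

__all__ = [
    "DesignSpec",
    "GroundTruth",
    "PARAM_NAMES",
    "N_PARAMS",
    "build_design",
    "default_ground_truth",
    "TRIAL_COLUMNS",
]

#: Exact column order of the trial CSV (schedule metadata columns are
#: appended after these when present).
TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "run",
    "block_index",
    "condition",
    "trial_index",
    "trial_type",
    "response",
    "correct",
    "rt_seconds",
    "missing",
]


def _drift_name(acc: str, cond: str, ttype: str) -> str:
    return f"v_{acc}.{ttype.capitalize()}.{cond}"


#: Canonical order of the 15-dimensional per-participant parameter vector:
#: 12 drift means (accumulator x condition x trial type, C order) followed
#: by the three structural parameters.
PARAM_NAMES: tuple[str, ...] = tuple(
    _drift_name(acc, cond, ttype)
    for acc in ACCUMULATORS
    for cond in CONDITIONS
    for ttype in TRIAL_TYPES
) + ("A", "k", "t0")

N_PARAMS = len(PARAM_NAMES)  # 15
N_DRIFTS = len(ACCUMULATORS) * len(CONDITIONS) * len(TRIAL_TYPES)  # 12


@dataclass
class DesignSpec:
    """Counts and timing that define the trial schedule."""

    n_group_a: int = 24  # CI
    n_group_b: int = 25  # NH
    runs_per_participant: int = 2
    conditions: tuple[str, ...] = CONDITIONS
    trials_per_block: int = 28
    sentence_trials_per_block: int = 18
    null_trials_per_block: int = 10
    response_deadline: float = 3.0
    #: (participant_id, runs completed) for participants who stopped early.
    partial_completers: tuple[tuple[str, int], ...] = ()
    groups: tuple[str, str] = GROUPS

    def __post_init__(self) -> None:
        for name in ("n_group_a", "n_group_b", "runs_per_participant",
                     "trials_per_block", "sentence_trials_per_block",
                     "null_trials_per_block"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sentence_trials_per_block + self.null_trials_per_block != self.trials_per_block:
            raise ValueError(
                "sentence + null trial counts must equal trials_per_block "
                f"({self.sentence_trials_per_block} + {self.null_trials_per_block} "
                f"!= {self.trials_per_block})"
            )
        if len(self.conditions) != 3:
            raise ValueError("exactly three ordered conditions are required")
        if not (self.response_deadline > 0):
            raise ValueError("response_deadline must be > 0")
        self.partial_completers = tuple(
            (str(p), int(r)) for p, r in self.partial_completers
        )
        known = set(self.participant_ids())
        for pid, runs in self.partial_completers:
            if pid not in known:
                raise ValueError(f"partial completer {pid!r} is not a participant")
            if not (0 <= runs <= self.runs_per_participant):
                raise ValueError(f"invalid completed-run count for {pid!r}: {runs}")

    def participant_ids(self, group: str | None = None) -> list[str]:
        ga, gb = self.groups
        a = [f"{ga}{i + 1:02d}" for i in range(self.n_group_a)]
        b = [f"{gb}{i + 1:02d}" for i in range(self.n_group_b)]
        if group is None:
            return a + b
        if group == ga:
            return a
        if group == gb:
            return b
        raise ValueError(f"unknown group {group!r}")

    def group_of(self, participant_id: str) -> str:
        for g in self.groups:
            if participant_id.startswith(g):
                return g
        raise ValueError(f"cannot infer group of {participant_id!r}")

    def runs_completed(self, participant_id: str) -> int:
        for pid, runs in self.partial_completers:
            if pid == participant_id:
                return runs
        return self.runs_per_participant

    @property
    def trials_per_run(self) -> int:
        return len(self.conditions) * self.trials_per_block

    def total_trials(self) -> int:
        return sum(
            self.runs_completed(p) * self.trials_per_run
            for p in self.participant_ids()
        )


def build_design(spec: DesignSpec, seed=0) -> pd.DataFrame:
    """Lay out the full trial schedule (no outcomes yet).

    Per participant and completed run, one block per condition in a
    randomised order, each block interleaving sentence and null trials in
    randomised order.  Block order and the per-trial stimulus-onset jitter
    (6-10 s) are carried as schedule metadata only; they enter no
    likelihood.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    trial_types = np.array(
        ["sentence"] * spec.sentence_trials_per_block
        + ["null"] * spec.null_trials_per_block
    )
    for pid in spec.participant_ids():
        group = spec.group_of(pid)
        for run in range(spec.runs_completed(pid)):
            block_order = rng.permutation(len(spec.conditions))
            for block_index, cond_idx in enumerate(block_order):
                condition = spec.conditions[cond_idx]
                order = rng.permutation(len(trial_types))
                onsets = rng.uniform(6.0, 10.0, size=len(trial_types))
                for trial_index, (tt, onset) in enumerate(
                    zip(trial_types[order], onsets)
                ):
                    rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "run": run,
                            "block_index": block_index,
                            "condition": condition,
                            "trial_index": trial_index,
                            "trial_type": tt,
                            "response": "none",
                            "correct": pd.NA,
                            "rt_seconds": np.nan,
                            "missing": True,
                            "onset_jitter": onset,
                        }
                    )
    columns = TRIAL_COLUMNS + ["onset_jitter"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns)


@dataclass
class GroundTruth:
    """Generative population parameters for the synthetic study.

    Individual parameter vectors are drawn on the log scale from a
    multivariate normal per group and exponentiated, which guarantees
    positive A, k, t0 and positive drift magnitudes; negative generative
    drifts remain expressible through ``drift_sign``.

    ``log_mean`` / ``log_sd`` follow the :data:`PARAM_NAMES` order.  The
    default values are anchored to the published group-level posterior
    means of the study this package emulates (see docs/methods.md).
    """

    log_mean: dict[str, np.ndarray]
    log_sd: dict[str, np.ndarray]
    log_corr: np.ndarray | None = None
    #: Optional per-accumulator sign flips for the 12 drift cells (+1/-1).
    drift_sign: np.ndarray = field(
        default_factory=lambda: np.ones(N_DRIFTS)
    )
    #: Ordered-beta linear predictors per (group, question, condition).
    rating_cell_effects: dict[tuple[str, str, str], float] = field(default_factory=dict)
    rating_cutpoints: tuple[float, float] = (-3.0, 3.0)
    rating_precision: float = 8.0
    rating_intercept_sd: dict[str, float] = field(default_factory=dict)
    #: instrument -> (target correlation with efficiency, low, high) per group.
    score_specs: dict[str, dict[str, tuple[float, float, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for g, m in self.log_mean.items():
            self.log_mean[g] = np.asarray(m, dtype=float)
            if self.log_mean[g].shape != (N_PARAMS,):
                raise ValueError(f"log_mean[{g!r}] must have length {N_PARAMS}")
        for g, s in self.log_sd.items():
            self.log_sd[g] = np.asarray(s, dtype=float)
            if np.any(self.log_sd[g] < 0):
                raise ValueError("log_sd entries must be non-negative")
        if self.log_corr is not None:
            self.log_corr = np.asarray(self.log_corr, dtype=float)
            _check_correlation(self.log_corr)
        self.drift_sign = np.asarray(self.drift_sign, dtype=float)
        if not np.all(np.isin(self.drift_sign, (-1.0, 1.0))):
            raise ValueError("drift_sign entries must be +1 or -1")
        for specs in self.score_specs.values():
            for rho, lo, hi in specs.values():
                if not -1.0 <= rho <= 1.0:
                    raise ValueError("target correlations must lie in [-1, 1]")
                if not hi > lo:
                    raise ValueError("score range must have high > low")

    def covariance(self, group: str) -> np.ndarray:
        sd = self.log_sd[group]
        corr = np.eye(N_PARAMS) if self.log_corr is None else self.log_corr
        return np.outer(sd, sd) * corr


def _check_correlation(corr: np.ndarray) -> None:
    if corr.shape != (N_PARAMS, N_PARAMS):
        raise ValueError(f"correlation matrix must be {N_PARAMS}x{N_PARAMS}")
    if not np.allclose(corr, corr.T):
        raise ValueError("correlation matrix must be symmetric")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError("correlation matrix must be positive semi-definite")


# Group-level posterior means of the published fit (differential drift per
# condition/trial type, t0, response caution); the generator re-expresses
# them as v_correct = vDiff + baseline incorrect drift.
_TABLE_VDIFF = {
    "NH": {"sentence": (4.14, 4.04, 3.62), "null": (4.32, 4.20, 4.50)},
    "CI": {"sentence": (2.79, 2.16, 1.57), "null": (3.60, 3.74, 4.10)},
}
_BASELINE_V_INCORRECT = 0.5
_TABLE_T0 = {"NH": 0.21, "CI": 0.21}
_DEFAULT_A = 1.0
_TABLE_CAUTION = {"NH": 2.76, "CI": 2.70}  # k = caution - A/2

# Approximate published cell means of the three task ratings (effort,
# intelligibility, disengagement) per group across Easy/Med/Hard, mapped to
# the ordered-beta linear predictor via the logit of the target mean.
_RATING_MEANS = {
    ("CI", "EF"): (0.48, 0.69, 0.82),
    ("NH", "EF"): (0.02, 0.04, 0.10),
    ("CI", "IN"): (0.83, 0.74, 0.59),
    ("NH", "IN"): (0.99, 0.99, 0.98),
    ("CI", "TD"): (0.017, 0.02, 0.04),
    ("NH", "TD"): (0.006, 0.005, 0.004),
}

# Published individual-level correlations with listening efficiency in the
# CI group (SSQ12 without reversing, EAS, TRT); NH correlations were null.
_SCORE_SPECS = {
    "SSQ12": {"CI": (0.4, 0.0, 10.0), "NH": (0.0, 0.0, 10.0)},
    "EAS": {"CI": (-0.3, 0.0, 60.0), "NH": (0.0, 0.0, 60.0)},
    "TRT": {"CI": (-0.4, 0.0, 100.0), "NH": (0.0, 0.0, 100.0)},
    "RSpan": {"CI": (0.0, 0.0, 100.0), "NH": (0.0, 0.0, 100.0)},
}


def default_ground_truth(
    drift_log_sd: float = 0.15,
    structural_log_sd: float = 0.10,
) -> GroundTruth:
    """Ground truth anchored to the published group-level estimates.

    ``drift_log_sd`` / ``structural_log_sd`` set the between-participant
    spread on the log scale (modest individual differences around the group
    means).
    """

    def logit(p):
        return float(np.log(p / (1.0 - p)))

    log_mean: dict[str, np.ndarray] = {}
    log_sd: dict[str, np.ndarray] = {}
    for group in GROUPS:
        vals = []
        for acc in ACCUMULATORS:
            for ci, cond in enumerate(CONDITIONS):
                for ttype in TRIAL_TYPES:
                    vdiff = _TABLE_VDIFF[group][ttype][ci]
                    v = (
                        vdiff + _BASELINE_V_INCORRECT
                        if acc == "correct"
                        else _BASELINE_V_INCORRECT
                    )
                    vals.append(np.log(v))
        vals.append(np.log(_DEFAULT_A))
        vals.append(np.log(_TABLE_CAUTION[group] - _DEFAULT_A / 2.0))
        vals.append(np.log(_TABLE_T0[group]))
        log_mean[group] = np.array(vals)
        log_sd[group] = np.array(
            [drift_log_sd] * N_DRIFTS + [structural_log_sd] * 3
        )

    effects = {
        (g, q, cond): logit(means[i])
        for (g, q), means in _RATING_MEANS.items()
        for i, cond in enumerate(CONDITIONS)
    }
    return GroundTruth(
        log_mean=log_mean,
        log_sd=log_sd,
        rating_cell_effects=effects,
        rating_intercept_sd={g: 0.5 for g in GROUPS},
        score_specs={k: dict(v) for k, v in _SCORE_SPECS.items()},
    )
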