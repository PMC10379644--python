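"""End-to-end orchestration: simulate -> fit -> metrics -> associate ->
ratings -> report, with a manifest for reproducibility.

A single top-level seed deterministically derives per-stage substreams, so
identical configs give byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .association import individual_efficiency, plausible_correlation_analysis
from .design import DesignSpec, GroundTruth, build_design, default_ground_truth
from .hier import ModelSpec, Priors, build_model, sample_posterior
from .labels import QUESTIONS
from .metrics import efficiency_summary
from .ratings import fit_rating_model
from .synthetic import (
    draw_participants,
    simulate_behavior,
    simulate_ratings,
    simulate_scores,
)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and error record."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.record = {"stage": stage, "error": type(cause).__name__,
                       "message": str(cause)}


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    mode: str = "simulate"  # or "data"
    spec: DesignSpec = field(default_factory=DesignSpec)
    truth: GroundTruth | None = None
    trials_csv: str | None = None
    scores_csv: str | None = None
    ratings_csv: str | None = None
    chains: int = 4
    warmup: int = 1000
    iters: int = 2000
    thin: int = 5
    hdi_mass: float = 0.95
    rho_grid_size: int = 2001
    fit_ratings: bool = True
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    priors: Priors = field(default_factory=Priors)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.mode not in ("simulate", "data"):
            raise ValueError("mode must be 'simulate' or 'data'")
        if self.mode == "data":
            for name in ("trials_csv", "scores_csv", "ratings_csv"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ValueError(f"{name} path does not exist: {p}")
            if self.trials_csv is None:
                raise ValueError("data mode requires trials_csv")

    def digest(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "mode": self.mode,
                "chains": self.chains,
                "warmup": self.warmup,
                "iters": self.iters,
                "thin": self.thin,
                "hdi_mass": self.hdi_mass,
                "rho_grid_size": self.rho_grid_size,
                "spec": repr(self.spec),
                "truth": "default" if self.truth is None else "custom",
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the result bundle under ``config.out_dir``.

    Returns the manifest dict (also written as ``manifest.json``).  Any
    stage failure aborts with :class:`StageError`, after writing a
    machine-readable ``error.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = dict(zip(
        ("design", "participants", "behavior", "ratings", "scores", "fit",
         "ratings_fit"),
        ss.spawn(7),
    ))
    manifest: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "mode": config.mode,
        "versions": {
            "listeneff": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    err = StageError(name, exc)
                    with open(out / "error.json", "w") as fh:
                        json.dump(err.record, fh, indent=2)
                    raise err from exc
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t0, 3)
                }
                return False

        return _Ctx()

    truth = config.truth or default_ground_truth()
    spec = config.spec

    # --- stage: obtain data -------------------------------------------------
    with stage("data"):
        if config.mode == "simulate":
            schedule = build_design(spec, seed=stage_seeds["design"])
            params = draw_participants(truth, spec, seed=stage_seeds["participants"])
            trials = simulate_behavior(
                schedule, params, deadline=spec.response_deadline,
                seed=stage_seeds["behavior"],
            )
            ratings = simulate_ratings(spec, truth, seed=stage_seeds["ratings"])
            score_frames = []
            score_rng = np.random.default_rng(stage_seeds["scores"])
            for group in spec.groups:
                pids = spec.participant_ids(group)
                true_eff = pd.Series(
                    {
                        pid: float(
                            np.mean(params[pid].v[0, :, 0] - params[pid].v[1, :, 0])
                        )
                        for pid in pids
                    }
                )
                targets = {
                    inst: per[group][0]
                    for inst, per in truth.score_specs.items()
                    if group in per
                }
                ranges = {
                    inst: (per[group][1], per[group][2])
                    for inst, per in truth.score_specs.items()
                    if group in per
                }
                if targets:
                    score_frames.append(
                        simulate_scores(
                            true_eff, targets, ranges,
                            seed=score_rng.integers(2**31), group=group,
                        )
                    )
            scores = (
                pd.concat(score_frames, ignore_index=True)
                if score_frames
                else pd.DataFrame(columns=io.SCORE_COLUMNS)
            )
            io.write_trials(trials, out / "trials.csv")
            io.write_ratings(ratings, out / "ratings.csv")
            io.write_scores(scores, out / "scores.csv")
        else:
            trials = io.read_trials(config.trials_csv)
            scores = (
                io.read_scores(config.scores_csv)
                if config.scores_csv
                else pd.DataFrame(columns=io.SCORE_COLUMNS)
            )
            ratings = (
                io.read_ratings(config.ratings_csv)
                if config.ratings_csv
                else pd.DataFrame(columns=io.RATING_COLUMNS)
            )
            report = validate_inputs(trials, scores, ratings,
                                     deadline=spec.response_deadline)
            if report["errors"]:
                raise ValueError(f"input validation failed: {report['errors']}")

    # --- stage: hierarchical fit -------------------------------------------
    with stage("fit"):
        model = build_model(trials, config.model_spec, config.priors)
        draws = sample_posterior(
            model,
            chains=config.chains,
            warmup=config.warmup,
            iters=config.iters,
            thin=config.thin,
            seed=stage_seeds["fit"],
        )
        draws.to_files(out / "draws.csv", out / "draws_meta.json")
        finite = [v for v in draws.rhat.values() if np.isfinite(v)]
        manifest["fit"] = {
            "n_draws": draws.n_draws,
            "rhat_min": min(finite) if finite else None,
            "rhat_max": max(finite) if finite else None,
        }

    # --- stage: efficiency metrics -----------------------------------------
    with stage("metrics"):
        summary = efficiency_summary(draws, mass=config.hdi_mass)
        summary.to_csv(out / "efficiency_summary.csv", index=False)

    # --- stage: associations -------------------------------------------------
    with stage("associate"):
        records = []
        if len(scores):
            for group in draws.groups:
                if (scores["group"] == group).any():
                    records.extend(
                        plausible_correlation_analysis(
                            draws, scores, group,
                            grid_size=config.rho_grid_size,
                        )
                    )
        with open(out / "associations.json", "w") as fh:
            json.dump(records, fh, indent=2)

    # --- stage: rating models ------------------------------------------------
    with stage("ratings"):
        frames = []
        if config.fit_ratings and len(ratings):
            for q in sorted(ratings["question"].unique()):
                fit = fit_rating_model(
                    ratings[ratings["question"] == q],
                    chains=2,
                    warmup=min(config.warmup, 400),
                    iters=min(config.iters, 400),
                    seed=stage_seeds["ratings_fit"],
                )
                s = fit.summary(mass=config.hdi_mass)
                s.insert(0, "question", q)
                frames.append(s)
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out / "rating_summary.csv", index=False
            )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def validate_inputs(
    trials: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    ratings: pd.DataFrame | None = None,
    deadline: float = 3.0,
) -> dict:
    """Schema, range, and referential checks on input tables.

    Returns ``{"errors": [...], "warnings": [...]}``; errors are fatal for
    the pipeline, warnings are not.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    from .design import TRIAL_COLUMNS
    from .labels import CONDITIONS

    missing_cols = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing_cols:
        errors.append(f"trials: missing columns {sorted(missing_cols)}")
        return {"errors": errors, "warnings": warnings_}

    bad_cond = set(trials["condition"]) - set(CONDITIONS)
    if bad_cond:
        errors.append(f"trials: unknown condition labels {sorted(bad_cond)}")
    obs = trials[~trials["missing"].astype(bool)]
    if (obs["rt_seconds"] <= 0).any():
        errors.append("trials: non-positive RT on non-missing trials")
    late = obs["rt_seconds"] > deadline
    if late.any():
        errors.append(
            f"trials: {int(late.sum())} non-missing trial(s) with RT beyond "
            f"the {deadline} s deadline"
        )
    if obs["correct"].isna().any():
        errors.append("trials: non-missing trials must define correctness")
    mis = trials[trials["missing"].astype(bool)]
    if (mis["response"] != "none").any():
        errors.append("trials: missing trials must have response 'none'")

    known = set(trials["participant_id"])
    for name, tab in (("scores", scores), ("ratings", ratings)):
        if tab is None or not len(tab):
            continue
        extra = set(tab["participant_id"]) - known
        if extra:
            warnings_.append(
                f"{name}: participants absent from trials: {sorted(extra)}"
            )
    if ratings is not None and len(ratings):
        out_of_range = (ratings["rating"] < 0) | (ratings["rating"] > 1)
        if out_of_range.any():
            errors.append("ratings: values outside [0, 1]")
    return {"errors": errors, "warnings": warnings_}
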