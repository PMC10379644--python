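"""CSV and config I/O for trials, ratings, scores, and study configs.

Column orders are fixed contracts (see the trial schema in
:mod:`listeneff.design`); missing numeric fields serialise as empty
strings so the tables round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import DesignSpec, GroundTruth, TRIAL_COLUMNS

__all__ = [
    "write_trials",
    "read_trials",
    "write_ratings",
    "read_ratings",
    "write_scores",
    "read_scores",
    "load_config",
    "dump_config",
]

RATING_COLUMNS = ["participant_id", "group", "condition", "question", "rating"]
SCORE_COLUMNS = ["participant_id", "group", "instrument", "score"]


def write_trials(trials: pd.DataFrame, path) -> None:
    out = trials.copy()
    cols = TRIAL_COLUMNS + [c for c in out.columns if c not in TRIAL_COLUMNS]
    out = out[cols]
    out["correct"] = out["correct"].map(
        lambda v: "" if pd.isna(v) else str(bool(v))
    )
    out["rt_seconds"] = out["rt_seconds"].map(
        lambda v: "" if pd.isna(v) else repr(float(v))
    )
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "group": str, "condition": str,
               "trial_type": str, "response": str},
        keep_default_na=False,
        na_values=[],
    )
    df["correct"] = df["correct"].map(
        lambda v: pd.NA if v == "" else v == "True"
    )
    df["rt_seconds"] = pd.to_numeric(
        df["rt_seconds"].replace("", np.nan), errors="raise"
    )
    df["missing"] = df["missing"].astype(str).str.lower().isin(("true", "1"))
    for col in ("run", "block_index", "trial_index"):
        df[col] = df[col].astype(int)
    return df


def write_ratings(ratings: pd.DataFrame, path) -> None:
    ratings[RATING_COLUMNS].to_csv(path, index=False)


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(RATING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ratings CSV lacks columns: {sorted(missing)}")
    return df


def write_scores(scores: pd.DataFrame, path) -> None:
    scores[SCORE_COLUMNS].to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scores CSV lacks columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Study config (YAML with JSON equivalence): seed + DesignSpec + GroundTruth
# ---------------------------------------------------------------------------


def dump_config(spec: DesignSpec, truth: GroundTruth, seed: int, path) -> None:
    cfg = {
        "seed": int(seed),
        "design": {
            "n_group_a": spec.n_group_a,
            "n_group_b": spec.n_group_b,
            "runs_per_participant": spec.runs_per_participant,
            "conditions": list(spec.conditions),
            "trials_per_block": spec.trials_per_block,
            "sentence_trials_per_block": spec.sentence_trials_per_block,
            "null_trials_per_block": spec.null_trials_per_block,
            "response_deadline": spec.response_deadline,
            "partial_completers": [list(t) for t in spec.partial_completers],
            "groups": list(spec.groups),
        },
        "ground_truth": {
            "log_mean": {g: m.tolist() for g, m in truth.log_mean.items()},
            "log_sd": {g: s.tolist() for g, s in truth.log_sd.items()},
            "log_corr": None if truth.log_corr is None else truth.log_corr.tolist(),
            "drift_sign": truth.drift_sign.tolist(),
            "rating_cell_effects": {
                "|".join(k): v for k, v in truth.rating_cell_effects.items()
            },
            "rating_cutpoints": list(truth.rating_cutpoints),
            "rating_precision": truth.rating_precision,
            "rating_intercept_sd": dict(truth.rating_intercept_sd),
            "score_specs": {
                inst: {g: list(v) for g, v in per.items()}
                for inst, per in truth.score_specs.items()
            },
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_config(path) -> tuple[DesignSpec, GroundTruth, int]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "seed" not in cfg:
        raise ValueError("config must define a top-level seed")
    d = cfg.get("design", {})
    d["conditions"] = tuple(d.get("conditions", ("Easy", "Med", "Hard")))
    d["groups"] = tuple(d.get("groups", ("CI", "NH")))
    d["partial_completers"] = tuple(
        tuple(t) for t in d.get("partial_completers", ())
    )
    spec = DesignSpec(**d)
    g = cfg["ground_truth"]
    truth = GroundTruth(
        log_mean={k: np.asarray(v) for k, v in g["log_mean"].items()},
        log_sd={k: np.asarray(v) for k, v in g["log_sd"].items()},
        log_corr=None if g.get("log_corr") is None else np.asarray(g["log_corr"]),
        drift_sign=np.asarray(g.get("drift_sign", np.ones(12))),
        rating_cell_effects={
            tuple(k.split("|")): v
            for k, v in g.get("rating_cell_effects", {}).items()
        },
        rating_cutpoints=tuple(g.get("rating_cutpoints", (-3.0, 3.0))),
        rating_precision=g.get("rating_precision", 8.0),
        rating_intercept_sd=g.get("rating_intercept_sd", {}),
        score_specs={
            inst: {grp: tuple(v) for grp, v in per.items()}
            for inst, per in g.get("score_specs", {}).items()
        },
    )
    return spec, truth, int(cfg["seed"])
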