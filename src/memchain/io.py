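"""File formats and the shared YAML configuration dialect.

Retention data travel as plain CSV with columns ``group,time,successes,
trials`` (a ``proportion`` column is accepted on read when counts are
absent). Model objects -- chains, lesion profiles, learning schedules,
simulation designs and fit specifications -- serialize to a flat YAML
mapping; floats round-trip at full repr precision.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import yaml

from .chain import ChainParams, StoreParams
from .fitting import FitSpec, ParamSpec, RetentionDataset
from .learning import LearningSchedule
from .pathology import LesionProfile
from .synthetic import GroupDesign, SimDesign

__all__ = [
    "read_retention", "write_retention",
    "chain_to_dict", "chain_from_dict",
    "lesion_to_dict", "lesion_from_dict",
    "schedule_to_dict", "schedule_from_dict",
    "design_to_dict", "design_from_dict",
    "fitspec_to_dict", "fitspec_from_dict",
    "load_yaml", "save_yaml",
]


# ---------------------------------------------------------------------------
# retention CSV

def read_retention(path) -> RetentionDataset:
    """Read and validate a retention CSV; all violations reported at once."""
    df = pd.read_csv(path)
    missing = {"group", "time"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    has_counts = {"successes", "trials"} <= set(df.columns)
    if not has_counts and "proportion" not in df.columns:
        raise ValueError(f"{path}: need successes/trials columns or a proportion column")
    if not has_counts and "trials" not in df.columns:
        warnings.warn(f"{path}: proportion data without trial counts; "
                      "points cannot be weighted and the binomial loss is "
                      "unavailable", stacklevel=2)
    try:
        return RetentionDataset(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_retention(dataset: RetentionDataset, path) -> None:
    df = dataset.frame.copy()
    if dataset.has_counts:
        df["successes"] = df["successes"].astype(int)
        df["trials"] = df["trials"].astype(int)
        df = df[["group", "time", "successes", "trials"]]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# config dialect

def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return data


def save_yaml(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def chain_to_dict(params: ChainParams) -> dict:
    return {
        "stores": [{"mu": s.mu, "a": s.a, "decline_kind": s.decline_kind}
                   for s in params.stores],
        "q": params.q,
        "g": params.g,
    }


def chain_from_dict(data: dict) -> ChainParams:
    stores = tuple(StoreParams(float(s["mu"]), float(s["a"]),
                               s.get("decline_kind", "exponential"))
                   for s in data["stores"])
    return ChainParams(stores, q=float(data.get("q", 1.0)), g=float(data.get("g", 0.0)))


def lesion_to_dict(lesion: LesionProfile) -> dict:
    return {
        "intensity_lesion": list(lesion.intensity_lesion),
        "induction_scale": list(lesion.induction_scale),
        "retrieval_scale": lesion.retrieval_scale,
        "lesion_time": lesion.lesion_time,
    }


def lesion_from_dict(data: dict) -> LesionProfile:
    return LesionProfile(
        intensity_lesion=tuple(data.get("intensity_lesion", ())),
        induction_scale=tuple(data.get("induction_scale", ())),
        retrieval_scale=float(data.get("retrieval_scale", 1.0)),
        lesion_time=data.get("lesion_time"),
    )


def schedule_to_dict(schedule: LearningSchedule) -> dict:
    return {
        "trial_times": list(schedule.trial_times),
        "trials_per_episode": list(schedule.trials_per_episode),
        "massed_factor": list(schedule.massed_factor),
    }


def schedule_from_dict(data: dict) -> LearningSchedule:
    return LearningSchedule(
        trial_times=tuple(data["trial_times"]),
        trials_per_episode=tuple(data["trials_per_episode"])
        if data.get("trials_per_episode") is not None else None,
        massed_factor=tuple(data["massed_factor"])
        if data.get("massed_factor") is not None else None,
    )


def design_to_dict(design: SimDesign) -> dict:
    groups = {}
    for name, grp in design.groups.items():
        entry = {
            "chain": chain_to_dict(grp.params),
            "times": list(grp.times),
            "n": list(grp.n),
        }
        if grp.lesion is not None:
            entry["lesion"] = lesion_to_dict(grp.lesion)
        if grp.difficulty is not None:
            entry["difficulty"] = list(grp.difficulty)
        groups[name] = entry
    return {"groups": groups, "seed": design.seed}


def design_from_dict(data: dict) -> SimDesign:
    groups = {}
    for name, entry in data["groups"].items():
        groups[name] = GroupDesign(
            params=chain_from_dict(entry["chain"]),
            times=tuple(entry["times"]),
            n=tuple(entry["n"]) if isinstance(entry["n"], (list, tuple)) else int(entry["n"]),
            lesion=lesion_from_dict(entry["lesion"]) if "lesion" in entry else None,
            difficulty=tuple(entry["difficulty"]) if "difficulty" in entry else None,
        )
    return SimDesign(groups=groups, seed=int(data["seed"]))


def _paramspec_to_dict(ps: ParamSpec) -> dict:
    if ps.is_free:
        out = {"free": True, "bounds": list(ps.bounds)}
        if ps.value is not None:
            out["init"] = ps.value
        return out
    return {"value": ps.value}


def _paramspec_from_dict(data: dict) -> ParamSpec:
    if data.get("free"):
        lo, hi = data["bounds"]
        return ParamSpec.free(float(lo), float(hi), data.get("init"))
    return ParamSpec.fixed(float(data["value"]))


def fitspec_to_dict(spec: FitSpec) -> dict:
    return {
        "n_stores": spec.n_stores,
        "loss": spec.loss,
        "multistart": spec.multistart,
        "seed": spec.seed,
        "chain": {k: _paramspec_to_dict(v) for k, v in spec.chain.items()},
        "lesions": {g: {k: _paramspec_to_dict(v) for k, v in entries.items()}
                    for g, entries in spec.lesions.items()},
    }


def fitspec_from_dict(data: dict) -> FitSpec:
    return FitSpec(
        n_stores=int(data.get("n_stores", 2)),
        chain={k: _paramspec_from_dict(v) for k, v in data.get("chain", {}).items()},
        lesions={g: {k: _paramspec_from_dict(v) for k, v in entries.items()}
                 for g, entries in data.get("lesions", {}).items()},
        loss=data.get("loss", "ls_prob"),
        multistart=int(data.get("multistart", 32)),
        seed=int(data.get("seed", 0)),
    )
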