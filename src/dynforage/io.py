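"""Serialization: tidy-CSV session records, JSON metadata, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .schedule import DatasetConfig, ScheduleConfig, SessionData

_CHOICE_CODES = np.array(["R", "G"])


def sessions_to_frame(sessions: Sequence[SessionData]) -> pd.DataFrame:
    """One row per trial: day, session, trial, block, choice, reward, free."""
    parts = []
    for i, s in enumerate(sessions):
        parts.append(
            pd.DataFrame(
                {
                    "day": s.meta.get("day", 0),
                    "session": s.meta.get("session", i),
                    "trial": np.arange(s.n_trials),
                    "block": s.block_id,
                    "choice": _CHOICE_CODES[s.choice],
                    "reward": s.reward.astype(int),
                    "free_choice": s.free_choice.astype(int),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def frame_to_sessions(
    frame: pd.DataFrame, meta: dict | None = None
) -> list[SessionData]:
    """Rebuild sessions from a tidy trial table (+ optional metadata map).

    ``meta`` maps stringified session ids to metadata dicts, as written by
    :func:`save_sessions`.
    """
    meta = meta or {}
    out = []
    for sid, g in frame.groupby("session", sort=True):
        g = g.sort_values("trial")
        m = dict(meta.get(str(sid), {}))
        m.setdefault("session", int(sid))
        if "day" in g.columns:
            m.setdefault("day", int(g["day"].iloc[0]))
        out.append(
            SessionData(
                choice=(g["choice"].to_numpy() == "G").astype(np.int8),
                reward=g["reward"].to_numpy(np.int8),
                free_choice=g["free_choice"].to_numpy(bool),
                block_id=g["block"].to_numpy(np.int64),
                meta=m,
            )
        )
    return out


def save_sessions(sessions: Sequence[SessionData], csv_path: str | Path) -> Path:
    """Write trials as CSV plus a ``<stem>.meta.json`` metadata sidecar."""
    csv_path = Path(csv_path)
    sessions_to_frame(sessions).to_csv(csv_path, index=False)
    meta = {
        str(s.meta.get("session", i)): _jsonable(s.meta)
        for i, s in enumerate(sessions)
    }
    side = csv_path.with_suffix(".meta.json")
    side.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return csv_path


def load_sessions(csv_path: str | Path) -> list[SessionData]:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    side = csv_path.with_suffix(".meta.json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return frame_to_sessions(frame, meta)


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        out[k] = v
    return out


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def schedule_config_from_dict(d: dict) -> ScheduleConfig:
    kwargs = dict(d)
    if "ratio_set" in kwargs:
        kwargs["ratio_set"] = tuple(tuple(p) for p in kwargs["ratio_set"])
    if "block_length_range" in kwargs:
        kwargs["block_length_range"] = tuple(kwargs["block_length_range"])
    return ScheduleConfig(**kwargs)


def dataset_config_from_dict(d: dict) -> DatasetConfig:
    kwargs = dict(d)
    if "schedule" in kwargs:
        kwargs["schedule"] = schedule_config_from_dict(kwargs["schedule"])
    if kwargs.get("weight_drift") is not None:
        kwargs["weight_drift"] = np.asarray(kwargs["weight_drift"], dtype=float)
    return DatasetConfig(**kwargs)
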