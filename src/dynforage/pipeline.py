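"""End-to-end orchestration: simulate -> metrics -> fit -> lmit (-> cascade).

A pipeline run is fully determined by a config mapping and a seed; every
artifact is written under one output directory and listed, with a content
hash, in ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io, lmit, metrics
from .agents import make_agent
from .cascade import CascadeParams, run_cascade_experiment
from .fitting import FitConfig, fit_dataset
from .schedule import generate_dataset

log = logging.getLogger("dynforage")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


def make_weight_drift(base_weights, w_slow_values) -> np.ndarray:
    """Per-session weight rows with the slow (last) weight following
    ``w_slow_values`` and the fast weights rescaled proportionally."""
    base = np.asarray(base_weights, dtype=float)
    ws = np.asarray(w_slow_values, dtype=float)
    fast = base[:-1]
    fast_sum = fast.sum()
    if fast_sum <= 0:
        raise ValueError("base weights must put mass on fast timescales")
    rows = np.empty((len(ws), len(base)))
    rows[:, :-1] = (1.0 - ws)[:, None] * (fast / fast_sum)[None, :]
    rows[:, -1] = ws
    return rows


def _require(config: dict, key: str) -> dict:
    if key not in config:
        raise PipelineError(f"[config] missing required config key: {key!r}")
    return config[key]


def _write(path: Path, content: str, overwrite: bool) -> Path:
    if path.exists() and not overwrite:
        raise PipelineError(f"[io] refusing to overwrite {path} (use overwrite)")
    path.write_text(content)
    return path


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise PipelineError(f"[{name}] {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("simulate")
def stage_simulate(config: dict, seed: int):
    dcfg = io.dataset_config_from_dict(dict(_require(config, "dataset")))
    agent_cfg = dict(_require(config, "agent"))
    model = agent_cfg.pop("model", "multi_timescale")
    drift = agent_cfg.pop("w_slow_drift", None)
    if drift is not None:
        n = dcfg.n_sessions
        ws = np.linspace(float(drift[0]), float(drift[1]), n)
        dcfg.weight_drift = make_weight_drift(agent_cfg["weights"], ws)
    rng = np.random.default_rng(seed)
    return generate_dataset(dcfg, lambda s: make_agent(model, **agent_cfg), rng)


@_stage("metrics")
def stage_metrics(sessions, config: dict):
    opts = config.get("metrics", {})
    return metrics.summarize_dataset(
        sessions,
        last_n=opts.get("last_n", 50),
        min_rewards=opts.get("min_rewards", 5),
        span=opts.get("span", 200),
    )


@_stage("fit")
def stage_fit(sessions, config: dict, seed: int):
    opts = dict(config.get("fit", {}))
    opts.setdefault("seed", seed)
    if "taus" in opts:
        opts["taus"] = tuple(opts["taus"])
    return fit_dataset(sessions, FitConfig(**opts))


@_stage("lmit")
def stage_lmit(summaries, config: dict):
    opts = config.get("lmit", {})
    cfg = lmit.LmitConfig(
        window=opts.get("window", 25),
        gamma=opts.get("gamma", 0.5),
        exclude_first=opts.get("exclude_first", 25),
    )
    return lmit.lmit_series(summaries, cfg), cfg


@_stage("cascade")
def stage_cascade(config: dict, seed: int):
    dcfg = io.dataset_config_from_dict(dict(_require(config, "dataset")))
    params = CascadeParams(**config.get("cascade", {}))
    rng = np.random.default_rng(seed)
    return run_cascade_experiment(dcfg, params, rng)


def run_pipeline(
    config: dict,
    seed: int,
    out_dir: str | Path,
    overwrite: bool = False,
    with_cascade: bool = False,
) -> dict:
    """Execute the full pipeline deterministically and write artifacts.

    Returns the manifest mapping (also written to ``manifest.json``):
    file name -> sha256 of content, plus the seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    sessions = stage_simulate(config, seed)
    csv = out / "sessions.csv"
    if csv.exists() and not overwrite:
        raise PipelineError(f"[io] refusing to overwrite {csv} (use overwrite)")
    io.save_sessions(sessions, csv)
    files += [csv, csv.with_suffix(".meta.json")]

    summaries = stage_metrics(sessions, config)
    files.append(
        _write(out / "session_summaries.csv", summaries.to_csv(index=False), overwrite)
    )

    if config.get("fit", {}).get("enabled", True):
        dfit = stage_fit(sessions, config, seed)
        files.append(
            _write(out / "session_fits.csv", dfit.table.to_csv(index=False), overwrite)
        )
        files.append(
            _write(
                out / "fit_correlation.json",
                json.dumps(
                    {
                        "w_slow_undermatching_correlation": dfit.correlation,
                        "p_value": dfit.p_value,
                    },
                    indent=1,
                ),
                overwrite,
            )
        )

    n_needed = 25 + 25 + 5
    if len(summaries) > n_needed:
        traj, _ = stage_lmit(summaries, config)
        files.append(
            _write(out / "lmit_trajectory.csv", traj.to_csv(index=False), overwrite)
        )
    else:
        log.info("lmit skipped: %d sessions (need > %d)", len(summaries), n_needed)

    if with_cascade:
        cas = stage_cascade(config, seed + 1)
        ccsv = out / "cascade_sessions.csv"
        if ccsv.exists() and not overwrite:
            raise PipelineError(f"[io] refusing to overwrite {ccsv}")
        io.save_sessions(cas, ccsv)
        files += [ccsv, ccsv.with_suffix(".meta.json")]
        csum = stage_metrics(cas, config)
        files.append(
            _write(
                out / "cascade_summaries.csv", csum.to_csv(index=False), overwrite
            )
        )

    manifest = {"seed": seed, "files": {}}
    for f in sorted(set(files)):
        digest = hashlib.sha256(f.read_bytes()).hexdigest()
        manifest["files"][f.name] = digest
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
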