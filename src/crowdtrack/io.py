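"""Configuration files, CSV dialects, results JSON and run manifests.

All CSVs are UTF-8, comma-separated, '.' decimal, header required. The
fixed dialect (and fixed float formatting) keeps reruns byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .observer import (ContinuousTrial, Dataset, ObserverConfig, ParticipantData,
                       TrackingTrace, TrialBasedReport)
from .paradigm import ConfigError, ParadigmConfig, StimulusTrace

_FLOAT_FMT = "%.6f"

TRACKING_COLUMNS = ["trial_id", "frame", "time_s", "condition", "trend",
                    "target_ori_deg", "response_ori_deg", "distance_deg",
                    "is_jump", "gap_mask"]
STIMULUS_COLUMNS = ["trial_id", "frame", "time_s", "condition", "trend",
                    "target_ori_deg", "flank1_ori_deg", "flank2_ori_deg",
                    "flank3_ori_deg", "flank4_ori_deg", "distance_deg",
                    "direction", "is_jump"]
TRIAL_BASED_COLUMNS = ["trial_id", "condition", "distance_deg",
                       "target_ori_deg", "report_ori_deg"]


@dataclass
class RunConfig:
    paradigm: ParadigmConfig
    observers: list
    n_runs: int = 2


def _build_dataclass(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    try:
        return cls(**data)
    except ConfigError as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def read_config(path) -> RunConfig:
    """Read a YAML/JSON run configuration; missing fields take the defaults.

    Schema: top-level keys ``paradigm`` (mapping), ``observers`` (list of
    mappings) or ``n_observers`` (int), and ``n_runs``. An empty file yields
    the full default study configuration. Unknown keys are rejected.
    """
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(data) - {"paradigm", "observers", "n_observers", "n_runs"}
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")
    paradigm = _build_dataclass(ParadigmConfig, data.get("paradigm") or {},
                                f"{path}: paradigm")
    if "observers" in data and data["observers"] is not None:
        observers = [_build_dataclass(ObserverConfig, o or {},
                                      f"{path}: observers[{i}]")
                     for i, o in enumerate(data["observers"])]
    else:
        n_obs = int(data.get("n_observers", 8))
        if n_obs < 1:
            raise ConfigError(f"{path}: n_observers must be >= 1")
        observers = [ObserverConfig(observer_id=f"obs{i + 1:02d}", seed=i + 1)
                     for i in range(n_obs)]
    n_runs = int(data.get("n_runs", 2))
    if n_runs < 1:
        raise ConfigError(f"{path}: n_runs must be >= 1")
    return RunConfig(paradigm, observers, n_runs)


def _config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    d.pop("trial_based_kappa_fn", None)  # not serializable; default derived
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def write_config(run_config: RunConfig, path) -> None:
    data = {"paradigm": _config_to_dict(run_config.paradigm),
            "observers": [_config_to_dict(o) for o in run_config.observers],
            "n_runs": run_config.n_runs}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def stimulus_frame(trace: StimulusTrace) -> pd.DataFrame:
    n = trace.n_frames
    is_jump = np.zeros(n, dtype=int)
    is_jump[trace.jump_indices] = 1
    gaps = trace.flanker_gap_orientations_deg
    df = pd.DataFrame({
        "trial_id": trace.trial_id, "frame": np.arange(n), "time_s": trace.time_s,
        "condition": trace.condition, "trend": trace.distance_trend,
        "target_ori_deg": trace.target_orientation_deg,
    })
    for k in range(4):
        df[f"flank{k + 1}_ori_deg"] = gaps[:, k] if gaps is not None else np.nan
    df["distance_deg"] = trace.flanker_distance_deg
    df["direction"] = trace.rotation_direction.astype(int)
    df["is_jump"] = is_jump
    return df[STIMULUS_COLUMNS]


def tracking_frame(trace: TrackingTrace) -> pd.DataFrame:
    n = trace.time_s.size
    is_jump = np.zeros(n, dtype=int)
    is_jump[trace.jump_indices] = 1
    return pd.DataFrame({
        "trial_id": trace.trial_id, "frame": np.arange(n), "time_s": trace.time_s,
        "condition": trace.condition, "trend": trace.distance_trend,
        "target_ori_deg": trace.theta_stimulus_deg,
        "response_ori_deg": trace.theta_response_deg,
        "distance_deg": trace.flanker_distance_deg,
        "is_jump": is_jump, "gap_mask": trace.gap_mask.astype(int),
    })[TRACKING_COLUMNS]


def write_tracking_csv(trials, path) -> None:
    df = pd.concat([tracking_frame(t.tracking if isinstance(t, ContinuousTrial) else t)
                    for t in trials], ignore_index=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_tracking_csv(path) -> list:
    """Read a tracking CSV back into per-trial TrackingTrace objects."""
    df = pd.read_csv(path)
    missing = set(TRACKING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces = []
    for trial_id, g in df.groupby("trial_id", sort=False):
        g = g.sort_values("frame")
        traces.append(TrackingTrace(
            trial_id=str(trial_id),
            time_s=g["time_s"].to_numpy(),
            theta_stimulus_deg=g["target_ori_deg"].to_numpy(),
            theta_response_deg=g["response_ori_deg"].to_numpy(),
            condition=str(g["condition"].iloc[0]),
            distance_trend=str(g["trend"].iloc[0]),
            jump_indices=np.flatnonzero(g["is_jump"].to_numpy()),
            flanker_distance_deg=g["distance_deg"].to_numpy(),
            gap_mask=g["gap_mask"].to_numpy().astype(bool),
        ))
    return traces


def write_trial_based_csv(reports, path) -> None:
    df = pd.DataFrame([{
        "trial_id": r.trial_id, "condition": r.condition,
        "distance_deg": np.nan if r.distance_deg is None else r.distance_deg,
        "target_ori_deg": r.target_ori_deg, "report_ori_deg": r.report_ori_deg,
    } for r in reports])[TRIAL_BASED_COLUMNS]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trial_based_csv(path) -> list:
    df = pd.read_csv(path)
    missing = set(TRIAL_BASED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [TrialBasedReport(
        trial_id=str(row.trial_id), condition=str(row.condition),
        distance_deg=None if pd.isna(row.distance_deg) else float(row.distance_deg),
        target_ori_deg=float(row.target_ori_deg),
        report_ori_deg=float(row.report_ori_deg)) for row in df.itertuples()]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(data, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True,
                                     default=_json_default) + "\n",
                          encoding="utf-8")


def write_dataset(dataset: Dataset, out_dir, seed: int,
                  include_timestamp: bool = False) -> Path:
    """Write a dataset to per-participant directories plus a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for part in dataset.participants:
        pdir = out / part.observer.observer_id
        pdir.mkdir(exist_ok=True)
        for r, run in enumerate(part.continuous_runs):
            p = pdir / f"continuous_run{r + 1}.csv"
            write_tracking_csv(run, p)
            files.append(p)
        p = pdir / "trial_based.csv"
        write_trial_based_csv(part.trial_based, p)
        files.append(p)
        p = pdir / "observer.yaml"
        p.write_text(yaml.safe_dump(_config_to_dict(part.observer), sort_keys=True),
                     encoding="utf-8")
        files.append(p)
    manifest = {
        "seed": seed,
        "paradigm_config": _config_to_dict(dataset.paradigm_config),
        "paradigm_config_sha256": hashlib.sha256(
            json.dumps(_config_to_dict(dataset.paradigm_config),
                       sort_keys=True).encode()).hexdigest(),
        "n_participants": len(dataset.participants),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
        "crowdtrack_version": _version(),
    }
    if include_timestamp:
        import datetime
        manifest["written_at"] = datetime.datetime.now().isoformat()
    write_json(manifest, out / "manifest.json")
    return out


def verify_manifest(data_dir) -> list:
    """Return the list of files whose hash no longer matches the manifest."""
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    bad = []
    for rel, digest in manifest["files"].items():
        p = data_dir / rel
        if not p.exists() or _sha256(p) != digest:
            bad.append(rel)
    return bad


def read_dataset(data_dir) -> Dataset:
    """Load a dataset written by :func:`write_dataset`."""
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    config = ParadigmConfig(**{k: v for k, v in manifest["paradigm_config"].items()})
    participants = []
    for pdir in sorted(d for d in data_dir.iterdir() if d.is_dir()):
        obs_data = yaml.safe_load((pdir / "observer.yaml").read_text())
        observer = ObserverConfig(**obs_data)
        runs = []
        r = 1
        while (pdir / f"continuous_run{r}.csv").exists():
            traces = read_tracking_csv(pdir / f"continuous_run{r}.csv")
            runs.append([_trial_from_trace(t) for t in traces])
            r += 1
        reports = read_trial_based_csv(pdir / "trial_based.csv")
        participants.append(ParticipantData(observer, runs, reports))
    return Dataset(config, participants, seed=manifest.get("seed", 0))


def _trial_from_trace(trace: TrackingTrace):
    """Wrap a loaded TrackingTrace as a ContinuousTrial (no stimulus geometry)."""
    from .paradigm import TrialSpec
    spec = TrialSpec("continuous", trace.condition, distance_trend=trace.distance_trend,
                     jump_times_s=tuple(trace.time_s[trace.jump_indices]),
                     trial_id=trace.trial_id)
    return ContinuousTrial(spec, None, trace)


def _version() -> str:
    from . import __version__
    return __version__
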