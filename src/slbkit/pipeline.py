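"""Reproducible multi-stage runs from a YAML configuration.

A run config names an output directory, a seed, and an ordered list of
stages; every stage writes its tables/JSON under the output directory and
the run finishes with a manifest (package version, full config echo, config
hash, per-stage outputs).  Re-running the same config reproduces the same
manifest hash and, because all randomness is seeded, the same numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import binding_geom, confinement, kinetics, simgen, tracks_io
from .core import Track

logger = logging.getLogger("slbkit")

__all__ = ["RunConfig", "run_pipeline", "load_config"]

_TOP_KEYS = {"seed", "output_dir", "log_level", "stages"}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration."""

    seed: int
    output_dir: Path
    stages: list[dict]
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = raw.get("stages") or []
        for st in stages:
            bad = set(st) - {"name", "params"}
            if bad:
                raise ValueError(f"unknown stage keys: {sorted(bad)}")
            if st.get("name") not in _STAGES:
                raise ValueError(
                    f"unknown stage {st.get('name')!r}; "
                    f"available: {sorted(_STAGES)}")
        return cls(seed=int(raw.get("seed", 0)),
                   output_dir=Path(raw.get("output_dir", "slbkit_out")),
                   stages=stages,
                   log_level=str(raw.get("log_level", "INFO")))


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the configured stages in order and write the run manifest.

    Returns the manifest dict.  A stage failure aborts the run with the
    stage name in the exception; outputs of completed stages persist.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    logging.basicConfig(level=config.log_level)
    out_dir = config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    echo = {"seed": config.seed, "output_dir": str(config.output_dir),
            "log_level": config.log_level, "stages": config.stages}
    blob = json.dumps(echo, sort_keys=True).encode()
    manifest = {"package": "slbkit", "version": __version__,
                "config": echo,
                "config_sha256": hashlib.sha256(blob).hexdigest(),
                "stage_outputs": {}}
    ctx: dict = {"seed": config.seed}
    for i, st in enumerate(config.stages):
        name, params = st["name"], dict(st.get("params") or {})
        logger.info("stage %d/%d %s params=%s", i + 1, len(config.stages),
                    name, params)
        try:
            outputs = _STAGES[name](ctx, params, out_dir)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        manifest["stage_outputs"][f"{i:02d}_{name}"] = outputs
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate_tracks(ctx, params, out_dir: Path) -> dict:
    params.setdefault("seed", ctx["seed"])
    cfg = simgen.TwoStateSimConfig(**params)
    tracks, truth = simgen.simulate_two_state_tracks(cfg)
    tracks_path = out_dir / "tracks.csv"
    tracks_io.write_tracks(tracks, tracks_path)
    truth_path = out_dir / "ground_truth_events.csv"
    with open(truth_path, "w") as fh:
        fh.write("track_id,start_time_s,end_time_s,zone_id\n")
        for e in truth:
            fh.write(f"{e.track_id},{e.start_time!r},{e.end_time!r},"
                     f"{e.zone_id}\n")
    ctx["tracks"] = tracks
    return {"tracks": str(tracks_path), "ground_truth": str(truth_path)}


def _stage_confine(ctx, params, out_dir: Path) -> dict:
    path = params.pop("tracks", None)
    if path is not None:
        tracks = tracks_io.read_tracks(
            path, frame_interval=params.pop("frame_interval", None))
    elif "tracks" in ctx:
        tracks = ctx["tracks"]
    else:
        raise ValueError("no tracks: give a 'tracks' path or run a "
                         "simulate_tracks stage first")
    p_thresh = float(params.pop("p_thresh", 1000.0))
    t_thresh = float(params.pop("t_thresh", 0.25))
    window_n = params.pop("window_n", None)
    min_duration = float(params.pop("min_track_duration", 1.0))
    if params:
        raise ValueError(f"unknown confine parameters: {sorted(params)}")
    tracks = confinement.filter_tracks(tracks, min_duration=min_duration)
    events = []
    for t in tracks:
        events.extend(confinement.detect_events(
            t, p_thresh=p_thresh, t_thresh=t_thresh, window_n=window_n))
    ev_path = out_dir / "confinement_events.csv"
    with open(ev_path, "w") as fh:
        fh.write("track_id,t_start_s,t_end_s,duration_s,x_um,y_um,"
                 "mean_p_um-2\n")
        for e in events:
            fh.write(f"{e.track_id},{e.start_time!r},{e.end_time!r},"
                     f"{e.duration!r},{e.centroid[0]!r},{e.centroid[1]!r},"
                     f"{e.mean_p!r}\n")
    stats = confinement.confinement_stats(events, tracks)
    stats_path = out_dir / "confinement_stats.json"
    stats_path.write_text(json.dumps({
        "mean_confinement_time_s": stats.mean_confinement_time,
        "tau_stderr_s": stats.tau_stderr,
        "confined_fraction_percent": stats.confined_fraction,
        "n_events": stats.n_events}, indent=2))
    return {"events": str(ev_path), "stats": str(stats_path)}


def _stage_lifetime(ctx, params, out_dir: Path) -> dict:
    sim = params.pop("simulate", None)
    datasets = []
    if sim is not None:
        sim.setdefault("seed", ctx["seed"])
        cfg = simgen.DwellSimConfig(**sim)
        dwells = simgen.simulate_dwell_tracks(cfg)
        datasets = [kinetics.DwellDataset(tl, d, cfg.integration_time)
                    for tl, d in dwells.items()]
    else:
        for entry in params.pop("manifest", []):
            tracks = tracks_io.read_tracks(
                entry["path"], frame_interval=entry["lapse_interval_s"])
            datasets.append(kinetics.DwellDataset(
                entry["lapse_interval_s"],
                kinetics.dwell_durations(tracks),
                entry.get("integration_time_s", float("nan"))))
    if params:
        raise ValueError(f"unknown lifetime parameters: {sorted(params)}")
    fit = kinetics.bleach_corrected_lifetime(datasets)
    out = out_dir / "lifetime.json"
    out.write_text(json.dumps({
        "k_off_per_s": fit.params.get("k_off"),
        "lifetime_s": fit.params.get("lifetime"),
        "bleach_number": fit.params.get("bleach_number"),
        "stderr": fit.stderr, "success": fit.success,
        "message": fit.message}, indent=2))
    return {"lifetime": str(out)}


def _stage_hill(ctx, params, out_dir: Path) -> dict:
    model = params.pop("model", "qcmd")
    path = params.pop("curve", None)
    if path is None:
        raise ValueError("hill stage needs a 'curve' CSV path")
    if params:
        raise ValueError(f"unknown hill parameters: {sorted(params)}")
    arr = np.genfromtxt(path, delimiter=",", names=True)
    names = arr.dtype.names
    from .core import BindingSeries
    series = BindingSeries(arr[names[0]], arr[names[1]],
                           arr[names[2]] if len(names) > 2 else None)
    fit = binding_geom.fit_hill_qcmd(series) if model == "qcmd" \
        else binding_geom.fit_hill_mst(series)
    out = out_dir / f"hill_{model}.json"
    out.write_text(json.dumps({"params": fit.params, "stderr": fit.stderr,
                               "r_squared": fit.r_squared,
                               "success": fit.success}, indent=2))
    return {"fit": str(out)}


def _stage_packing(ctx, params, out_dir: Path) -> dict:
    footprint = float(params.pop("footprint_nm2"))
    lipid = float(params.pop("lipid_area_nm2", 0.5))
    if params:
        raise ValueError(f"unknown packing parameters: {sorted(params)}")
    lipids, percent = binding_geom.max_packing(footprint, lipid)
    out = out_dir / "packing.json"
    out.write_text(json.dumps({
        "footprint_nm2": footprint, "lipid_area_nm2": lipid,
        "lipids_per_molecule": lipids,
        "saturating_tris_nta_percent": percent}, indent=2))
    return {"packing": str(out)}


_STAGES = {
    "simulate_tracks": _stage_simulate_tracks,
    "confine": _stage_confine,
    "lifetime": _stage_lifetime,
    "hill": _stage_hill,
    "packing": _stage_packing,
}
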