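"""I/O, configuration and the end-to-end pipeline runner.

Trajectories travel as CSV (columns: trial_id, group, region, time_min,
infused_uL, measured_uL); statistical results are emitted as JSON with
the seed, the config hash and the package version embedded, so reruns
of noise-free stages are byte-comparable.

The package also ships small reference tables transcribed from
published NHP/gel comparisons: per-trial Vd/Vi slopes for the cortical
and thalamic conditions, and final bolus volumes for the
medial-temporal-lobe (MTL) condition in trajectory format.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from cedphantom import calib_stats, protocols, synthgen
from cedphantom.calib_stats import Trajectory, TrajectoryPoint
from cedphantom.errors import CedPhantomError, ValidationError

__all__ = [
    "TRAJECTORY_COLUMNS",
    "read_trajectories",
    "write_trajectories",
    "load_reference_slopes",
    "load_mtl_volumes",
    "run_pipeline",
]

logger = logging.getLogger("cedphantom")

TRAJECTORY_COLUMNS = (
    "trial_id",
    "group",
    "region",
    "time_min",
    "infused_uL",
    "measured_uL",
)


def read_trajectories(path) -> list[Trajectory]:
    """Read a trajectory CSV into per-trial Trajectory objects.

    Rows are grouped by trial_id preserving first-appearance order;
    group/region vocabularies and volume signs are validated with the
    offending row named in the error. Empty measured cells load as
    missing points.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    trials: dict[str, dict] = {}
    for i, row in df.iterrows():
        tid = str(row["trial_id"])
        group, region = str(row["group"]), str(row["region"])
        infused, measured = float(row["infused_uL"]), float(row["measured_uL"])
        if group not in calib_stats.GROUPS:
            raise ValidationError(f"{path} row {i}: unknown group {group!r}")
        if region not in calib_stats.REGIONS:
            raise ValidationError(f"{path} row {i}: unknown region {region!r}")
        if infused < 0 or (np.isfinite(measured) and measured < 0):
            raise ValidationError(f"{path} row {i}: negative volume")
        entry = trials.setdefault(tid, {"group": group, "region": region, "points": []})
        entry["points"].append(
            TrajectoryPoint(float(row["time_min"]), infused, measured)
        )
    return [
        Trajectory(tid, e["group"], e["region"], tuple(e["points"]))
        for tid, e in trials.items()
    ]


def write_trajectories(trials: Sequence[Trajectory], path) -> None:
    """Write trajectories as CSV, rows ordered by trial then time.

    Deterministic: same trials produce a byte-identical file.
    """
    rows = []
    for traj in sorted(trials, key=lambda t: t.trial_id):
        for p in sorted(traj.points, key=lambda p: (p.time_min, p.infused_ul)):
            rows.append(
                {
                    "trial_id": traj.trial_id,
                    "group": traj.group,
                    "region": traj.region,
                    "time_min": p.time_min,
                    "infused_uL": p.infused_ul,
                    "measured_uL": p.measured_ul,
                }
            )
    df = pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS))
    df.to_csv(path, index=False)


def _data_path(name: str):
    return resources.files("cedphantom").joinpath("data", name)


def load_reference_slopes(region: str) -> pd.DataFrame:
    """Packaged per-trial Vd/Vi slopes for ``cortical`` or ``thalamic``.

    Columns: group (nhp|agar), trial, slope_ul_per_ul.
    """
    if region not in ("cortical", "thalamic"):
        raise ValidationError(f"no packaged slope table for region {region!r}")
    with resources.as_file(_data_path(f"{region}_slopes.csv")) as p:
        return pd.read_csv(p)


def load_mtl_volumes() -> list[Trajectory]:
    """Packaged MTL final bolus volumes as single-point trajectories.

    Four NHP next-day measurements (15 and 20 µL infusions) and five
    gel trials sampled ~29 min after the end of a 15 µL infusion.
    """
    with resources.as_file(_data_path("mtl_volumes.csv")) as p:
        return read_trajectories(p)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_protocol(cfg: dict) -> dict:
    if "preset" in cfg:
        protocol = protocols.get_preset(cfg["preset"])
    else:
        protocol = protocols.build_protocol(
            [(s["rate_ul_min"], s["duration_min"]) for s in cfg["steps"]],
            name=cfg.get("name", "custom"),
        )
    volume, time = protocols.protocol_totals(protocol)
    out = {"name": protocol.name, "total_volume_ul": volume, "total_time_min": time}
    if "at_time" in cfg:
        out["cumulative_volume_ul"] = protocols.cumulative_volume(
            protocol, float(cfg["at_time"])
        )
    return out


def _stage_simulate(cfg: dict, seed: int, out_dir: Optional[Path]) -> dict:
    agar, nhp = synthgen.make_trajectories(
        n_per_group=(int(cfg.get("n_agar", 10)), int(cfg.get("n_nhp", 10))),
        group_slopes=(float(cfg.get("agar_slope", 3.0)), float(cfg.get("nhp_slope", 4.0))),
        slope_sd=float(cfg.get("slope_sd", 0.3)),
        noise_sd=float(cfg.get("noise_sd", 2.0)),
        n_points=int(cfg.get("n_points", 20)),
        seed=seed,
    )
    if out_dir is not None:
        write_trajectories(agar, out_dir / "agar_trajectories.csv")
        write_trajectories(nhp, out_dir / "nhp_trajectories.csv")
    fit = calib_stats.fit_mixed_model(agar, nhp)
    return {
        "n_agar": len(agar),
        "n_nhp": len(nhp),
        "base_slope": fit.base_slope,
        "interaction": fit.interaction,
        "interaction_se": fit.interaction_se,
        "method": fit.method,
    }


def _stage_mixed_model(cfg: dict) -> dict:
    agar = [t for t in read_trajectories(cfg["agar"]) if t.group == "agar"]
    nhp = [t for t in read_trajectories(cfg["nhp"]) if t.group == "nhp"]
    fit = calib_stats.fit_mixed_model(agar, nhp, reference=cfg.get("reference", "agar"))
    return {
        "base_slope": fit.base_slope,
        "interaction": fit.interaction,
        "interaction_se": fit.interaction_se,
        "trial_slopes": fit.trial_slopes,
        "method": fit.method,
    }


def _stage_mtl_compare(cfg: dict) -> dict:
    if "trajectories" in cfg:
        trials = read_trajectories(cfg["trajectories"])
    else:
        trials = load_mtl_volumes()
    nhp_vols = [p.measured_ul for t in trials if t.group == "nhp" for p in t.usable_points]
    gel_vols = [p.measured_ul for t in trials if t.group == "agar" for p in t.usable_points]
    nhp_by_size: dict[float, list[float]] = {}
    for t in trials:
        if t.group == "nhp":
            for p in t.usable_points:
                nhp_by_size.setdefault(p.infused_ul, []).append(p.measured_ul)
    out = {
        "nhp_mean_ul": float(np.mean(nhp_vols)),
        "gel_mean_ul": float(np.mean(gel_vols)),
        "percent_error": calib_stats.percent_error(
            float(np.mean(nhp_vols)), float(np.mean(gel_vols))
        ),
    }
    sizes = sorted(nhp_by_size)
    if len(sizes) == 2 and all(len(nhp_by_size[s]) >= 2 for s in sizes):
        out["pooling_t_test_p"] = calib_stats.pooled_t_test(
            nhp_by_size[sizes[0]], nhp_by_size[sizes[1]]
        )
    return out


def run_pipeline(config: Union[dict, str, Path], out: Optional[Union[str, Path]] = None) -> dict:
    """Run the configured stages and return (and optionally write) results.

    ``config`` is a dict or a YAML/JSON file path with any of the stage
    keys ``protocol``, ``simulate``, ``mixed_model``, ``mtl_compare``
    plus optional ``seed`` (default 0) and ``out_dir``. Stage errors
    are re-raised with the stage name attached. Results embed the
    seed, a hash of the config and the package version.
    """
    if not isinstance(config, dict):
        path = Path(config)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        import yaml

        config = yaml.safe_load(path.read_text())
    seed = int(config.get("seed", 0))
    out_dir = Path(config["out_dir"]) if "out_dir" in config else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    from cedphantom import __version__

    results: dict = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "version": __version__,
        "stages": {},
    }
    stage_runners = {
        "protocol": lambda cfg: _stage_protocol(cfg),
        "simulate": lambda cfg: _stage_simulate(cfg, seed, out_dir),
        "mixed_model": lambda cfg: _stage_mixed_model(cfg),
        "mtl_compare": lambda cfg: _stage_mtl_compare(cfg),
    }
    for stage, runner in stage_runners.items():
        if stage not in config:
            continue
        logger.info("running stage %s", stage)
        try:
            results["stages"][stage] = runner(config[stage])
        except FileNotFoundError as exc:
            raise CedPhantomError(f"stage {stage!r}: missing input file: {exc}") from exc
        except CedPhantomError as exc:
            raise type(exc)(f"stage {stage!r}: {exc}") from exc
    if out is not None:
        Path(out).write_text(json.dumps(results, indent=2, sort_keys=True))
    return results
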