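"""File formats, run configuration, and the end-to-end pipeline.

Keypoint tracks travel as CSV (one row per frame, a ``# tank_size=w,h``
header comment, and x/y/visibility columns per keypoint); usage tensors,
factor models and HMM parameters travel as HDF5 groups.  ``run_pipeline``
chains the stages on synthetic inputs at two tiers: a frame-level tier
(tracks -> pose features -> syllable HMM -> decoded syllables) and a
day-level tier (lifelong usage cohort -> tensor decomposition -> clocks,
forecasts, divergences, change points, life stages).  Every output is
stamped with the config hash and seed so identical configs reproduce
identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import aging_models, behaviorome_tca, life_stages, pose_features, syllable_hmm
from . import synthetic_data
from .behaviorome_tca import CPModel, UsageTensor
from .pose_features import KEYPOINTS, KeypointTrack, PoseConfig
from .syllable_hmm import GaussianHMMParams, StochasticEMSchedule
from .synthetic_data import BehaviorProgram, CohortSpec, SimConfig

__all__ = [
    "RunConfig",
    "write_track_csv",
    "read_keypoints",
    "save_usage_tensor",
    "load_usage_tensor",
    "save_hmm_params",
    "load_hmm_params",
    "save_cp_model",
    "load_cp_model",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# keypoint CSV
# ---------------------------------------------------------------------------

def write_track_csv(track: KeypointTrack, path: str | Path) -> None:
    """Write a keypoint track with a tank-size header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tank_size={track.tank_size[0]},{track.tank_size[1]}\n")
        track.df.to_csv(fh, index=False)


def read_keypoints(path: str | Path) -> tuple[KeypointTrack, int]:
    """Read a keypoint CSV, dropping frames with duplicate detections.

    A frame number appearing on more than one row means the tracker emitted
    duplicate keypoints for that frame; all its rows are dropped and
    counted.  Returns (track, n_dropped_frames).
    """
    path = Path(path)
    tank = (512.0, 384.0)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "tank_size=" in first:
        w, h = first.split("tank_size=")[1].strip().split(",")
        tank = (float(w), float(h))
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty track file")
    need = {"frame", "timestamp"} | {
        f"{p}_{kp}" for kp in KEYPOINTS for p in ("x", "y", "vis")
    }
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dup = df["frame"].duplicated(keep=False)
    n_dropped = int(df.loc[dup, "frame"].nunique())
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} frame(s) with duplicate keypoints")
        df = df[~dup].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"{path}: no frames left after duplicate filtering")
    return KeypointTrack(df=df, tank_size=tank), n_dropped


# ---------------------------------------------------------------------------
# HDF5 round trips
# ---------------------------------------------------------------------------

def save_usage_tensor(tensor: UsageTensor, path: str | Path, group: str = "usage"):
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("counts", data=tensor.counts)
        g.create_dataset(
            "animal_ids", data=np.asarray(tensor.animal_ids, dtype="S")
        )
        g.create_dataset("ages", data=tensor.ages)
        g.attrs["frames_per_bin"] = tensor.frames_per_bin
        if tensor.normalized is not None:
            g.create_dataset("normalized", data=tensor.normalized)
            g.create_dataset("norm_min", data=tensor.norm_min)
            g.create_dataset("norm_max", data=tensor.norm_max)


def load_usage_tensor(path: str | Path, group: str = "usage") -> UsageTensor:
    with h5py.File(path, "r") as f:
        g = f[group]
        kw = {}
        if "normalized" in g:
            kw = {
                "normalized": g["normalized"][...],
                "norm_min": g["norm_min"][...],
                "norm_max": g["norm_max"][...],
            }
        return UsageTensor(
            counts=g["counts"][...],
            animal_ids=np.array([s.decode() for s in g["animal_ids"][...]],
                                dtype=object),
            ages=g["ages"][...],
            frames_per_bin=int(g.attrs["frames_per_bin"]),
            **kw,
        )


def save_hmm_params(params: GaussianHMMParams, path: str | Path,
                    group: str = "hmm", meta: dict | None = None):
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("pi", data=params.pi)
        g.create_dataset("A", data=params.A)
        g.create_dataset("means", data=params.means)
        g.create_dataset("covars", data=params.covars)
        for k, v in (meta or {}).items():
            g.attrs[k] = v


def load_hmm_params(path: str | Path, group: str = "hmm") -> GaussianHMMParams:
    with h5py.File(path, "r") as f:
        g = f[group]
        return GaussianHMMParams(
            pi=g["pi"][...], A=g["A"][...],
            means=g["means"][...], covars=g["covars"][...],
        )


def save_cp_model(model: CPModel, path: str | Path, group: str = "cp"):
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.attrs["rank"] = model.rank
        g.create_dataset("syllable_factors", data=model.syllable_factors)
        g.create_dataset("time_factors", data=model.time_factors)
        g.create_dataset("age_factors", data=model.age_factors)


def load_cp_model(path: str | Path, group: str = "cp") -> CPModel:
    with h5py.File(path, "r") as f:
        g = f[group]
        return CPModel(
            rank=int(g.attrs["rank"]),
            syllable_factors=g["syllable_factors"][...],
            time_factors=g["time_factors"][...],
            age_factors=g["age_factors"][...],
        )


# ---------------------------------------------------------------------------
# run configuration and the end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All knobs for one pipeline run; serialized alongside every output.

    The frame tier simulates short keypoint tracks and takes them through
    pose features and a syllable HMM; the day tier simulates a lifelong
    usage cohort and takes it through the tensor decomposition, clocks,
    forecasting, divergence/change-point analysis and the life-stage HMM.
    Sizes default to a desk-scale demonstration; the statistical structure
    (20 fps, 12/12 photoperiod, feeding peaks, long/short lifespans,
    forward stages) matches the full-scale design.
    """

    seed: int = 0
    # frame tier
    n_track_animals: int = 2
    track_minutes: float = 4.0
    fps: float = 20.0
    jitter_sd: float = 0.5
    n_syllable_states: int = 4
    hmm_batch_frames: int = 2000
    hmm_epochs: int = 3
    # day tier
    n_animals: int = 12
    n_syllables: int = 20
    n_bins_per_day: int = 48
    n_stages: int = 3
    mean_dwell_days: float = 60.0
    day_stride: int = 3
    cp_rank: int = 4
    forecast_age: float = 100.0
    forecast_window: float = 15.0
    penalty_scale: float = 1.0
    light_hours: float = 12.0
    # stage toggles
    run_frame_tier: bool = True
    run_day_tier: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _demo_program(minutes: float, rng: np.random.Generator) -> BehaviorProgram:
    """A varied behavioral script covering all simulated modes."""
    modes = ["rest", "cruise", "drift", "burst", "reversal", "glass_surf"]
    segments = []
    remaining = minutes * 60.0
    while remaining > 0:
        mode = modes[rng.integers(len(modes))]
        dur = float(min(rng.uniform(5, 30), remaining))
        segments.append((mode, dur, {}))
        remaining -= dur
    return BehaviorProgram(segments=segments)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled tiers in dependency order and write artifacts.

    Returns a dict of in-memory results; files (HDF5/CSV/JSON) land in
    ``outdir`` with the config hash recorded in ``run_config.json``.
    Re-running with an identical config reproduces identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": config.config_hash}
    (outdir / "run_config.json").write_text(json.dumps({
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash,
    }, indent=2))

    if config.run_frame_tier:
        results["frame_tier"] = _run_frame_tier(config, outdir)
    if config.run_day_tier:
        results["day_tier"] = _run_day_tier(config, outdir)
    return results


def _run_frame_tier(config: RunConfig, outdir: Path) -> dict:
    sim = SimConfig(fps=config.fps, jitter_sd=config.jitter_sd,
                    tank_size=(800.0, 600.0), seed=config.seed)
    pose_cfg = PoseConfig()
    rng = np.random.default_rng(config.seed + 1)
    all_pcs = []
    manifest = []
    for i in range(config.n_track_animals):
        prog = _demo_program(config.track_minutes, rng)
        sim_i = dataclasses.replace(sim, seed=config.seed + 100 + i)
        track = synthetic_data.simulate_track(prog, sim_i)
        csv_path = outdir / f"track_{i:02d}.csv"
        write_track_csv(track, csv_path)
        feats = pose_features.assemble_features(track, pose_cfg)
        feats = pose_features.reduce_to_pcs(feats, n_pcs=15)
        all_pcs.append(feats.pc_scores)
        manifest.append({"animal": f"track{i:02d}", "file": csv_path.name,
                         "frames": len(track), "seed": sim_i.seed})
    pd.DataFrame(manifest).to_csv(outdir / "track_manifest.csv", index=False)
    X = np.concatenate(all_pcs, axis=0)
    sched = StochasticEMSchedule(batch_size=config.hmm_batch_frames,
                                 n_epochs=config.hmm_epochs, seed=config.seed)
    params, trace = syllable_hmm.stochastic_em_fit(X, config.n_syllable_states, sched)
    seq = syllable_hmm.decode_syllables(X, params)
    save_hmm_params(params, outdir / "models.h5", group="syllable_hmm",
                    meta={"seed": config.seed, "config_hash": config.config_hash})
    seq.bout_stats.to_csv(outdir / "syllable_bouts.csv", index=False)
    return {
        "n_frames": len(X),
        "hmm_params": params,
        "ll_trace": trace,
        "labels": seq.labels,
        "bout_stats": seq.bout_stats,
    }


def _run_day_tier(config: RunConfig, outdir: Path) -> dict:
    sim = SimConfig(
        fps=config.fps, n_bins_per_day=config.n_bins_per_day,
        n_syllables=config.n_syllables, light_hours=config.light_hours,
        seed=config.seed,
    )
    spec = CohortSpec(n_stages=config.n_stages, day_stride=config.day_stride,
                      mean_dwell_days=config.mean_dwell_days)
    tensor, truth = synthetic_data.simulate_syllable_cohort(
        config.n_animals, spec, sim
    )
    tensor = behaviorome_tca.normalize_usage(tensor)
    save_usage_tensor(tensor, outdir / "usage.h5")
    pd.DataFrame({
        "animal": truth.animal_ids,
        "lifespan_days": truth.lifespans_days,
        "group": truth.group,
    }).to_csv(outdir / "animal_manifest.csv", index=False)

    model = behaviorome_tca.fit_nonneg_cp(tensor, config.cp_rank,
                                          seed=config.seed, n_restarts=2)
    save_cp_model(model, outdir / "models.h5")
    err = behaviorome_tca.normalized_error(tensor, model)
    factors = aging_models.age_factor_table(model, tensor)
    factors.to_csv(outdir / "age_factors.csv", index=False)

    clock = aging_models.fit_behavior_clock(factors, seed=config.seed)
    clock.predictions.to_csv(outdir / "clock_predictions.csv", index=False)
    rates = aging_models.aging_rate(clock)

    lifespans = dict(zip(truth.animal_ids, truth.lifespans_days.astype(float)))
    forecast = None
    survival = None
    try:
        forecast = aging_models.forecast_lifespan(
            factors, lifespans, config.forecast_age,
            window=config.forecast_window, seed=config.seed,
        )
        forecast.predictions.to_csv(outdir / "forecast_predictions.csv", index=False)
        pred_groups = np.where(forecast.predictions["predicted"] == 1,
                               "pred_long", "pred_short")
        if len(np.unique(pred_groups)) == 2:
            ls = forecast.predictions["animal"].map(lifespans).to_numpy()
            survival = aging_models.survival_compare(ls, pred_groups)
    except ValueError as err_:
        warnings.warn(f"forecast skipped: {err_}")

    usage = life_stages.daily_usage_from_tensor(tensor, sim.light_bins)
    cps = {}
    for animal in truth.animal_ids:
        sel = tensor.animal_ids == animal
        if sel.sum() < 3:
            continue
        cps[animal] = life_stages.detect_change_points(
            usage[sel], days=tensor.ages[sel],
            penalty_scale=config.penalty_scale,
        )
    pd.DataFrame([
        {"animal": a, "change_days": ";".join(map(str, c.change_days))}
        for a, c in cps.items()
    ]).to_csv(outdir / "change_points.csv", index=False)

    stage_model = life_stages.fit_stage_model(
        model.age_factors, tensor.animal_ids, tensor.ages,
        K_stages=config.n_stages, seed=config.seed,
    )
    summaries = life_stages.stage_summaries(stage_model, tensor)
    np.savetxt(outdir / "stage_transitions.csv",
               summaries["transition_matrix"], delimiter=",")
    return {
        "tensor": tensor,
        "truth": truth,
        "cp_model": model,
        "reconstruction_error": err,
        "clock": clock,
        "aging_rates": rates,
        "forecast": forecast,
        "survival": survival,
        "change_points": cps,
        "stage_model": stage_model,
        "stage_summaries": summaries,
    }
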