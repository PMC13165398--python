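"""Ground-truth-labeled synthetic inputs for the whole pipeline.

Two tiers of simulation, matching the two time scales of the analysis:

* **Frame level** — short 2-D tank trajectories of a fish body laid out on
  six keypoints, driven by scripted behavioral modes (rest, drift, cruise,
  burst, reversal, glass surfing) with i.i.d. keypoint jitter.  These test
  pose features and syllable HMMs.

* **Day level** — lifelong cohorts of daily syllable-usage tensors: each
  animal draws a lifespan from a long/short mixture, progresses through
  forward-only life stages with geometric dwell times, and emits per-bin
  multinomial syllable counts from its stage's circadian usage template
  (12 h light / 12 h dark, seven feeding-time activity peaks).  These test
  tensor decomposition, behavioral clocks, lifespan forecasting, and
  life-stage detection, with all truth labels returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .behaviorome_tca import UsageTensor
from .pose_features import KEYPOINTS, KeypointTrack
from .syllable_hmm import GaussianHMMParams

__all__ = [
    "SimConfig",
    "BehaviorProgram",
    "CohortSpec",
    "CohortTruth",
    "simulate_track",
    "simulate_hmm_data",
    "simulate_syllable_cohort",
    "stage_templates",
]

MODES = ("rest", "drift", "cruise", "burst", "reversal", "glass_surf")
# body segment lengths (px): snout-midbody, midbody-endbody, endbody-tail, tail-fan
SEGMENT_LENGTHS = (10.0, 10.0, 10.0, 8.0)
_DEFAULT_SPEEDS = {  # px/s
    "rest": 0.0, "drift": 10.0, "cruise": 60.0,
    "burst": 300.0, "reversal": 40.0, "glass_surf": 40.0,
}


@dataclass
class SimConfig:
    """Recording and binning geometry for the simulators.

    Defaults mirror the recording design: 20 fps, 12 h of light per day,
    144 ten-minute bins per day, a 100-syllable alphabet, and sub-pixel
    keypoint jitter small relative to the sleep dispersion threshold.
    """

    fps: float = 20.0
    tank_size: tuple[float, float] = (512.0, 384.0)
    jitter_sd: float = 0.5
    light_hours: float = 12.0
    n_bins_per_day: int = 144
    n_syllables: int = 100
    sidebody_visible_prob: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if 86400 % self.n_bins_per_day and (86400 / self.n_bins_per_day) % 1:
            raise ValueError("n_bins_per_day must evenly divide 24 h")
        if min(self.tank_size) <= 0:
            raise ValueError("tank_size must be positive")

    @property
    def frames_per_bin(self) -> int:
        return int(round(self.fps * 86400 / self.n_bins_per_day))

    @property
    def light_bins(self) -> int:
        return int(round(self.n_bins_per_day * self.light_hours / 24.0))


@dataclass
class BehaviorProgram:
    """Ordered behavioral script: (mode, duration_s, kinematic params).

    Params may override ``speed`` (px/s) and ``heading_noise`` (rad/sqrt s).
    """

    segments: list[tuple[str, float, dict]]

    def __post_init__(self) -> None:
        for mode, dur, _ in self.segments:
            if mode not in MODES:
                raise ValueError(f"unknown behavioral mode {mode!r}; "
                                 f"known modes: {MODES}")
            if dur <= 0:
                raise ValueError(f"segment duration must be positive, got {dur}")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d, _ in self.segments)


def simulate_track(
    program: BehaviorProgram,
    config: SimConfig,
    start_xy: tuple[float, float] | None = None,
    start_heading: float = 0.0,
) -> KeypointTrack:
    """Simulate one keypoint track following a behavioral program.

    The body is laid backward from the snout along the heading with fixed
    segment lengths; the sidebody sits perpendicular to the midbody and is
    only rarely visible (exercising missing-data paths).  Gaussian jitter is
    added i.i.d. per keypoint and frame.  Timestamps increase strictly at
    1/fps.
    """
    if program.total_duration > 86400:
        raise ValueError("program must not exceed 24 h")
    rng = np.random.default_rng(config.seed)
    w, h = config.tank_size
    margin = 2.0
    pos = np.array(start_xy if start_xy is not None else (w / 2, h / 2), dtype=float)
    phi = float(start_heading)
    dt = 1.0 / config.fps

    rows_pos = []
    rows_phi = []
    for mode, dur, params in program.segments:
        n = int(round(dur * config.fps))
        speed = float(params.get("speed", _DEFAULT_SPEEDS[mode]))
        hnoise = float(params.get("heading_noise", 0.2 if mode == "drift" else 0.0))
        for _ in range(n):
            if hnoise:
                phi += rng.normal(0.0, hnoise * np.sqrt(dt))
            u = np.array([np.cos(phi), np.sin(phi)])
            if mode == "reversal":
                step = -speed * dt * u
            elif mode == "glass_surf":
                # snap to the nearest wall, run along it
                dists = [pos[0], w - pos[0], pos[1], h - pos[1]]
                wall = int(np.argmin(dists))
                if wall == 0:
                    pos[0] = margin
                    phi = np.pi / 2
                elif wall == 1:
                    pos[0] = w - margin
                    phi = -np.pi / 2
                elif wall == 2:
                    pos[1] = margin
                    phi = 0.0
                else:
                    pos[1] = h - margin
                    phi = np.pi
                u = np.array([np.cos(phi), np.sin(phi)])
                step = speed * dt * u
            else:
                step = speed * dt * u
            pos = pos + step
            # reflect off walls
            if pos[0] < margin or pos[0] > w - margin:
                pos[0] = np.clip(pos[0], margin, w - margin)
                phi = np.pi - phi
            if pos[1] < margin or pos[1] > h - margin:
                pos[1] = np.clip(pos[1], margin, h - margin)
                phi = -phi
            rows_pos.append(pos.copy())
            rows_phi.append(phi)

    T = len(rows_pos)
    snout = np.asarray(rows_pos)
    phis = np.asarray(rows_phi)
    u = np.column_stack([np.cos(phis), np.sin(phis)])
    perp = np.column_stack([-np.sin(phis), np.cos(phis)])
    cum = np.cumsum(SEGMENT_LENGTHS)
    body = {
        "snout": snout,
        "midbody": snout - cum[0] * u,
        "endbody": snout - cum[1] * u,
        "tail": snout - cum[2] * u,
        "fan": snout - cum[3] * u,
    }
    body["sidebody"] = body["midbody"] + 5.0 * perp

    data = {"frame": np.arange(T), "timestamp": np.arange(T) / config.fps}
    side_vis = rng.random(T) < config.sidebody_visible_prob
    for kp in KEYPOINTS:
        p = body[kp]
        if config.jitter_sd > 0:
            p = p + rng.normal(0.0, config.jitter_sd, size=p.shape)
        data[f"x_{kp}"] = p[:, 0]
        data[f"y_{kp}"] = p[:, 1]
        data[f"vis_{kp}"] = side_vis if kp == "sidebody" else np.ones(T, dtype=bool)
    return KeypointTrack(df=pd.DataFrame(data), tank_size=config.tank_size)


def simulate_hmm_data(
    params: GaussianHMMParams,
    n_frames: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact ancestral sampling from a Gaussian HMM.

    Returns (observations, true_states); the test harness for syllable
    inference and parameter recovery.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    K, D = params.K, params.D
    chol = np.stack([cholesky(params.covars[k], lower=True) for k in range(K)])
    states = np.empty(n_frames, dtype=int)
    obs = np.empty((n_frames, D))
    z = rng.choice(K, p=params.pi)
    for t in range(n_frames):
        if t > 0:
            z = rng.choice(K, p=params.A[z])
        states[t] = z
        obs[t] = params.means[z] + chol[z] @ rng.standard_normal(D)
    return obs, states


# ---------------------------------------------------------------------------
# lifelong cohorts of daily syllable usage
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Distribution parameters for a synthetic lifelong cohort.

    Lifespans come from a two-component Gaussian mixture truncated at
    ``min_lifespan`` (long-lived mean 250 d, short-lived mean 150 d).  Life
    stages progress forward only, with shifted-geometric dwell times.  The
    two lifespan groups differ in day-time inactivity and in the weight of
    peak-activity (feeding) syllables.
    """

    p_long: float = 0.5
    long_mean: float = 250.0
    long_sd: float = 30.0
    short_mean: float = 150.0
    short_sd: float = 25.0
    min_lifespan: float = 30.0
    n_stages: int = 6
    mean_dwell_days: float = 40.0
    min_dwell_days: int = 5
    record_start_day: int = 25
    day_stride: int = 1
    template_separation: float = 3.0
    short_rest_boost: float = 1.6
    short_peak_scale: float = 0.6
    noise_free: bool = False
    templates: dict[str, np.ndarray] | None = None


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort.

    ``stage_sequence[i]`` holds the true stage id for each *recorded* day of
    animal i (non-decreasing); ``change_points[i]`` the recorded-day indices
    at which a new stage begins; ``stage_templates[group]`` the (stages x
    syllables x bins) usage probability templates.
    """

    animal_ids: list[str]
    lifespans_days: np.ndarray
    group: np.ndarray
    recorded_days: list[np.ndarray]
    stage_sequence: list[np.ndarray]
    change_points: list[np.ndarray]
    stage_templates: dict[str, np.ndarray] = field(repr=False)


def _activity_profile(config: SimConfig, peak_scale: float = 1.0) -> np.ndarray:
    """Circadian activity in [0, 1]: light baseline + 7 feeding bumps."""
    T = config.n_bins_per_day
    L = config.light_bins
    act = np.full(T, 0.08)
    act[:L] = 0.35
    centers = np.round(L * (np.arange(1, 8) / 8.0)).astype(int)
    width = max(1.0, T / 48.0)  # ~3 bins at 144 bins/day
    t = np.arange(T)
    for c in centers:
        act = act + 0.6 * peak_scale * np.exp(-0.5 * ((t - c) / width) ** 2) * (t < L)
    return np.clip(act, 0.0, 1.0)


def stage_templates(config: SimConfig, spec: CohortSpec) -> dict[str, np.ndarray]:
    """Per-group (stages x syllables x bins) usage probability templates.

    Syllables split into a rest block and active blocks; each stage has a
    signature block of active syllables it up-weights, and the rest weight
    grows with stage index (aging shifts usage toward inactivity).  The
    short-lived group has more day-time rest and weaker feeding peaks.
    """
    N, T, S = config.n_syllables, config.n_bins_per_day, spec.n_stages
    n_rest = max(2, N // 5)
    n_active = N - n_rest
    if n_active < S:
        raise ValueError("need at least one active syllable per stage")
    blocks = np.array_split(np.arange(n_rest, N), S)
    out: dict[str, np.ndarray] = {}
    for group in ("long", "short"):
        peak = spec.short_peak_scale if group == "short" else 1.0
        act = _activity_profile(config, peak_scale=peak)
        tmpl = np.empty((S, N, T))
        for s in range(S):
            w = np.ones(N)
            rest_w = 0.5 + (1.5 * s / max(S - 1, 1))
            w[:n_rest] = rest_w
            w[blocks[s]] *= spec.template_separation
            gate = np.empty((N, T))
            gate[:n_rest] = (1.0 - 0.8 * act)[None, :]
            gate[n_rest:] = (0.15 + act)[None, :]
            if group == "short":
                light = np.arange(T) < config.light_bins
                gate[:n_rest, light] *= spec.short_rest_boost
            p = w[:, None] * gate
            tmpl[s] = p / p.sum(axis=0, keepdims=True)
        out[group] = tmpl
    return out


def _draw_lifespan(rng: np.random.Generator, spec: CohortSpec) -> tuple[float, str]:
    group = "long" if rng.random() < spec.p_long else "short"
    mean = spec.long_mean if group == "long" else spec.short_mean
    sd = spec.long_sd if group == "long" else spec.short_sd
    while True:
        x = rng.normal(mean, sd)
        if x >= spec.min_lifespan:
            return float(np.round(x)), group


def simulate_syllable_cohort(
    n_animals: int,
    spec: CohortSpec | None = None,
    config: SimConfig | None = None,
) -> tuple[UsageTensor, CohortTruth]:
    """Simulate lifelong daily syllable usage for a cohort with known truth.

    For each animal, a lifespan and long/short group are drawn, days are
    assigned to forward-only stages with shifted-geometric dwell times, and
    each recorded day emits, per time-of-day bin, multinomial syllable
    counts from the group- and stage-specific template, so every bin's
    counts sum to frames-per-bin.  With ``spec.noise_free`` counts equal
    their expected values exactly.
    """
    if n_animals < 2:
        raise ValueError("cohort needs at least 2 animals")
    spec = spec or CohortSpec()
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    templates = spec.templates or stage_templates(config, spec)
    for g, tmpl in templates.items():
        if (np.asarray(tmpl) < 0).any():
            raise ValueError(f"negative entries in {g} stage templates")
        if tmpl.shape[1] != config.n_syllables:
            raise ValueError(
                f"template syllable count {tmpl.shape[1]} != config "
                f"n_syllables {config.n_syllables}"
            )

    fpb = config.frames_per_bin
    N, T = config.n_syllables, config.n_bins_per_day
    ids, lifespans, groups = [], [], []
    rec_days, stage_seqs, cps = [], [], []
    slices = []
    slice_ids, slice_ages = [], []
    for i in range(n_animals):
        animal = f"fish{i:03d}"
        lifespan, group = _draw_lifespan(rng, spec)
        S = templates[group].shape[0]
        # shifted geometric dwell: min_dwell + Geometric, mean = mean_dwell
        shift = spec.min_dwell_days
        p_dwell = 1.0 / max(spec.mean_dwell_days - shift + 1, 1.0)
        bounds = np.cumsum(shift - 1 + rng.geometric(p_dwell, size=S))
        days = np.arange(spec.record_start_day, int(lifespan) + 1, spec.day_stride)
        if len(days) == 0:
            days = np.array([int(lifespan)])
        stages = np.minimum(np.searchsorted(bounds, days, side="left"), S - 1)
        change = days[np.flatnonzero(np.diff(stages)) + 1]
        for day, s in zip(days, stages):
            tmpl = templates[group][s]
            if spec.noise_free:
                counts = tmpl * fpb
            else:
                counts = np.column_stack(
                    [rng.multinomial(fpb, tmpl[:, t]) for t in range(T)]
                )
            slices.append(counts)
            slice_ids.append(animal)
            slice_ages.append(float(day))
        ids.append(animal)
        lifespans.append(lifespan)
        groups.append(group)
        rec_days.append(days)
        stage_seqs.append(stages)
        cps.append(change)

    dtype = float if spec.noise_free else np.int32
    counts = np.stack(slices, axis=2).astype(dtype)
    tensor = UsageTensor(
        counts=counts,
        animal_ids=np.asarray(slice_ids, dtype=object),
        ages=np.asarray(slice_ages),
        frames_per_bin=fpb,
    )
    truth = CohortTruth(
        animal_ids=ids,
        lifespans_days=np.asarray(lifespans),
        group=np.asarray(groups, dtype=object),
        recorded_days=rec_days,
        stage_sequence=stage_seqs,
        change_points=cps,
        stage_templates=templates,
    )
    return tensor, truth
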