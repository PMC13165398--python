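"""Per-frame pose features from 6-keypoint fish tracks.

Six keypoints (snout, midbody, endbody, tail, fan, sidebody) tracked at 20
frames per second are turned into a 57-dimensional per-frame feature vector:
keypoint coordinates, filtered velocities, snout acceleration, snout
dispersion (the inactivity statistic behind sleep scoring), whole-body
bounding area, body length and segment proportions, keypoint visibility
counts, distance to the nearest tank wall, heading, body-bend angles,
signed curvature angles, reversal statistics, and a behavioral sleep flag —
each expanded by rolling-window mean and, for the kinematic/shape subset,
rolling standard deviation.  Features are then z-scored and reduced to 15
principal components for downstream syllable modeling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter, lfilter_zi
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

KEYPOINTS = ("snout", "midbody", "endbody", "tail", "fan", "sidebody")
BODY_CHAIN = ("snout", "midbody", "endbody", "tail", "fan")
# fixed column order for visibility counts
COUNT_ORDER = ("snout", "midbody", "sidebody", "endbody", "tail", "fan")

__all__ = [
    "KEYPOINTS",
    "KeypointTrack",
    "PoseConfig",
    "PoseFeatureMatrix",
    "compute_kinematics",
    "compute_dispersion",
    "compute_geometry",
    "compute_angles",
    "detect_reversal",
    "score_sleep",
    "assemble_features",
    "reduce_to_pcs",
    "linear_separability",
    "minimum_enclosing_circle_area",
]


@dataclass
class KeypointTrack:
    """One animal's keypoint track in tank coordinates.

    ``df`` holds one row per frame with columns ``frame``, ``timestamp`` and,
    per keypoint, ``x_<kp>``, ``y_<kp>``, ``vis_<kp>``.  The origin is the
    bottom-left corner of the tank and the feeding side is aligned across
    animals.  Timestamps are seconds and strictly increasing.
    """

    df: pd.DataFrame
    tank_size: tuple[float, float]

    def __post_init__(self) -> None:
        need = {"frame", "timestamp"}
        for kp in KEYPOINTS:
            need |= {f"x_{kp}", f"y_{kp}", f"vis_{kp}"}
        missing = need - set(self.df.columns)
        if missing:
            raise ValueError(f"track missing columns: {sorted(missing)}")
        ts = self.df["timestamp"].to_numpy()
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def timestamps(self) -> np.ndarray:
        return self.df["timestamp"].to_numpy(dtype=float)

    @property
    def fps(self) -> float:
        ts = self.timestamps
        if len(ts) < 2:
            return float("nan")
        return float(1.0 / np.median(np.diff(ts)))

    def xy(self, kp: str) -> np.ndarray:
        """(T, 2) positions with NaN where the keypoint is invisible."""
        p = self.df[[f"x_{kp}", f"y_{kp}"]].to_numpy(dtype=float).copy()
        vis = self.df[f"vis_{kp}"].to_numpy(dtype=bool)
        p[~vis] = np.nan
        return p

    def visible(self, kp: str) -> np.ndarray:
        return self.df[f"vis_{kp}"].to_numpy(dtype=bool)


@dataclass
class PoseConfig:
    """Windows, thresholds and filter coefficients for pose features.

    The dispersion window is 2 s (40 frames at 20 fps); an animal whose
    dispersion area stays below ``sleep_dispersion_threshold`` (same units
    as the area, px^2) for at least ``sleep_min_duration_s`` is scored
    asleep.  ``filter_b``/``filter_a`` define the causal linear filter
    applied to positions before differencing (default: 5-tap moving
    average).
    """

    rolling_window: int = 10
    dispersion_window: int = 40
    sleep_dispersion_threshold: float = 50.0
    sleep_min_duration_s: float = 60.0
    filter_b: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    filter_a: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.rolling_window < 1 or self.dispersion_window < 1:
            raise ValueError("windows must be >= 1")
        if self.sleep_dispersion_threshold <= 0:
            raise ValueError("sleep threshold must be positive")


@dataclass
class Kinematics:
    """Filtered kinematic series; one entry (possibly NaN) per frame."""

    speeds: pd.DataFrame            # <kp>_velocity, px/s, 5 body keypoints
    snout_acceleration: np.ndarray  # px/s^2
    heading_vec: np.ndarray         # (T, 2) unit midbody->snout
    heading_angle: np.ndarray       # radians
    snout_velocity_vec: np.ndarray  # (T, 2) px/s


@dataclass
class PoseFeatureMatrix:
    """57 named per-frame features plus their principal-component scores."""

    features: pd.DataFrame = field(repr=False)
    pc_scores: np.ndarray | None = None
    loadings: np.ndarray | None = None
    explained_variance_ratio: np.ndarray | None = None
    dropped_columns: list[str] = field(default_factory=list)


# features that get a rolling std column in addition to the rolling mean
_STD_FEATURES = (
    "snout_velocity", "midbody_velocity", "endbody_velocity",
    "tail_velocity", "fan_velocity", "snout_acceleration",
    "disp", "bounding_area", "body_length_norm", "tail_fan_prop",
    "alpha1", "alpha2", "alpha3", "alpha_all",
    "theta1", "theta2", "theta3", "dot_product",
)


def _filter_positions(p: np.ndarray, config: PoseConfig) -> np.ndarray:
    """Causal linear filter on each coordinate; NaN gaps bridged by ffill.

    The filter state is initialized at the first sample so the startup
    transient does not masquerade as a large velocity at recording start.
    """
    out = np.empty_like(p)
    order = max(len(config.filter_b), len(config.filter_a)) - 1
    zi = lfilter_zi(config.filter_b, config.filter_a) if order else None
    for j in range(p.shape[1]):
        col = pd.Series(p[:, j]).ffill().bfill().to_numpy()
        if np.isnan(col).all():
            out[:, j] = np.nan
            continue
        if zi is None:
            out[:, j] = lfilter(config.filter_b, config.filter_a, col)
        else:
            out[:, j], _ = lfilter(config.filter_b, config.filter_a, col,
                                   zi=zi * col[0])
    out[np.isnan(p)] = np.nan
    return out


def compute_kinematics(track: KeypointTrack, config: PoseConfig) -> Kinematics:
    """Filtered velocities (5 body keypoints), snout acceleration, heading.

    Positions are low-pass filtered before differencing to suppress keypoint
    jitter.  Velocities are in px/s using timestamps (robust to dropped
    frames).  Heading is the unit vector from midbody to snout; frames where
    a required keypoint is invisible yield NaN.
    """
    T = len(track)
    ts = track.timestamps
    if T < 2:
        warnings.warn("kinematics undefined for single-frame input; all missing")
        nan2 = np.full((T, 2), np.nan)
        return Kinematics(
            speeds=pd.DataFrame(
                np.nan, index=range(T), columns=[f"{kp}_velocity" for kp in BODY_CHAIN]
            ),
            snout_acceleration=np.full(T, np.nan),
            heading_vec=nan2,
            heading_angle=np.full(T, np.nan),
            snout_velocity_vec=nan2,
        )
    dt = np.diff(ts)
    speeds = {}
    snout_vel = None
    for kp in BODY_CHAIN:
        pf = _filter_positions(track.xy(kp), config)
        vel = np.full((T, 2), np.nan)
        vel[1:] = (pf[1:] - pf[:-1]) / dt[:, None]
        speeds[f"{kp}_velocity"] = np.linalg.norm(vel, axis=1)
        if kp == "snout":
            snout_vel = vel
    acc_vec = np.full((T, 2), np.nan)
    acc_vec[1:] = (snout_vel[1:] - snout_vel[:-1]) / dt[:, None]
    snout_acc = np.linalg.norm(acc_vec, axis=1)
    h = track.xy("snout") - track.xy("midbody")
    norm = np.linalg.norm(h, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        hv = h / norm[:, None]
    hv[norm == 0] = np.nan
    angle = np.arctan2(hv[:, 1], hv[:, 0])
    return Kinematics(
        speeds=pd.DataFrame(speeds),
        snout_acceleration=snout_acc,
        heading_vec=hv,
        heading_angle=angle,
        snout_velocity_vec=snout_vel,
    )


def _bbox_circle_area(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    # circle on the bounding-box diagonal: radius^2 = (dx^2 + dy^2) / 4
    return np.pi * (dx**2 + dy**2) / 4.0


def compute_dispersion(snout_xy: np.ndarray, config: PoseConfig) -> np.ndarray:
    """Trailing-window snout dispersion area (px^2).

    The area of the circle whose diameter is the diagonal of the
    axis-aligned bounding box of snout positions over the trailing
    ``dispersion_window`` frames (windows truncated at recording start).
    This is the inactivity statistic used for sleep scoring.
    """
    x = pd.Series(snout_xy[:, 0])
    y = pd.Series(snout_xy[:, 1])
    w = config.dispersion_window
    dx = x.rolling(w, min_periods=1).max() - x.rolling(w, min_periods=1).min()
    dy = y.rolling(w, min_periods=1).max() - y.rolling(w, min_periods=1).min()
    return _bbox_circle_area(dx.to_numpy(), dy.to_numpy())


def minimum_enclosing_circle_area(points: np.ndarray) -> float:
    """Exact smallest-enclosing-circle area (Welzl); test oracle only."""
    pts = [tuple(p) for p in np.asarray(points, float) if not np.isnan(p).any()]
    if not pts:
        return float("nan")

    def circle_two(a, b):
        cx, cy = (a[0] + b[0]) / 2, (a[1] + b[1]) / 2
        r = math.dist(a, b) / 2
        return cx, cy, r

    def circle_three(a, b, c):
        ax, ay = a
        bx, by = b
        cx, cy = c
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            return None
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
              + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
              + (cx**2 + cy**2) * (bx - ax)) / d
        return ux, uy, math.dist((ux, uy), a)

    def inside(circ, p, eps=1e-9):
        return math.dist(circ[:2], p) <= circ[2] + eps

    best = (pts[0][0], pts[0][1], 0.0)
    for i, p in enumerate(pts):
        if inside(best, p):
            continue
        best = (p[0], p[1], 0.0)
        for j in range(i):
            q = pts[j]
            if inside(best, q):
                continue
            best = circle_two(p, q)
            for k in range(j):
                r = pts[k]
                if inside(best, r):
                    continue
                c3 = circle_three(p, q, r)
                if c3 is not None:
                    best = c3
    return math.pi * best[2] ** 2


def compute_geometry(
    track: KeypointTrack,
    config: PoseConfig,
    day_index: np.ndarray | None = None,
) -> pd.DataFrame:
    """Whole-body bounding area, body length, proportions, counts, wall distance.

    The bounding area uses the same bounding-box-diagonal circle rule as
    dispersion, over all visible keypoints in the trailing window, and is
    centered and normalized by the mean of the recording day.  Body length
    sums the four segments along the body chain and is normalized the same
    way.
    """
    T = len(track)
    xs = np.column_stack([track.xy(kp)[:, 0] for kp in KEYPOINTS])
    ys = np.column_stack([track.xy(kp)[:, 1] for kp in KEYPOINTS])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fx_max = pd.Series(np.nanmax(xs, axis=1))
        fx_min = pd.Series(np.nanmin(xs, axis=1))
        fy_max = pd.Series(np.nanmax(ys, axis=1))
        fy_min = pd.Series(np.nanmin(ys, axis=1))
    w = config.dispersion_window
    dx = fx_max.rolling(w, min_periods=1).max() - fx_min.rolling(w, min_periods=1).min()
    dy = fy_max.rolling(w, min_periods=1).max() - fy_min.rolling(w, min_periods=1).min()
    bounding_raw = _bbox_circle_area(dx.to_numpy(), dy.to_numpy())

    length = np.zeros(T)
    for a, b in zip(BODY_CHAIN[:-1], BODY_CHAIN[1:]):
        length = length + np.linalg.norm(track.xy(a) - track.xy(b), axis=1)
    tail_fan = np.linalg.norm(track.xy("tail") - track.xy("fan"), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tail_fan_prop = tail_fan / length

    if day_index is None:
        day_index = np.floor(track.timestamps / 86400.0).astype(int)
    bounding = np.full(T, np.nan)
    body_norm = np.full(T, np.nan)
    for day in np.unique(day_index):
        sel = day_index == day
        for raw, out, name in ((bounding_raw, bounding, "bounding area"),
                               (length, body_norm, "body length")):
            m = np.nanmean(raw[sel])
            if not np.isfinite(m) or m == 0:
                warnings.warn(f"day {day}: zero/undefined mean {name}; "
                              "normalization skipped")
                out[sel] = raw[sel]
            else:
                out[sel] = (raw[sel] - m) / m

    snout = track.xy("snout")
    tw, th = track.tank_size
    dist = np.nanmin(
        np.column_stack([snout[:, 0], tw - snout[:, 0], snout[:, 1], th - snout[:, 1]]),
        axis=1,
    ) if T else np.empty(0)

    out = pd.DataFrame({
        "bounding_area": bounding,
        "body_length": length,
        "body_length_norm": body_norm,
        "tail_fan_prop": tail_fan_prop,
        "dist_snout": dist,
    })
    for kp in COUNT_ORDER:
        out[f"count_{kp}"] = track.visible(kp).astype(float)
    return out


def _interior_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
    cosang = np.where((nu == 0) | (nv == 0), np.nan, cosang)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _signed_angle(ref: np.ndarray, vec: np.ndarray) -> np.ndarray:
    # positive when vec points to the animal's left of ref (counterclockwise)
    cross = ref[:, 0] * vec[:, 1] - ref[:, 1] * vec[:, 0]
    dot = np.einsum("ij,ij->i", ref, vec)
    return np.arctan2(cross, dot)


def compute_angles(track: KeypointTrack) -> pd.DataFrame:
    """Body-bend angles (alpha) and signed curvature angles (theta).

    alpha_k is the interior angle at the middle keypoint of each consecutive
    body triple, in [0, pi] (pi = straight).  theta_k is the local tangent
    direction at midbody/endbody/tail relative to heading, positive toward
    the animal's left.
    """
    kp = {name: track.xy(name) for name in BODY_CHAIN}
    alpha1 = _interior_angle(kp["snout"], kp["midbody"], kp["endbody"])
    alpha2 = _interior_angle(kp["midbody"], kp["endbody"], kp["tail"])
    alpha3 = _interior_angle(kp["endbody"], kp["tail"], kp["fan"])
    heading = kp["snout"] - kp["midbody"]
    # local tangent: central difference along the body chain, head-pointing.
    # theta is the angle of the heading relative to the local tangent, so a
    # body on a left-turning arc (heading rotated counterclockwise of the
    # rear tangents) gives positive values.
    theta1 = _signed_angle(kp["snout"] - kp["endbody"], heading)
    theta2 = _signed_angle(kp["midbody"] - kp["tail"], heading)
    theta3 = _signed_angle(kp["endbody"] - kp["fan"], heading)
    return pd.DataFrame({
        "alpha1": alpha1, "alpha2": alpha2, "alpha3": alpha3,
        "alpha_all": alpha1 + alpha2 + alpha3,
        "theta1": theta1, "theta2": theta2, "theta3": theta3,
    })


def detect_reversal(track: KeypointTrack, config: PoseConfig) -> pd.DataFrame:
    """Reversal statistics: heading-velocity dot product and backward flag.

    Keypoint coordinates are pre-smoothed with a rolling average over
    ``rolling_window`` frames; the dot product of the unit heading with the
    snout velocity is negative when the animal moves backward.  Zero-velocity
    frames give a dot product of 0 and are not reversals.
    """
    T = len(track)
    ts = track.timestamps
    w = config.rolling_window

    def smooth(p: np.ndarray) -> np.ndarray:
        return pd.DataFrame(p).rolling(w, min_periods=1).mean().to_numpy()

    snout = smooth(track.xy("snout"))
    mid = smooth(track.xy("midbody"))
    h = snout - mid
    norm = np.linalg.norm(h, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        hv = h / norm[:, None]
    hv[norm == 0] = 0.0
    vel = np.zeros((T, 2))
    if T > 1:
        vel[1:] = (snout[1:] - snout[:-1]) / np.diff(ts)[:, None]
    dot = np.einsum("ij,ij->i", hv, vel)
    dot = np.where(np.isnan(dot), 0.0, dot)
    reversal = np.maximum(-dot, 0.0)
    return pd.DataFrame({
        "dot_product": dot,
        "reversal": reversal,
        "reversal_binary": (dot < 0).astype(float),
    })


def score_sleep(dispersion: np.ndarray, config: PoseConfig, fps: float) -> np.ndarray:
    """Per-frame sleep flag from the dispersion series.

    Frames with dispersion below the threshold are inactive; maximal runs of
    consecutive inactive frames lasting at least ``sleep_min_duration_s``
    are labeled sleep in full.  Missing dispersion breaks a run.
    """
    disp = np.asarray(dispersion, dtype=float)
    inactive = np.where(np.isnan(disp), False, disp < config.sleep_dispersion_threshold)
    min_frames = int(math.ceil(config.sleep_min_duration_s * fps))
    sleep = np.zeros(len(disp), dtype=bool)
    start = None
    for i, flag in enumerate(np.append(inactive, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_frames:
                sleep[start:i] = True
            start = None
    return sleep


def assemble_features(track: KeypointTrack, config: PoseConfig) -> PoseFeatureMatrix:
    """Assemble the 57-dimensional per-frame pose feature matrix.

    39 base features are computed per frame, then each is expanded by a
    rolling mean over ``rolling_window`` frames and the 18 kinematic/shape
    features additionally by a rolling standard deviation, for 57 columns.
    Rolling statistics require at least half the window present, else NaN.
    """
    kin = compute_kinematics(track, config)
    snout = track.xy("snout")
    disp = compute_dispersion(snout, config)
    geom = compute_geometry(track, config)
    ang = compute_angles(track)
    rev = detect_reversal(track, config)
    sleep = score_sleep(disp, config, track.fps if len(track) > 1 else 20.0)

    base = pd.DataFrame(index=track.df.index)
    for kp in BODY_CHAIN:
        p = track.xy(kp)
        base[f"x_{kp}"] = p[:, 0]
        base[f"y_{kp}"] = p[:, 1]
    for col in kin.speeds.columns:
        base[col] = kin.speeds[col].to_numpy()
    base["snout_acceleration"] = kin.snout_acceleration
    base["disp"] = disp
    base["bounding_area"] = geom["bounding_area"].to_numpy()
    base["body_length_norm"] = geom["body_length_norm"].to_numpy()
    base["tail_fan_prop"] = geom["tail_fan_prop"].to_numpy()
    for kp in COUNT_ORDER:
        base[f"count_{kp}"] = geom[f"count_{kp}"].to_numpy()
    base["dist_snout"] = geom["dist_snout"].to_numpy()
    base["heading_direction"] = kin.heading_angle
    for col in ang.columns:
        base[col] = ang[col].to_numpy()
    for col in rev.columns:
        base[col] = rev[col].to_numpy()
    base["sleep"] = sleep.astype(float)

    w = config.rolling_window
    minp = max(1, w // 2)
    out = {}
    for col in base.columns:
        out[f"{col}_mean"] = base[col].rolling(w, min_periods=minp).mean()
    for col in _STD_FEATURES:
        out[f"{col}_std"] = base[col].rolling(w, min_periods=minp).std()
    features = pd.DataFrame(out, index=base.index)
    if features.shape[1] != 57:
        raise RuntimeError(
            f"feature allocation yields {features.shape[1]} columns, expected 57"
        )
    return PoseFeatureMatrix(features=features)


def reduce_to_pcs(
    matrix: PoseFeatureMatrix,
    n_pcs: int = 15,
    smooth_window: int = 10,
) -> PoseFeatureMatrix:
    """Z-score features, project onto the top principal components, smooth.

    Constant columns (z-score undefined) are dropped with a warning and
    recorded on the result.  NaNs are imputed at the column mean (0 after
    z-scoring).  Scores are smoothed with a moving-average filter.
    """
    F = matrix.features
    std = F.std(ddof=0)
    constant = std[(std == 0) | std.isna()].index.tolist()
    if constant:
        warnings.warn(f"dropping {len(constant)} constant column(s): {constant[:5]}...")
    use = F.drop(columns=constant)
    if use.shape[1] < n_pcs:
        n_pcs = use.shape[1]
    Z = (use - use.mean()) / use.std(ddof=0)
    Z = Z.fillna(0.0).to_numpy()
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(Z)
    if smooth_window > 1:
        scores = (
            pd.DataFrame(scores).rolling(smooth_window, min_periods=1).mean().to_numpy()
        )
    return PoseFeatureMatrix(
        features=F,
        pc_scores=scores,
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped_columns=constant,
    )


def linear_separability(
    pc_scores: np.ndarray,
    labels: np.ndarray,
    n_pcs: int = 5,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated linear-SVM accuracy on the top pose-feature PCs.

    Measures how linearly separable two conditions (e.g. day vs night, young
    vs old) are in pose space.  Returns mean stratified k-fold accuracy.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("linear separability needs both labels present")
    X = np.asarray(pc_scores)[:, :n_pcs]
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    acc = cross_val_score(SVC(kernel="linear"), X, labels, cv=cv, scoring="accuracy")
    return float(acc.mean())
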