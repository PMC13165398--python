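"""Divergence analysis, change-point detection, and the life-stage HMM.

Three views of how behavior reorganizes across life:

* day-to-day **divergence**: each day is summarized by the time spent in
  each syllable during the light and dark photoperiods (a 200-element
  vector for 100 syllables); symmetrized Kullback-Leibler divergence
  between days exposes block structure — long stretches of similar days
  separated by abrupt shifts;
* **change points**: penalized kernel (RBF) segmentation of the smoothed,
  z-scored daily usage series, with the penalty scaling with the natural
  log of the number of recorded days so longer lives are not fragmented;
* a **life-stage HMM**: a Gaussian HMM over smoothed, z-scored daily age
  factors whose hidden states are discrete life stages, summarized by
  their empirical transitions, dwell durations, usage profiles, and
  emission divergences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.ndimage import gaussian_filter1d
from scipy.stats import entropy

from .behaviorome_tca import UsageTensor
from .syllable_hmm import GaussianHMMParams, fit_em, forward_backward

__all__ = [
    "DailyUsage",
    "ChangePointSet",
    "StageModel",
    "daily_usage",
    "daily_usage_from_tensor",
    "symmetrized_dkl",
    "symmetrized_dkl_gaussian",
    "day_matrix",
    "detect_change_points",
    "fit_stage_model",
    "stage_summaries",
]


@dataclass
class DailyUsage:
    """One animal-day's syllable usage split by photoperiod.

    ``counts`` has 2N entries for N syllables: time (frames) in each
    syllable during the light period, then during the dark period.
    ``distribution`` is the same vector normalized to sum to 1.
    """

    counts: np.ndarray
    distribution: np.ndarray


@dataclass
class ChangePointSet:
    """Detected behavioral change points for one animal."""

    change_points: np.ndarray   # indices into the day series, strictly increasing
    change_days: np.ndarray     # same points in age-in-days units
    penalty: float
    segment_means: list[np.ndarray] = field(default_factory=list, repr=False)


@dataclass
class StageModel:
    """Life-stage HMM over daily age factors, with per-animal labels.

    Stages are relabeled so stage ids increase with the mean age of their
    member days ("forward" is well defined for reporting).
    """

    params: GaussianHMMParams
    animal_ids: list[str]
    days: list[np.ndarray]
    labels: list[np.ndarray]

    @property
    def K_stages(self) -> int:
        return self.params.K


# ---------------------------------------------------------------------------
# daily usage vectors
# ---------------------------------------------------------------------------

def daily_usage(
    labels: np.ndarray,
    n_syllables: int,
    fps: float = 20.0,
    light_hours: float = 12.0,
) -> DailyUsage:
    """Photoperiod-split syllable usage for one day of frame labels.

    Frames in the first ``light_hours`` of the day are the light period.
    Negative labels (missing frames) are ignored.
    """
    labels = np.asarray(labels)
    max_frames = int(round(fps * 86400))
    if len(labels) > max_frames:
        raise ValueError(f"{len(labels)} frames exceed one day ({max_frames})")
    if labels[labels >= 0].size and labels.max() >= n_syllables:
        raise ValueError("syllable id out of range")
    light_frames = int(round(fps * light_hours * 3600))
    out = np.zeros(2 * n_syllables)
    for offset, seg in ((0, labels[:light_frames]), (n_syllables, labels[light_frames:])):
        seg = seg[seg >= 0]
        out[offset:offset + n_syllables] = np.bincount(seg, minlength=n_syllables)
    total = out.sum()
    dist = out / total if total > 0 else out
    return DailyUsage(counts=out, distribution=dist)


def daily_usage_from_tensor(tensor: UsageTensor, light_bins: int) -> np.ndarray:
    """(K, 2N) light/dark usage counts for every animal-day slice."""
    c = tensor.counts
    light = c[:, :light_bins, :].sum(axis=1)  # (N, K)
    dark = c[:, light_bins:, :].sum(axis=1)
    return np.vstack([light, dark]).T.astype(float)


# ---------------------------------------------------------------------------
# divergences
# ---------------------------------------------------------------------------

def symmetrized_dkl(p: np.ndarray, q: np.ndarray, eps: float = 1.0) -> float:
    """Symmetrized KL divergence (nats) between two usage vectors.

    A pseudocount ``eps`` is added to every cell before normalization so
    syllables unused on one day do not produce infinite divergence; with
    ``eps=0`` the raw vectors are normalized as-is.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("usage vectors must be non-negative")
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("all-zero usage vector")
    ps = (p + eps) / (p + eps).sum()
    qs = (q + eps) / (q + eps).sum()
    return float(0.5 * entropy(ps, qs) + 0.5 * entropy(qs, ps))


def _chol_pd(S: np.ndarray):
    S = np.asarray(S, dtype=float)
    try:
        return cho_factor(S, lower=True)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance is not positive definite") from err


def symmetrized_dkl_gaussian(
    mu1: np.ndarray, S1: np.ndarray, mu2: np.ndarray, S2: np.ndarray
) -> float:
    """Closed-form symmetrized KL divergence between two Gaussians (nats).

    KL(N1||N2) = 1/2 [tr(S2^-1 S1) + (m2-m1)^T S2^-1 (m2-m1) - d
                      + ln det S2 - ln det S1].
    """
    mu1 = np.atleast_1d(np.asarray(mu1, float))
    mu2 = np.atleast_1d(np.asarray(mu2, float))
    S1 = np.atleast_2d(np.asarray(S1, float))
    S2 = np.atleast_2d(np.asarray(S2, float))
    d = len(mu1)

    def kl(ma, Sa, mb, Sb):
        cb = _chol_pd(Sb)
        ca = _chol_pd(Sa)
        tr = np.trace(cho_solve(cb, Sa))
        diff = mb - ma
        maha = diff @ cho_solve(cb, diff)
        logdet_b = 2.0 * np.sum(np.log(np.diag(cb[0])))
        logdet_a = 2.0 * np.sum(np.log(np.diag(ca[0])))
        return 0.5 * (tr + maha - d + logdet_b - logdet_a)

    return float(0.5 * kl(mu1, S1, mu2, S2) + 0.5 * kl(mu2, S2, mu1, S1))


def day_matrix(usage: np.ndarray, eps: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Day x day symmetrized divergence matrix for one animal.

    ``usage`` is (days, 2N) light/dark usage counts.  Returns the symmetric
    zero-diagonal matrix and the adjacent-day trace used to display
    behavioral shifts.
    """
    usage = np.asarray(usage, dtype=float)
    n = len(usage)
    if n < 2:
        raise ValueError("need at least 2 days")
    sm = (usage + eps) / (usage + eps).sum(axis=1, keepdims=True)
    log_sm = np.log(sm)
    # 0.5*sum(p log p/q) + 0.5*sum(q log q/p), vectorized over all pairs
    H = np.sum(sm * log_sm, axis=1)  # negative entropy per day
    cross = sm @ log_sm.T            # cross[i, j] = sum_i p_i log q_j
    M = 0.5 * (H[:, None] - cross) + 0.5 * (H[None, :] - cross.T)
    M = 0.5 * (M + M.T)
    np.fill_diagonal(M, 0.0)
    return M, np.diag(M, k=1).copy()


# ---------------------------------------------------------------------------
# kernel change-point detection
# ---------------------------------------------------------------------------

def _rbf_gram(Z: np.ndarray, gamma: float | None) -> np.ndarray:
    sq = np.sum(Z**2, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * Z @ Z.T
    np.maximum(D2, 0.0, out=D2)
    if gamma is None:  # median heuristic
        off = D2[np.triu_indices_from(D2, k=1)]
        med = np.median(off[off > 0]) if (off > 0).any() else 1.0
        gamma = 1.0 / med
    return np.exp(-gamma * D2)


def detect_change_points(
    usage: np.ndarray,
    days: np.ndarray | None = None,
    penalty_scale: float = 1.0,
    smooth_sigma: float = 1.0,
    gamma: float | None = None,
    min_size: int = 2,
    eps: float = 1e-12,
) -> ChangePointSet:
    """Penalized kernel change-point detection on daily usage.

    The daily usage series is Gaussian-smoothed along age (sigma in days),
    z-scored per dimension, and segmented by minimizing the within-segment
    RBF-kernel scatter plus ``penalty_scale * ln(L)`` per change point,
    where L is the number of recorded days — so the effective penalty
    scales identically with log lifespan across animals.  The number of
    change points is unknown a priori and is non-increasing in the penalty.

    The default ``penalty_scale`` of 1 is calibrated on synthetic cohorts
    with known transitions: because the RBF kernel is bounded by 1, the
    scatter reduction a true change can deliver is bounded by the shorter
    flanking segment length, so the per-change penalty must stay well below
    that for short end-of-life segments to remain detectable.
    """
    usage = np.atleast_2d(np.asarray(usage, dtype=float))
    n = len(usage)
    days = np.arange(n) if days is None else np.asarray(days)
    penalty = penalty_scale * np.log(max(n, 2))
    if n < 3:
        return ChangePointSet(np.array([], int), np.array([]), penalty)
    Z = gaussian_filter1d(usage, sigma=smooth_sigma, axis=0) if smooth_sigma > 0 else usage
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Z - mu) / sd
    G = _rbf_gram(Z, gamma)
    # prefix sums for O(1) segment costs
    P = np.zeros((n + 1, n + 1))
    P[1:, 1:] = G.cumsum(axis=0).cumsum(axis=1)
    dsum = np.concatenate(([0.0], np.cumsum(np.diag(G))))

    def cost(a: int, b: int) -> float:
        block = P[b, b] - P[a, b] - P[b, a] + P[a, a]
        return (dsum[b] - dsum[a]) - block / (b - a)

    F = np.full(n + 1, np.inf)
    F[0] = -penalty  # first segment pays no change-point penalty
    prev = np.zeros(n + 1, dtype=int)
    for b in range(min_size, n + 1):
        for a in range(0, b - min_size + 1):
            if a != 0 and (a < min_size or not np.isfinite(F[a])):
                continue
            val = F[a] + cost(a, b) + penalty
            if val < F[b] - eps:
                F[b] = val
                prev[b] = a
    bps = []
    b = n
    while b > 0:
        a = prev[b]
        if a > 0:
            bps.append(a)
        b = a
    bps = np.array(sorted(bps), dtype=int)
    seg_bounds = np.concatenate(([0], bps, [n]))
    seg_means = [usage[s:e].mean(axis=0) for s, e in zip(seg_bounds[:-1], seg_bounds[1:])]
    return ChangePointSet(
        change_points=bps,
        change_days=days[bps] if len(bps) else np.array([]),
        penalty=penalty,
        segment_means=seg_means,
    )


# ---------------------------------------------------------------------------
# life-stage HMM
# ---------------------------------------------------------------------------

def _prepare_factor_sequences(
    factors: np.ndarray,
    animal_ids: np.ndarray,
    ages: np.ndarray,
    smooth_sigma: float,
):
    """Group rows by animal, order by age, smooth along age, z-score globally."""
    factors = np.asarray(factors, dtype=float)
    animal_ids = np.asarray(animal_ids)
    ages = np.asarray(ages, dtype=float)
    seqs, day_lists, ids = [], [], []
    for animal in pd.unique(animal_ids):
        sel = animal_ids == animal
        if sel.sum() < 2:
            continue
        order = np.argsort(ages[sel])
        X = factors[sel][order]
        if smooth_sigma > 0:
            X = gaussian_filter1d(X, sigma=smooth_sigma, axis=0)
        seqs.append(X)
        day_lists.append(ages[sel][order])
        ids.append(str(animal))
    if not seqs:
        raise ValueError("no animal has >= 2 recorded days")
    allX = np.concatenate(seqs, axis=0)
    mu = allX.mean(axis=0)
    sd = allX.std(axis=0)
    sd[sd == 0] = 1.0
    seqs = [(X - mu) / sd for X in seqs]
    return seqs, day_lists, ids


def fit_stage_model(
    factors: np.ndarray,
    animal_ids: np.ndarray,
    ages: np.ndarray,
    K_stages: int = 6,
    n_iter: int = 20,
    seed: int = 0,
    smooth_sigma: float = 1.0,
) -> StageModel:
    """Fit the life-stage Gaussian HMM to daily age factors.

    Age factors are smoothed along age (Gaussian, sigma = 1 day), z-scored,
    and modeled as one observation sequence per animal with a full-covariance
    Gaussian HMM (k-means initialization, 20 EM iterations).  Daily stage
    labels are the posterior mode; stages are then reordered by the mean age
    of their member days so ids progress forward.
    """
    seqs, day_lists, ids = _prepare_factor_sequences(
        factors, animal_ids, ages, smooth_sigma
    )
    params, _ = fit_em(seqs, K_stages, n_iter=n_iter, seed=seed)
    labels = [forward_backward(X, params)[0].argmax(axis=1) for X in seqs]
    # forward ordering: relabel stages by mean member-day age
    all_labels = np.concatenate(labels)
    all_days = np.concatenate(day_lists)
    mean_age = np.full(K_stages, np.inf)
    for k in range(K_stages):
        sel = all_labels == k
        if sel.any():
            mean_age[k] = all_days[sel].mean()
    order = np.argsort(mean_age)          # order[new] = old
    params = params.permuted(order)
    relabel = np.argsort(order)           # relabel[old] = new
    labels = [relabel[lab] for lab in labels]
    return StageModel(params=params, animal_ids=ids, days=day_lists, labels=labels)


def stage_summaries(
    model: StageModel,
    tensor: UsageTensor | None = None,
) -> dict:
    """Empirical transitions, stage durations, usage profiles, divergences.

    Returns a dict with ``transition_matrix`` (row-normalized day-to-day
    transition frequencies, self-transitions included; unvisited stages give
    NaN rows), ``jump_matrix`` (the same conditioned on a stage change,
    since day-to-day persistence dominates), ``durations`` (per-stage list
    of bout lengths in recorded
    days), ``median_duration``, ``emission_dkl`` (K x K symmetrized
    divergence of stage emissions), and — when a usage tensor aligned with
    the model's animal-days is given — ``usage_profiles``: per-stage median
    of the binned syllable usage across member days.
    """
    K = model.K_stages
    trans = np.zeros((K, K))
    durations: dict[int, list[int]] = {k: [] for k in range(K)}
    for lab in model.labels:
        for a, b in zip(lab[:-1], lab[1:]):
            trans[a, b] += 1
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(lab)]))
        for s, e in zip(starts, ends):
            durations[int(lab[s])].append(int(e - s))
    rows = trans.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tmat = np.where(rows > 0, trans / rows, np.nan)
        # jump matrix: transitions conditioned on a stage change
        jumps = trans - np.diag(np.diag(trans))
        jrows = jumps.sum(axis=1, keepdims=True)
        jmat = np.where(jrows > 0, jumps / np.where(jrows == 0, 1, jrows), np.nan)
    dkl = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            dkl[i, j] = dkl[j, i] = symmetrized_dkl_gaussian(
                model.params.means[i], model.params.covars[i],
                model.params.means[j], model.params.covars[j],
            )
    out = {
        "transition_matrix": tmat,
        "jump_matrix": jmat,
        "transition_counts": trans,
        "durations": durations,
        "median_duration": {
            k: (float(np.median(v)) if v else float("nan"))
            for k, v in durations.items()
        },
        "emission_dkl": dkl,
    }
    if tensor is not None:
        # map model labels back onto tensor slices via (animal, age) keys
        key_to_label: dict[tuple[str, float], int] = {}
        for animal, dl, lab in zip(model.animal_ids, model.days, model.labels):
            for d, s in zip(dl, lab):
                key_to_label[(animal, float(d))] = int(s)
        N, T, _ = tensor.shape
        profiles = np.full((K, N, T), np.nan)
        for k in range(K):
            idx = [
                i for i, (a, d) in enumerate(zip(tensor.animal_ids, tensor.ages))
                if key_to_label.get((str(a), float(d))) == k
            ]
            if idx:
                profiles[k] = np.median(tensor.counts[:, :, idx], axis=2)
        out["usage_profiles"] = profiles
    return out
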