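"""Behaviorome tensor component analysis.

Daily behavior is summarized as a third-order count tensor: syllable x
time-of-day bin x animal-day.  Non-negative canonical polyadic (CP)
decomposition factors it into R components, each the outer product of a
time-of-day profile, a syllable composition, and a per-animal-day amplitude
(the "age factor").  Rank is chosen by cross-validation against time bins
held out of the fit.

The solver is masked non-negative HALS (hierarchical alternating least
squares): held-out entries are imputed with the current reconstruction
between sweeps, which minimizes the squared error over observed entries
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UsageTensor",
    "CPModel",
    "bin_usage",
    "normalize_usage",
    "fit_nonneg_cp",
    "normalized_error",
    "cross_validate_rank",
    "factor_congruence",
]


@dataclass
class UsageTensor:
    """Syllable x time-of-day-bin x animal-day usage counts.

    ``counts[n, t, k]`` is the number of frames animal-day ``k`` spent in
    syllable ``n`` during time-of-day bin ``t``.  Every bin's counts over
    syllables sum to the frames recorded in that bin (12,000 for 10-min bins
    at 20 fps), minus any missing frames.
    """

    counts: np.ndarray
    animal_ids: np.ndarray
    ages: np.ndarray
    frames_per_bin: int
    missing_frames: np.ndarray | None = None  # (T, K) frames absent per bin
    normalized: np.ndarray | None = field(default=None, repr=False)
    norm_min: np.ndarray | None = None
    norm_max: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a 3rd-order tensor (N, T, K)")
        if len(self.animal_ids) != self.counts.shape[2]:
            raise ValueError("one animal id per animal-day slice required")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape


@dataclass
class CPModel:
    """Rank-R non-negative CP factorization of a usage tensor.

    Time and syllable factor columns have unit Euclidean norm; component
    magnitude is absorbed into the age factors so per-animal-day amplitudes
    are comparable.  Components are ordered by reconstruction contribution.
    """

    rank: int
    syllable_factors: np.ndarray  # (N, R)
    time_factors: np.ndarray      # (T, R)
    age_factors: np.ndarray       # (K, R)
    converged: bool = True
    n_iter: int = 0

    def reconstruct(self) -> np.ndarray:
        return np.einsum(
            "nr,tr,kr->ntk", self.syllable_factors, self.time_factors, self.age_factors
        )

    def normalize_components(self) -> "CPModel":
        """Push scale into age factors, order components by contribution."""
        A, B, C = self.syllable_factors, self.time_factors, self.age_factors
        na = np.linalg.norm(A, axis=0)
        nb = np.linalg.norm(B, axis=0)
        na = np.where(na == 0, 1.0, na)
        nb = np.where(nb == 0, 1.0, nb)
        A = A / na
        B = B / nb
        C = C * na * nb
        weight = np.linalg.norm(C, axis=0)
        order = np.argsort(weight)[::-1]
        return CPModel(self.rank, A[:, order], B[:, order], C[:, order],
                       self.converged, self.n_iter)


# ---------------------------------------------------------------------------
# tensor construction
# ---------------------------------------------------------------------------

def bin_usage(
    sequences: list[tuple[str, float, np.ndarray]],
    n_syllables: int,
    fps: float = 20.0,
    n_bins_per_day: int = 144,
) -> UsageTensor:
    """Bin per-frame syllable labels into a usage tensor.

    Parameters
    ----------
    sequences : list of (animal_id, age_days, labels) where ``labels`` holds
        one syllable id per frame of that animal-day, in recording order.
        Negative ids mark missing frames and are counted per bin but not
        assigned to any syllable.
    """
    frames_per_day = int(round(fps * 86400))
    frames_per_bin = frames_per_day // n_bins_per_day
    seen: set[tuple[str, float]] = set()
    K = len(sequences)
    counts = np.zeros((n_syllables, n_bins_per_day, K), dtype=np.int64)
    missing = np.zeros((n_bins_per_day, K), dtype=np.int64)
    ids, ages = [], []
    for k, (animal, age, labels) in enumerate(sequences):
        key = (animal, age)
        if key in seen:
            raise ValueError(f"duplicate animal-day slice {key}")
        seen.add(key)
        labels = np.asarray(labels)
        if labels[labels >= 0].size and labels.max() >= n_syllables:
            raise ValueError(f"syllable id {labels.max()} >= n_syllables {n_syllables}")
        bins = np.minimum(np.arange(len(labels)) // frames_per_bin, n_bins_per_day - 1)
        ok = labels >= 0
        np.add.at(counts[:, :, k], (labels[ok], bins[ok]), 1)
        np.add.at(missing[:, k], bins[~ok], 1)
        # frames never recorded in a bin count as missing too
        recorded = np.bincount(bins, minlength=n_bins_per_day)
        missing[:, k] += np.maximum(frames_per_bin - recorded, 0)
        ids.append(animal)
        ages.append(age)
    return UsageTensor(
        counts=counts,
        animal_ids=np.asarray(ids, dtype=object),
        ages=np.asarray(ages, dtype=float),
        frames_per_bin=frames_per_bin,
        missing_frames=missing,
    )


def normalize_usage(tensor: UsageTensor, zero_min: bool = False) -> UsageTensor:
    """Min-max scale each syllable's usage to [0, 1] over the whole dataset.

    Scaling is per syllable across all bins and animal-days, so heavily used
    syllables do not dominate the decomposition.  Constant syllables map to 0
    and are flagged with a warning.  ``zero_min`` forces the minimum to 0
    instead of the empirical minimum.
    """
    x = tensor.counts.astype(float)
    mins = x.min(axis=(1, 2))
    if zero_min:
        mins = np.zeros_like(mins)
    maxs = x.max(axis=(1, 2))
    span = maxs - mins
    flat = span == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} syllable(s) constant; mapped to 0")
    safe = np.where(flat, 1.0, span)
    normalized = (x - mins[:, None, None]) / safe[:, None, None]
    normalized[flat] = 0.0
    return UsageTensor(
        counts=tensor.counts,
        animal_ids=tensor.animal_ids,
        ages=tensor.ages,
        frames_per_bin=tensor.frames_per_bin,
        missing_frames=tensor.missing_frames,
        normalized=normalized,
        norm_min=mins,
        norm_max=maxs,
    )


# ---------------------------------------------------------------------------
# non-negative CP via masked HALS
# ---------------------------------------------------------------------------

def _unfold(X: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)


def _khatri_rao(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    # column-wise Kronecker product, (I*J, R)
    I, R = U.shape
    J = V.shape[0]
    return (U[:, None, :] * V[None, :, :]).reshape(I * J, R)


def _hals_sweep(X: np.ndarray, factors: list[np.ndarray]) -> None:
    """One in-place HALS sweep over the three factor matrices."""
    for mode in range(3):
        others = [factors[m] for m in range(3) if m != mode]
        # note: unfolding of mode m pairs with KR of remaining modes in order
        kr = _khatri_rao(others[0], others[1])
        W = _unfold(X, mode) @ kr
        H = (others[0].T @ others[0]) * (others[1].T @ others[1])
        U = factors[mode]
        for r in range(U.shape[1]):
            h = H[r, r]
            if h <= 1e-12:
                continue
            u = U[:, r] + (W[:, r] - U @ H[:, r]) / h
            U[:, r] = np.maximum(u, 0.0)


def fit_nonneg_cp(
    tensor: np.ndarray | UsageTensor,
    rank: int,
    seed: int = 0,
    mask: np.ndarray | None = None,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-7,
    init_factors: list[np.ndarray] | None = None,
) -> CPModel:
    """Fit a non-negative CP model by masked HALS with random restarts.

    ``mask`` (same shape as the tensor, True = observed) restricts the fit
    objective to observed entries: unobserved entries are imputed with the
    current reconstruction before every sweep, so they exert no pull on the
    factors at the optimum.  The best of ``n_restarts`` random starts is
    returned (a single start if ``init_factors`` is given).
    """
    X = tensor.normalized if isinstance(tensor, UsageTensor) else np.asarray(tensor, float)
    if X is None:
        raise ValueError("tensor not normalized; call normalize_usage first")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != X.shape:
            raise ValueError("mask shape must match tensor shape")
        if not mask.any():
            raise ValueError("mask excludes every entry")
    rng = np.random.default_rng(seed)
    shapes = X.shape
    scale = float(X[mask].mean() if mask is not None else X.mean()) or 1.0
    best: tuple[float, list[np.ndarray], bool, int] | None = None
    starts = 1 if init_factors is not None else n_restarts
    for _ in range(starts):
        if init_factors is not None:
            factors = [f.astype(float).copy() for f in init_factors]
        else:
            factors = [
                rng.uniform(0.1, 1.0, size=(s, rank)) * scale ** (1 / 3) for s in shapes
            ]
        prev = np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            if mask is not None:
                recon = np.einsum("nr,tr,kr->ntk", *factors)
                Xw = np.where(mask, X, recon)
            else:
                Xw = X
            _hals_sweep(Xw, factors)
            recon = np.einsum("nr,tr,kr->ntk", *factors)
            err = normalized_error(X, recon, mask=mask)
            if prev - err < tol * max(prev, 1e-12):
                converged = True
                break
            prev = err
        final = normalized_error(X, np.einsum("nr,tr,kr->ntk", *factors), mask=mask)
        if best is None or final < best[0]:
            best = (final, factors, converged, it)
    err, factors, converged, it = best
    if not converged:
        warnings.warn(f"CP fit did not converge in {max_iter} iterations")
    model = CPModel(rank, factors[0], factors[1], factors[2], converged, it)
    return model.normalize_components()


def normalized_error(
    data: np.ndarray | UsageTensor,
    model: CPModel | np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Fraction-of-unexplained-variance analogue in [0, 1].

    Squared Frobenius norm of the (masked) residual over the squared
    Frobenius norm of the (masked) data: 0 for a perfect reconstruction,
    1 for the all-zero model.
    """
    X = data.normalized if isinstance(data, UsageTensor) else np.asarray(data, float)
    R = model.reconstruct() if isinstance(model, CPModel) else np.asarray(model, float)
    if X.shape != R.shape:
        raise ValueError("shape mismatch between data and reconstruction")
    if mask is not None:
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("mask excludes every entry")
        X = X[mask]
        R = R[mask]
    denom = float(np.sum(X * X))
    if denom == 0:
        return 0.0 if np.allclose(R, 0) else 1.0
    return float(np.sum((X - R) ** 2) / denom)


def cross_validate_rank(
    tensor: np.ndarray | UsageTensor,
    rank_grid: list[int],
    holdout_fraction: float = 0.5,
    seed: int = 0,
    elbow_tol: float = 0.1,
    **fit_kwargs,
) -> tuple[pd.DataFrame, int, np.ndarray]:
    """Select CP rank by holding out time bins.

    A fraction of (time-bin, animal-day) pairs is masked out across all
    syllables; models over ``rank_grid`` are fit on the remaining entries and
    scored on both sets.  The selected rank is the one after which returns
    become marginal: the smallest R whose successor improves test error by
    less than a fraction ``elbow_tol`` of the error at R.

    Returns the error table, the selected rank, and the holdout mask.
    """
    X = tensor.normalized if isinstance(tensor, UsageTensor) else np.asarray(tensor, float)
    if not rank_grid:
        raise ValueError("rank grid is empty")
    rank_grid = sorted(rank_grid)
    N, T, K = X.shape
    rng = np.random.default_rng(seed)
    held = rng.random((T, K)) < holdout_fraction
    if held.all() or not held.any():  # degenerate draw on tiny tensors
        held.flat[0] = not held.flat[0]
    train_mask = np.broadcast_to(~held, (N, T, K))
    rows = []
    prev_test = None
    prev_model: CPModel | None = None
    selected = rank_grid[-1]
    chosen = False
    for R in rank_grid:
        model = fit_nonneg_cp(X, R, seed=seed + R, mask=train_mask, **fit_kwargs)
        if prev_model is not None:
            # warm start from the previous rank, padded with a fresh column,
            # so training error is non-increasing along the grid
            pad = R - prev_model.rank
            if pad > 0:
                wrng = np.random.default_rng(seed + 1000 + R)
                init = [
                    np.hstack([F, wrng.uniform(0.01, 0.1, size=(F.shape[0], pad))])
                    for F in (prev_model.syllable_factors, prev_model.time_factors,
                              prev_model.age_factors)
                ]
                warm = fit_nonneg_cp(X, R, seed=seed + R, mask=train_mask,
                                     init_factors=init, **fit_kwargs)
                if normalized_error(X, warm, mask=train_mask) < normalized_error(
                    X, model, mask=train_mask
                ):
                    model = warm
        prev_model = model
        recon = model.reconstruct()
        tr = normalized_error(X, recon, mask=train_mask)
        te = normalized_error(X, recon, mask=~train_mask)
        rows.append({"rank": R, "train_error": tr, "test_error": te})
        if (not chosen and prev_test is not None
                and prev_test - te < elbow_tol * max(prev_test, 1e-12)):
            selected = rows[-2]["rank"]
            chosen = True
        prev_test = te
    table = pd.DataFrame(rows)
    if not chosen:
        selected = int(table.loc[table["test_error"].idxmin(), "rank"])
    return table, int(selected), ~train_mask


def factor_congruence(est: np.ndarray, true: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute cosine similarity of matched factor columns.

    Columns are matched greedily by similarity; used to score recovery of
    known factors up to permutation and scale.
    """
    def unit(M):
        n = np.linalg.norm(M, axis=0)
        return M / np.where(n == 0, 1.0, n)

    C = unit(est).T @ unit(true)  # (Rest, Rtrue)
    C = np.abs(C)
    perm = np.full(true.shape[1], -1)
    used: set[int] = set()
    for j in np.argsort(-C.max(axis=0)):
        order = np.argsort(-C[:, j])
        for i in order:
            if i not in used:
                perm[j] = i
                used.add(i)
                break
    score = float(np.mean([C[perm[j], j] for j in range(true.shape[1])]))
    return score, perm
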