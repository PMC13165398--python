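"""Gaussian hidden Markov models for behavioral syllables.

A K-state Gaussian HMM is fit to smoothed pose-feature principal components.
Each hidden state is interpreted as a *behavioral syllable*: a short,
stereotyped, reused motif of movement.  Fitting uses either full-batch
Baum-Welch EM (small data, life-stage models) or a memory-bounded stochastic
EM in which each update blends the expected sufficient statistics of one
contiguous batch of frames into a running estimate with a Robbins-Monro step
size, so peak memory scales with the batch, not the recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import squareform
from scipy.special import logsumexp
from sklearn.cluster import KMeans

__all__ = [
    "GaussianHMMParams",
    "StochasticEMSchedule",
    "SyllableSequence",
    "forward_backward",
    "viterbi",
    "kmeans_init",
    "fit_em",
    "stochastic_em_fit",
    "decode_syllables",
    "select_num_states",
    "cluster_syllables",
]

_RIDGE = 1e-6


@dataclass
class GaussianHMMParams:
    """Parameters of a K-state Gaussian HMM with full covariances.

    Attributes
    ----------
    pi : (K,) initial state probabilities.
    A : (K, K) transition matrix, rows sum to 1.
    means : (K, D) emission means.
    covars : (K, D, D) emission covariances, symmetric positive definite.
    """

    pi: np.ndarray
    A: np.ndarray
    means: np.ndarray
    covars: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covars = np.asarray(self.covars, dtype=float)
        if self.covars.ndim == 2:  # single state
            self.covars = self.covars[None]
        self.validate()

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def D(self) -> int:
        return self.means.shape[1]

    def validate(self, atol: float = 1e-8) -> None:
        if not np.allclose(self.pi.sum(), 1.0, atol=atol):
            raise ValueError(f"initial probabilities sum to {self.pi.sum()}, not 1")
        rows = self.A.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=atol):
            bad = int(np.argmax(np.abs(rows - 1.0)))
            raise ValueError(f"transition row {bad} sums to {rows[bad]}, not 1")
        if self.A.shape != (self.K, self.K):
            raise ValueError("transition matrix shape mismatch")
        for k, S in enumerate(self.covars):
            if not np.allclose(S, S.T, atol=1e-10):
                raise ValueError(f"covariance {k} not symmetric")
            if np.linalg.eigvalsh(S)[0] <= 0:
                raise ValueError(f"covariance {k} not positive definite")

    def permuted(self, perm: np.ndarray) -> "GaussianHMMParams":
        """Return an equivalent model with states relabeled by ``perm``."""
        perm = np.asarray(perm)
        return GaussianHMMParams(
            pi=self.pi[perm],
            A=self.A[np.ix_(perm, perm)],
            means=self.means[perm],
            covars=self.covars[perm],
        )


@dataclass
class StochasticEMSchedule:
    """Batching and Robbins-Monro step sizes for stochastic EM.

    The step size at update t (1-based) is ``rho_t = (t + offset)**(-decay)``
    with ``rho_1`` forced to 1 so the first update adopts the first batch's
    sufficient statistics outright.  ``0.5 < decay <= 1`` satisfies the
    Robbins-Monro conditions (step sizes sum to infinity, squares converge).
    """

    batch_size: int = 100_000
    n_epochs: int = 5
    decay: float = 0.6
    offset: float = 2.0
    shuffle: bool = True
    seed: int = 0
    constant_rho: float | None = None  # rho=1 with one batch == Baum-Welch

    def __post_init__(self) -> None:
        if not 0.5 < self.decay <= 1.0:
            raise ValueError("decay must lie in (0.5, 1] for Robbins-Monro")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.constant_rho is not None and not 0.0 < self.constant_rho <= 1.0:
            raise ValueError("constant_rho must lie in (0, 1]")

    def rho(self, t: int) -> float:
        if self.constant_rho is not None:
            return self.constant_rho
        if t == 1:
            return 1.0
        return float((t + self.offset) ** (-self.decay))


@dataclass
class SyllableSequence:
    """Per-frame syllable labels plus bout-duration summaries."""

    labels: np.ndarray
    posterior_max: np.ndarray
    bout_stats: pd.DataFrame = field(repr=False)


# ---------------------------------------------------------------------------
# emission densities and message passing
# ---------------------------------------------------------------------------

def _log_emission(X: np.ndarray, params: GaussianHMMParams) -> np.ndarray:
    """(T, K) log N(x_t; mu_k, Sigma_k), Cholesky-based, ridge on failure."""
    T, D = X.shape
    out = np.empty((T, params.K))
    for k in range(params.K):
        S = params.covars[k]
        try:
            c, low = cho_factor(S, lower=True)
        except np.linalg.LinAlgError:
            warnings.warn(f"singular covariance in state {k}; adding ridge")
            c, low = cho_factor(S + _RIDGE * np.trace(S) / D * np.eye(D), lower=True)
        diff = X - params.means[k]
        sol = cho_solve((c, low), diff.T)
        maha = np.einsum("ij,ji->i", diff, sol)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        out[:, k] = -0.5 * (maha + logdet + D * np.log(2.0 * np.pi))
    return out


def forward_backward(
    X: np.ndarray,
    params: GaussianHMMParams,
    implementation: str = "scaled",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior state marginals, expected transition counts, log likelihood.

    Parameters
    ----------
    X : (T, D) observation sequence.
    implementation : "scaled" uses per-frame normalization constants;
        "log" runs the recursions entirely in log space.  Both are exact and
        agree to ~1e-8; the scaled path is the fast default.

    Returns
    -------
    gamma : (T, K) per-frame posteriors, each row sums to 1.
    xi_sum : (K, K) expected transition counts summed over time.
    loglik : float.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("observations must be finite")
    logB = _log_emission(X, params)
    if implementation == "scaled":
        return _fb_scaled(logB, params)
    if implementation == "log":
        return _fb_log(logB, params)
    raise ValueError(f"unknown implementation {implementation!r}")


def _fb_scaled(logB: np.ndarray, params: GaussianHMMParams):
    T, K = logB.shape
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    A = params.A
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = params.pi * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = (A @ bb) / c[t + 1]
        xi_sum += np.outer(alpha[t], bb) * A / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + shift.sum())
    return gamma, xi_sum, loglik


def _fb_log(logB: np.ndarray, params: GaussianHMMParams):
    T, K = logB.shape
    with np.errstate(divide="ignore"):
        logA = np.log(params.A)
        logpi = np.log(params.pi)
    la = np.empty((T, K))
    la[0] = logpi + logB[0]
    for t in range(1, T):
        la[t] = logsumexp(la[t - 1][:, None] + logA, axis=0) + logB[t]
    lb = np.empty((T, K))
    lb[-1] = 0.0
    for t in range(T - 2, -1, -1):
        lb[t] = logsumexp(logA + (logB[t + 1] + lb[t + 1])[None, :], axis=1)
    loglik = float(logsumexp(la[-1]))
    gamma = np.exp(la + lb - loglik)
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        lxi = la[t][:, None] + logA + (logB[t + 1] + lb[t + 1])[None, :] - loglik
        xi_sum += np.exp(lxi)
    return gamma, xi_sum, loglik


def viterbi(X: np.ndarray, params: GaussianHMMParams) -> np.ndarray:
    """Most-probable state path (log-space max-product)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    logB = _log_emission(X, params)
    T, K = logB.shape
    with np.errstate(divide="ignore"):
        logA = np.log(params.A)
        logpi = np.log(params.pi)
    delta = logpi + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _batch_stats(X: np.ndarray, params: GaussianHMMParams):
    gamma, xi_sum, ll = forward_backward(X, params)
    return {
        "pi": gamma[0].copy(),
        "trans": xi_sum,
        "N": gamma.sum(axis=0),
        "S1": gamma.T @ X,
        "S2": np.einsum("tk,ti,tj->kij", gamma, X, X),
    }, ll


def _m_step(stats: dict, global_cov: np.ndarray) -> GaussianHMMParams:
    K = len(stats["N"])
    D = stats["S1"].shape[1]
    pi = stats["pi"] / stats["pi"].sum()
    trans = stats["trans"]
    rowsum = trans.sum(axis=1, keepdims=True)
    A = np.where(rowsum > 0, trans / np.where(rowsum == 0, 1.0, rowsum), 1.0 / K)
    means = np.empty((K, D))
    covars = np.empty((K, D, D))
    for k in range(K):
        n = stats["N"][k]
        if n < 1.0:  # state starvation: keep mean, reset spread
            warnings.warn(f"state {k} starved (expected count {n:.3g}); covariance reset")
            means[k] = stats["S1"][k] / max(n, 1e-12)
            covars[k] = global_cov + _RIDGE * np.eye(D)
            continue
        mu = stats["S1"][k] / n
        means[k] = mu
        S = stats["S2"][k] / n - np.outer(mu, mu)
        S = 0.5 * (S + S.T) + _RIDGE * np.eye(D)
        covars[k] = S
    return GaussianHMMParams(pi=pi, A=A, means=means, covars=covars)


def kmeans_init(
    X: np.ndarray,
    K: int,
    seed: int = 0,
    n_subsample: int = 100_000,
    self_bias: float = 0.9,
) -> GaussianHMMParams:
    """K-means means on a subsample, shared diagonal covariance, sticky A."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rng = np.random.default_rng(seed)
    if len(X) > n_subsample:
        idx = rng.choice(len(X), n_subsample, replace=False)
        sub = X[idx]
    else:
        sub = X
    if K == 1:
        means = sub.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=K, n_init=10, random_state=int(seed) % (2**31))
        km.fit(sub)
        means = km.cluster_centers_
    var = np.maximum(sub.var(axis=0), _RIDGE)
    covars = np.broadcast_to(np.diag(var), (K, X.shape[1], X.shape[1])).copy()
    pi = np.full(K, 1.0 / K)
    A = np.full((K, K), (1.0 - self_bias) / max(K - 1, 1))
    np.fill_diagonal(A, self_bias if K > 1 else 1.0)
    return GaussianHMMParams(pi=pi, A=A, means=means, covars=covars)


def fit_em(
    sequences: list[np.ndarray] | np.ndarray,
    K: int,
    n_iter: int = 20,
    seed: int = 0,
    init: GaussianHMMParams | None = None,
    tol: float | None = None,
) -> tuple[GaussianHMMParams, list[float]]:
    """Full-batch Baum-Welch EM over one or more observation sequences.

    Returns the fitted parameters and the per-iteration log-likelihood trace
    (evaluated under the parameters *before* each M-step, so the trace is
    non-decreasing by the EM guarantee).
    """
    if isinstance(sequences, np.ndarray) and sequences.ndim == 2:
        sequences = [sequences]
    sequences = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
    Xall = np.concatenate(sequences, axis=0)
    params = init if init is not None else kmeans_init(Xall, K, seed=seed)
    global_cov = np.cov(Xall.T) if Xall.shape[0] > 1 else np.eye(Xall.shape[1])
    global_cov = np.atleast_2d(global_cov)
    trace: list[float] = []
    for _ in range(n_iter):
        tot: dict | None = None
        ll = 0.0
        for seq in sequences:
            stats, l = _batch_stats(seq, params)
            ll += l
            if tot is None:
                tot = stats
            else:
                for key in tot:
                    tot[key] = tot[key] + stats[key]
        trace.append(ll)
        params = _m_step(tot, global_cov)
        if tol is not None and len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
    return params, trace


def stochastic_em_fit(
    X: np.ndarray,
    K: int,
    schedule: StochasticEMSchedule,
    init: GaussianHMMParams | None = None,
) -> tuple[GaussianHMMParams, list[float]]:
    """Memory-bounded stochastic EM on one long contiguous recording.

    The recording is cut into contiguous batches of ``schedule.batch_size``
    frames.  Each update runs forward-backward on one batch only, then blends
    the batch's expected sufficient statistics into a running estimate:
    ``stats <- (1 - rho_t) * stats + rho_t * batch_stats``.  Blending in
    sufficient-statistic space (not parameter space) keeps transition rows
    stochastic and covariances positive semi-definite by construction.  With a
    single batch covering all data and a constant step size of 1, every
    update reduces to a plain Baum-Welch iteration, so the two coincide
    exactly.

    Returns fitted parameters and the per-update batch log-likelihood trace
    (per frame, so batches of different sizes are comparable).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = len(X)
    B = min(schedule.batch_size, T)
    starts = list(range(0, T, B))
    batches = [slice(s, min(s + B, T)) for s in starts]
    rng = np.random.default_rng(schedule.seed)
    params = init if init is not None else kmeans_init(X, K, seed=schedule.seed)
    global_cov = np.atleast_2d(np.cov(X.T)) if T > 1 else np.eye(X.shape[1])
    run: dict | None = None
    trace: list[float] = []
    t = 0
    for _ in range(schedule.n_epochs):
        order = rng.permutation(len(batches)) if schedule.shuffle else np.arange(len(batches))
        for bi in order:
            t += 1
            rho = schedule.rho(t)
            sl = batches[bi]
            stats, ll = _batch_stats(X[sl], params)
            trace.append(ll / (sl.stop - sl.start))
            if run is None:
                run = stats
            else:
                for key in run:
                    run[key] = (1.0 - rho) * run[key] + rho * stats[key]
            params = _m_step(run, global_cov)
    return params, trace


# ---------------------------------------------------------------------------
# decoding, model selection, clustering
# ---------------------------------------------------------------------------

def bout_durations(labels: np.ndarray) -> pd.DataFrame:
    """Run-length summaries (frames): mean, 5th and 95th percentile per label."""
    labels = np.asarray(labels)
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    runs = pd.DataFrame({"syllable": labels[starts], "duration": ends - starts})
    g = runs.groupby("syllable")["duration"]
    out = g.agg(
        mean_frames="mean",
        p5_frames=lambda s: np.percentile(s, 5),
        p95_frames=lambda s: np.percentile(s, 95),
        n_bouts="count",
    )
    return out.reset_index()


def decode_syllables(
    X: np.ndarray,
    params: GaussianHMMParams,
    method: str = "posterior",
) -> SyllableSequence:
    """Label every frame with a syllable id.

    ``method="posterior"`` takes the per-frame posterior mode (the default:
    cheap and streaming-friendly); ``method="viterbi"`` returns the jointly
    most probable path.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.D:
        raise ValueError(
            f"observation dimension {X.shape[1]} != model dimension {params.D}"
        )
    if method == "viterbi":
        labels = viterbi(X, params)
        gamma, _, _ = forward_backward(X, params)
    elif method == "posterior":
        gamma, _, _ = forward_backward(X, params)
        labels = gamma.argmax(axis=1)
    else:
        raise ValueError(f"unknown decoding method {method!r}")
    pmax = gamma[np.arange(len(labels)), labels]
    return SyllableSequence(labels=labels, posterior_max=pmax,
                            bout_stats=bout_durations(labels))


def select_num_states(
    train_sequences: list[np.ndarray],
    val_sequences: list[np.ndarray],
    K_grid: list[int],
    n_iter: int = 30,
    seed: int = 0,
    plateau_tol: float = 0.02,
    train_animals: list | None = None,
    val_animals: list | None = None,
) -> tuple[pd.DataFrame, int]:
    """Held-out log likelihood per frame over a grid of state counts.

    The selected K is the smallest one whose held-out per-frame log
    likelihood is within ``plateau_tol`` nats of the grid maximum — the
    point where adding states stops paying for itself.
    """
    if train_animals is not None and val_animals is not None:
        overlap = set(train_animals) & set(val_animals)
        if overlap:
            raise ValueError(f"animals present in both train and validation: {overlap}")
    if not K_grid:
        raise ValueError("K grid is empty")
    val_frames = sum(len(s) for s in val_sequences)
    rows = []
    for K in K_grid:
        params, _ = fit_em(train_sequences, K, n_iter=n_iter, seed=seed)
        ll = sum(forward_backward(np.atleast_2d(s), params)[2] for s in val_sequences)
        rows.append({"K": K, "heldout_ll_per_frame": ll / val_frames})
    table = pd.DataFrame(rows)
    best = table["heldout_ll_per_frame"].max()
    ok = table[table["heldout_ll_per_frame"] >= best - plateau_tol]
    selected = int(ok["K"].min())
    return table, selected


def cluster_syllables(params: GaussianHMMParams, method: str = "average"):
    """Group syllables by the divergence of their emission distributions.

    Distances are symmetrized KL divergences between the Gaussian emissions
    (closed form); clustering is agglomerative with average linkage.

    Returns
    -------
    dict with ``distance`` (K x K symmetric matrix), ``linkage`` (scipy
    linkage matrix) and ``order`` (leaf order for display).
    """
    from .life_stages import symmetrized_dkl_gaussian

    K = params.K
    D = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            d = symmetrized_dkl_gaussian(
                params.means[i], params.covars[i], params.means[j], params.covars[j]
            )
            D[i, j] = D[j, i] = d
    Z = linkage(squareform(D, checks=False), method=method)
    return {"distance": D, "linkage": Z, "order": leaves_list(Z)}
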