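"""Diagonal-Gaussian hidden Markov models for one-class sequence scoring.

The concentration detector is a *one-class* model: an HMM theta is fitted
by Baum-Welch (expectation-maximisation) on positive windows only, and a
test window X is scored by its total sequence likelihood p(X | theta),
computed with the scaled forward algorithm.  Higher scores mean "more like
the training class".

Emissions are per-state independent Gaussians per channel (diagonal
covariance): with as few as five 60-frame training windows per subject,
anything richer would be badly over-parameterised.  Channels should be
standardised before fitting (see :class:`Standardizer`); heart rate in BPM
and skin conductance in microsiemens differ by orders of magnitude.

Sequences are ``(n_channels, n_frames)`` matrices, matching
:class:`~physioconc.sampling.Sample`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .signal_model import ValidationError

DEFAULT_N_STATES = 3
VARIANCE_FLOOR = 1e-6


class InsufficientDataError(ValueError):
    """Too few sequences (or subjects) for the requested fit."""


@dataclass(frozen=True)
class HMMParams:
    """Fitted model theta: initial distribution, transitions, emissions."""

    initial: np.ndarray          # (K,)
    transition: np.ndarray       # (K, K) row-stochastic
    means: np.ndarray            # (K, D)
    variances: np.ndarray        # (K, D)

    def __post_init__(self) -> None:
        initial = np.asarray(self.initial, dtype=float)
        transition = np.asarray(self.transition, dtype=float)
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        K = initial.shape[0]
        if transition.shape != (K, K):
            raise ValidationError("transition must be K x K")
        if means.shape[0] != K or variances.shape != means.shape:
            raise ValidationError("means/variances must be K x D")
        if abs(initial.sum() - 1.0) > 1e-10:
            raise ValidationError("initial distribution must sum to 1")
        if np.max(np.abs(transition.sum(axis=1) - 1.0)) > 1e-10:
            raise ValidationError("transition rows must sum to 1")
        if np.any(variances < VARIANCE_FLOOR * (1 - 1e-12)):
            raise ValidationError("variances below the variance floor")
        for name, arr in (
            ("initial", initial),
            ("transition", transition),
            ("means", means),
            ("variances", variances),
        ):
            object.__setattr__(self, name, arr)

    @property
    def n_states(self) -> int:
        return self.initial.shape[0]

    @property
    def n_channels(self) -> int:
        return self.means.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_states": self.n_states,
                "initial": self.initial.tolist(),
                "transition": self.transition.tolist(),
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "HMMParams":
        doc = json.loads(text)
        return cls(
            initial=np.array(doc["initial"]),
            transition=np.array(doc["transition"]),
            means=np.array(doc["means"]),
            variances=np.array(doc["variances"]),
        )


@dataclass
class FitReport:
    loglik_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False


class Standardizer:
    """Per-channel z-scoring with statistics from the training set only."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, sequences: list[np.ndarray]) -> "Standardizer":
        pooled = np.concatenate([np.asarray(s, dtype=float) for s in sequences], axis=1)
        self.mean_ = pooled.mean(axis=1)
        self.std_ = np.maximum(pooled.std(axis=1), 1e-8)
        return self

    def transform(self, seq: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValidationError("Standardizer not fitted")
        return (np.asarray(seq, dtype=float) - self.mean_[:, None]) / self.std_[:, None]


# ---------------------------------------------------------------------------
# internals: batched scaled forward / backward on (N, T, K) emission densities


def _log_emissions(params: HMMParams, X: np.ndarray) -> np.ndarray:
    """log N(x_t | mu_k, diag var_k) for X of shape (N, T, D) -> (N, T, K)."""
    diff = X[:, :, None, :] - params.means[None, None, :, :]
    return -0.5 * np.sum(
        diff * diff / params.variances[None, None] + np.log(2 * np.pi * params.variances)[None, None],
        axis=-1,
    )


def _forward(params, logB):
    """Scaled forward pass.

    Returns (alpha, log_norm, loglik) where alpha has shape (N, T, K) and
    is normalised per step, and loglik is the per-sequence log p(X|theta).
    Per-frame emission maxima are factored out of the exponential so the
    recursion never under- or overflows, even for 60-frame windows.
    """
    N, T, K = logB.shape
    bmax = logB.max(axis=2, keepdims=True)              # (N, T, 1)
    B = np.exp(logB - bmax)
    alpha = np.empty((N, T, K))
    log_norm = np.empty((N, T))
    a = params.initial[None, :] * B[:, 0, :]
    c = a.sum(axis=1)
    alpha[:, 0, :] = a / c[:, None]
    log_norm[:, 0] = np.log(c)
    for t in range(1, T):
        a = (alpha[:, t - 1, :] @ params.transition) * B[:, t, :]
        c = a.sum(axis=1)
        alpha[:, t, :] = a / c[:, None]
        log_norm[:, t] = np.log(c)
    loglik = log_norm.sum(axis=1) + bmax[:, :, 0].sum(axis=1)
    return alpha, B, loglik


def _backward(params, B):
    N, T, K = B.shape
    beta = np.empty((N, T, K))
    beta[:, T - 1, :] = 1.0
    for t in range(T - 2, -1, -1):
        b = (B[:, t + 1, :] * beta[:, t + 1, :]) @ params.transition.T
        beta[:, t, :] = b / b.sum(axis=1, keepdims=True)
    return beta


def _forward_log(params: HMMParams, logB: np.ndarray) -> np.ndarray:
    """Log-domain forward recursion: per-sequence log p(X|theta).

    Unlike the scaled recursion used inside EM, this cannot underflow even
    when a test sequence lies hundreds of standard deviations from every
    state (routine when scoring one subject's windows under another
    subject's model).
    """
    with np.errstate(divide="ignore"):
        log_init = np.log(params.initial)
        logA = np.log(params.transition)
    N, T, K = logB.shape
    la = log_init[None, :] + logB[:, 0, :]
    for t in range(1, T):
        m = la[:, :, None] + logA[None, :, :]           # (N, K, K)
        mmax = m.max(axis=1)
        with np.errstate(invalid="ignore"):
            la = mmax + np.log(np.sum(np.exp(m - mmax[:, None, :]), axis=1))
        la = np.where(np.isfinite(mmax), la, -np.inf) + logB[:, t, :]
    mmax = la.max(axis=1)
    out = mmax + np.log(np.sum(np.exp(la - mmax[:, None]), axis=1))
    return np.where(np.isfinite(mmax), out, -np.inf)


def loglik(params: HMMParams, sequence: np.ndarray) -> float:
    """log p(X | theta) by the log-domain forward algorithm."""
    return float(loglik_batch(params, [sequence])[0])


def loglik_batch(params: HMMParams, sequences: list[np.ndarray]) -> np.ndarray:
    """Vectorised log p(X | theta) for equal-length sequences."""
    X = _stack(params, sequences)
    return _forward_log(params, _log_emissions(params, X))


def _stack(params: HMMParams, sequences) -> np.ndarray:
    mats = [np.asarray(s, dtype=float) for s in sequences]
    for m in mats:
        if m.ndim != 2 or m.shape[0] != params.n_channels:
            raise ValidationError(
                f"sequence has {m.shape[0]} channels, model expects {params.n_channels}"
            )
        if m.shape[1] < 1:
            raise ValidationError("empty sequence")
    if len({m.shape[1] for m in mats}) != 1:
        raise ValidationError("loglik_batch requires equal-length sequences")
    return np.stack([m.T for m in mats])  # (N, T, D)


def _init_params(X: np.ndarray, n_states: int, rng: np.random.Generator) -> HMMParams:
    """Seeded initialisation: state means at evenly spaced quantiles of the
    pooled frames, perturbed by a little noise; uniform initial/transition."""
    N, T, D = X.shape
    pooled = X.reshape(-1, D)
    qs = (np.arange(n_states) + 0.5) / n_states
    means = np.quantile(pooled, qs, axis=0)             # (K, D)
    scale = np.maximum(pooled.std(axis=0), 1e-3)
    means = means + rng.normal(0.0, 0.05, means.shape) * scale
    variances = np.maximum(np.var(pooled, axis=0), VARIANCE_FLOOR)
    variances = np.tile(variances, (n_states, 1))
    K = n_states
    return HMMParams(
        initial=np.full(K, 1.0 / K),
        transition=np.full((K, K), 1.0 / K),
        means=means,
        variances=variances,
    )


def fit(
    sequences: list[np.ndarray],
    n_states: int = DEFAULT_N_STATES,
    seed: int | np.random.Generator = 0,
    *,
    max_iter: int = 100,
    tol: float = 1e-4,
    variance_floor: float = VARIANCE_FLOOR,
    n_restarts: int = 1,
) -> tuple[HMMParams, FitReport]:
    """Baum-Welch on all sequences jointly.

    Stops when the total log-likelihood gain over one EM sweep drops below
    ``tol`` or after ``max_iter`` sweeps.  Emission variances are floored
    at ``variance_floor`` so near-constant windows cannot collapse a state.
    The reported ``loglik_trace`` holds the total training log-likelihood
    evaluated at the start of each sweep and is non-decreasing.

    With ``n_restarts > 1``, EM is run from that many seeded
    initialisations and the run with the best final training
    log-likelihood is returned.
    """
    if n_restarts > 1:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        best = None
        for _ in range(n_restarts):
            cand = fit(
                sequences, n_states, rng, max_iter=max_iter, tol=tol,
                variance_floor=variance_floor, n_restarts=1,
            )
            if best is None or cand[1].loglik_trace[-1] > best[1].loglik_trace[-1]:
                best = cand
        return best
    if len(sequences) < 2:
        raise InsufficientDataError(f"need at least 2 sequences, got {len(sequences)}")
    mats = [np.asarray(s, dtype=float) for s in sequences]
    dims = {m.shape[0] for m in mats}
    if len(dims) != 1:
        raise ValidationError(f"sequences disagree on channel count: {sorted(dims)}")
    if min(m.shape[1] for m in mats) < n_states:
        raise ValidationError("sequences shorter than the number of states")
    if len({m.shape[1] for m in mats}) != 1:
        # rare path: pad-free handling by grouping is not needed for this
        # pipeline (all windows share one length); fit on truncation.
        tmin = min(m.shape[1] for m in mats)
        mats = [m[:, :tmin] for m in mats]
    X = np.stack([m.T for m in mats])                   # (N, T, D)
    N, T, D = X.shape
    K = n_states
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    params = _init_params(X, K, rng)
    report = FitReport()
    prev_ll = -np.inf
    for it in range(max_iter):
        logB = _log_emissions(params, X)
        alpha, B, ll_seq = _forward(params, logB)
        total_ll = float(ll_seq.sum())
        report.loglik_trace.append(total_ll)
        report.n_iterations = it + 1
        if total_ll - prev_ll < tol and it > 0:
            report.converged = True
            break
        prev_ll = total_ll

        beta = _backward(params, B)
        gamma = alpha * beta
        gamma /= gamma.sum(axis=2, keepdims=True)

        # xi accumulated over time: (K, K)
        xi_sum = np.zeros((K, K))
        for t in range(T - 1):
            # (N, K, K): alpha_t[i] * A[ij] * B_{t+1}[j] * beta_{t+1}[j]
            m = (
                alpha[:, t, :, None]
                * params.transition[None, :, :]
                * (B[:, t + 1, None, :] * beta[:, t + 1, None, :])
            )
            xi_sum += (m / m.sum(axis=(1, 2), keepdims=True)).sum(axis=0)

        initial = gamma[:, 0, :].mean(axis=0)
        initial /= initial.sum()
        transition = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        w = gamma.reshape(-1, K)                        # (N*T, K)
        flat = X.reshape(-1, D)
        wsum = w.sum(axis=0)                            # (K,)
        means = (w.T @ flat) / wsum[:, None]
        sq = (w.T @ (flat * flat)) / wsum[:, None]
        variances = np.maximum(sq - means * means, variance_floor)
        params = HMMParams(
            initial=initial, transition=transition, means=means, variances=variances
        )
    return params, report


def sample_from(
    params: HMMParams, length: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw one (n_channels, length) sequence from the model; seeded."""
    if length < 1:
        raise ValidationError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = params.n_states
    states = np.empty(length, dtype=int)
    states[0] = rng.choice(K, p=params.initial)
    for t in range(1, length):
        states[t] = rng.choice(K, p=params.transition[states[t - 1]])
    out = params.means[states] + rng.normal(size=(length, params.n_channels)) * np.sqrt(
        params.variances[states]
    )
    return out.T
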