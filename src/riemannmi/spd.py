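"""Affine-invariant Riemannian geometry of SPD matrices.

EEG trials are summarised by their spatial covariance matrices (SCMs), which
live on the manifold of symmetric positive-definite (SPD) matrices.  This
module provides the geometric toolbox everything else is built on: SCM
estimation, the affine-invariant distance, exponential/logarithmic maps, the
Karcher (geometric) mean, and the isometric tangent-space vectorization that
turns SPD matrices into Euclidean feature vectors.

All matrix functions go through symmetric eigendecompositions and accept
stacked inputs (``(..., n, n)``), which keeps the Karcher-mean inner loop
vectorized over whole trial sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "Trial",
    "MeanConfig",
    "DegenerateTrialError",
    "MeanConvergenceError",
    "compute_scm",
    "compute_scms",
    "riemannian_distance",
    "distances_to",
    "exp_map",
    "log_map",
    "riemannian_mean",
    "tangent_vectorize",
    "tangent_vectorize_many",
    "upper_vectorize",
    "upper_unvectorize",
    "check_spd",
    "is_spd",
    "sqrtm",
    "invsqrtm",
    "logm",
    "expm",
]

#: Labels equal to this sentinel mark trials whose class is unknown.
UNLABELLED = -1


class DegenerateTrialError(ValueError):
    """A trial whose covariance cannot be made positive definite."""


class MeanConvergenceError(RuntimeError):
    """Karcher flow failed to converge; carries the last iterate and residual."""

    def __init__(self, message: str, last_iterate: np.ndarray, residual: float):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.residual = residual


@dataclass
class Trial:
    """One epoched EEG segment.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Band-limited EEG, microvolts.
    fs : float
        Sampling rate in Hz.
    label : int
        Class identifier; ``UNLABELLED`` (-1) if unknown.
    """

    data: np.ndarray
    fs: float
    label: int = UNLABELLED

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trial data must be 2-D (channels x samples)")
        n, ts = self.data.shape
        if n < 2:
            raise ValueError("a trial needs at least 2 channels")
        if ts < n + 1:
            raise ValueError(
                f"need at least n+1={n + 1} samples for a full-rank SCM, got {ts}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data contains non-finite entries")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class MeanConfig:
    """Stopping rule for the Karcher flow.

    ``tolerance`` bounds the Frobenius norm of the mean tangent displacement,
    relative to the mean Frobenius norm of the inputs.
    """

    tolerance: float = 1e-8
    max_iterations: int = 300
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0 < self.step <= 1:
            raise ValueError("step must be in (0, 1]")


# ---------------------------------------------------------------------------
# matrix functions (batched, eigendecomposition based)
# ---------------------------------------------------------------------------

_EIG_CLIP = 1e-12  # eigenvalues below _EIG_CLIP * lambda_max are clipped


def _sym(A: np.ndarray) -> np.ndarray:
    return 0.5 * (A + np.swapaxes(A, -1, -2))


def _eig_fun(P: np.ndarray, fun, clip: bool) -> np.ndarray:
    w, V = np.linalg.eigh(_sym(np.asarray(P, dtype=float)))
    if clip:
        floor = _EIG_CLIP * w[..., -1:]
        w = np.maximum(w, floor)
    return _sym(np.einsum("...ij,...j,...kj->...ik", V, fun(w), V))


def sqrtm(P: np.ndarray) -> np.ndarray:
    """Principal square root of an SPD matrix (stacked OK)."""
    return _eig_fun(P, np.sqrt, clip=True)


def invsqrtm(P: np.ndarray) -> np.ndarray:
    """Inverse principal square root of an SPD matrix (stacked OK)."""
    return _eig_fun(P, lambda w: 1.0 / np.sqrt(w), clip=True)


def logm(P: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (stacked OK)."""
    return _eig_fun(P, np.log, clip=True)


def expm(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (stacked OK)."""
    return _eig_fun(S, np.exp, clip=False)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_SYM_RTOL = 1e-10


def is_spd(P: np.ndarray, sym_rtol: float = _SYM_RTOL) -> bool:
    """True when ``P`` is symmetric (relative Frobenius) with positive spectrum."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        return False
    if not np.all(np.isfinite(P)):
        return False
    nrm = np.linalg.norm(P)
    if nrm == 0:
        return False
    if np.linalg.norm(P - P.T) > sym_rtol * nrm:
        return False
    return bool(np.linalg.eigvalsh(_sym(P))[0] > 0)


def check_spd(P: np.ndarray, name: str = "matrix") -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if not is_spd(P):
        raise ValueError(f"{name} is not symmetric positive definite")
    return P


def _check_pair(P1: np.ndarray, P2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P1 = check_spd(P1, "P1")
    P2 = check_spd(P2, "P2")
    if P1.shape != P2.shape:
        raise ValueError(f"dimension mismatch: {P1.shape} vs {P2.shape}")
    return P1, P2


# ---------------------------------------------------------------------------
# covariance estimation
# ---------------------------------------------------------------------------

def compute_scm(trial: Trial | np.ndarray, regularization: float = 0.0) -> np.ndarray:
    """Sample spatial covariance matrix of one trial, ``X X^T / (Ts - 1)``.

    A ridge ``regularization * I`` is added if requested.  If the result is
    still poorly conditioned (smallest eigenvalue below ``1e-10`` times the
    largest), trace-normalized shrinkage ``(1-g) P + g (tr P / n) I`` is
    applied with the smallest ``g`` in {1e-6, 1e-4, 1e-2} that restores
    conditioning; the event is logged.

    Raises
    ------
    ValueError
        Non-finite input.
    DegenerateTrialError
        Covariance not positive definite even after shrinkage (e.g. an
        all-zero trial with no regularization).
    """
    X = trial.data if isinstance(trial, Trial) else np.asarray(trial, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a channels x samples matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("trial contains non-finite values")
    if regularization < 0:
        raise ValueError("regularization must be non-negative")
    n, ts = X.shape
    if ts < 2:
        raise ValueError("need at least 2 samples")
    P = (X @ X.T) / (ts - 1)
    if regularization > 0:
        P = P + regularization * np.eye(n)
    P = _sym(P)
    w = np.linalg.eigvalsh(P)
    if w[-1] <= 0:
        raise DegenerateTrialError("trial covariance has no positive eigenvalue")
    if w[0] > 1e-10 * w[-1]:
        return P
    mu = np.trace(P) / n
    for gamma in (1e-6, 1e-4, 1e-2):
        Q = _sym((1 - gamma) * P + gamma * mu * np.eye(n))
        wq = np.linalg.eigvalsh(Q)
        if wq[0] > 1e-10 * wq[-1] and wq[0] > 0:
            logger.info("SCM shrinkage applied (gamma=%g)", gamma)
            return Q
    raise DegenerateTrialError(
        "trial covariance is not positive definite after shrinkage"
    )


def compute_scms(trials: np.ndarray | Sequence, regularization: float = 0.0) -> np.ndarray:
    """SCMs for a stack of trials ``(I, n, Ts)`` -> ``(I, n, n)``."""
    if isinstance(trials, np.ndarray) and trials.ndim == 3:
        it = trials
    else:
        it = [t.data if isinstance(t, Trial) else t for t in trials]
    return np.stack([compute_scm(np.asarray(X), regularization) for X in it])


# ---------------------------------------------------------------------------
# distance, maps, mean
# ---------------------------------------------------------------------------

def riemannian_distance(P1: np.ndarray, P2: np.ndarray) -> float:
    """Affine-invariant distance ``sqrt(sum_i log^2 l_i)``.

    The ``l_i`` are the eigenvalues of ``P1^-1 P2`` (generalized eigenvalues
    of the pair), making the distance invariant under congruence
    ``P -> W P W^T`` and symmetric in its arguments.
    """
    P1, P2 = _check_pair(P1, P2)
    w = scipy.linalg.eigh(P2, P1, eigvals_only=True)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def distances_to(reference: np.ndarray, Ps: np.ndarray) -> np.ndarray:
    """Riemannian distances from each matrix in the stack ``Ps`` to ``reference``."""
    iref = invsqrtm(reference)
    w = np.linalg.eigvalsh(_sym(iref @ Ps @ iref))
    w = np.maximum(w, _EIG_CLIP * w[..., -1:])
    return np.sqrt(np.sum(np.log(w) ** 2, axis=-1))


def exp_map(P: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Exponential map at ``P``: ``P^1/2 exp(P^-1/2 S P^-1/2) P^1/2``."""
    P = check_spd(P, "P")
    S = np.asarray(S, dtype=float)
    if np.linalg.norm(S - S.T) > 1e-8 * max(np.linalg.norm(S), 1.0):
        raise ValueError("tangent matrix must be symmetric")
    h = sqrtm(P)
    ih = invsqrtm(P)
    return _sym(h @ expm(ih @ _sym(S) @ ih) @ h)


def log_map(P: np.ndarray, Pi: np.ndarray) -> np.ndarray:
    """Logarithmic map at ``P``: ``P^1/2 log(P^-1/2 Pi P^-1/2) P^1/2``."""
    P, Pi = _check_pair(P, Pi)
    h = sqrtm(P)
    ih = invsqrtm(P)
    return _sym(h @ logm(ih @ Pi @ ih) @ h)


def riemannian_mean(
    matrices: Sequence[np.ndarray] | np.ndarray,
    config: MeanConfig | None = None,
) -> np.ndarray:
    """Karcher (geometric) mean of a set of SPD matrices.

    Fixed-point Karcher flow: repeatedly average the whitened matrix logs and
    move the iterate along the resulting tangent direction, starting from the
    arithmetic mean.  Convergence is declared when the Frobenius norm of the
    mean tangent displacement drops below ``config.tolerance`` times the mean
    Frobenius norm of the inputs.  The manifold has non-positive curvature,
    so with unit step the flow converges for any input set in practice.
    """
    config = config or MeanConfig()
    Ps = np.asarray(matrices, dtype=float)
    if Ps.ndim == 2:
        Ps = Ps[None]
    if Ps.ndim != 3 or Ps.shape[0] == 0:
        raise ValueError("need a non-empty stack of square matrices")
    if Ps.shape[1] != Ps.shape[2]:
        raise ValueError("matrices must be square")
    if Ps.shape[0] == 1:
        return Ps[0].copy()
    scale = float(np.mean(np.linalg.norm(Ps, axis=(1, 2))))
    M = _sym(Ps.mean(axis=0))
    residual = np.inf
    step = config.step
    prev_residual = np.inf
    prev_M = M
    for _ in range(config.max_iterations):
        h = sqrtm(M)
        ih = invsqrtm(M)
        S = _sym(logm(ih @ Ps @ ih).mean(axis=0))
        residual = float(np.linalg.norm(h @ S @ h))
        if residual <= config.tolerance * scale:
            return M
        if residual >= prev_residual:
            # overshoot on widely spread / ill-conditioned inputs: backtrack
            step *= 0.5
            M = prev_M
            h = sqrtm(M)
            ih = invsqrtm(M)
            S = _sym(logm(ih @ Ps @ ih).mean(axis=0))
        else:
            prev_residual = residual
            prev_M = M
            step = min(step * 1.2, config.step)  # recover after backtracking
        M = _sym(h @ expm(step * S) @ h)
    raise MeanConvergenceError(
        f"Karcher flow did not converge in {config.max_iterations} iterations "
        f"(residual {residual:.3e})",
        last_iterate=M,
        residual=residual,
    )


# ---------------------------------------------------------------------------
# tangent-space vectorization
# ---------------------------------------------------------------------------

def upper_vectorize(S: np.ndarray) -> np.ndarray:
    """Row-major upper-triangle vectorization with sqrt(2) off-diagonal weights.

    The weighting makes the map a linear isometry from symmetric matrices
    with the Frobenius inner product to Euclidean space:
    ``||upper_vectorize(S)||_2 == ||S||_F``.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[-1]
    if S.shape[-2] != n:
        raise ValueError("matrix must be square")
    if np.max(np.abs(S - np.swapaxes(S, -1, -2))) > 1e-8 * max(
        np.max(np.abs(S)), 1.0
    ):
        raise ValueError("matrix must be symmetric")
    iu, ju = np.triu_indices(n)
    weights = np.where(iu == ju, 1.0, np.sqrt(2.0))
    return S[..., iu, ju] * weights


def upper_unvectorize(v: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`upper_vectorize`."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != n * (n + 1) // 2:
        raise ValueError(
            f"vector length {v.shape[-1]} incompatible with n={n} "
            f"(expected {n * (n + 1) // 2})"
        )
    iu, ju = np.triu_indices(n)
    weights = np.where(iu == ju, 1.0, np.sqrt(2.0))
    S = np.zeros(v.shape[:-1] + (n, n))
    S[..., iu, ju] = v / weights
    S[..., ju, iu] = S[..., iu, ju]
    return S


def tangent_vectorize(reference: np.ndarray, Pi: np.ndarray) -> np.ndarray:
    """Map ``Pi`` to the tangent plane anchored at ``reference``.

    Returns ``upper(log(reference^-1/2 Pi reference^-1/2))``, a vector of
    length ``n(n+1)/2`` whose Euclidean norm equals the Riemannian distance
    between ``reference`` and ``Pi`` (isometry at the anchor).
    """
    reference, Pi = _check_pair(reference, Pi)
    iref = invsqrtm(reference)
    return upper_vectorize(logm(iref @ Pi @ iref))


def tangent_vectorize_many(reference: np.ndarray, Ps: np.ndarray) -> np.ndarray:
    """Vectorized :func:`tangent_vectorize` over a stack ``(I, n, n)``."""
    reference = check_spd(reference, "reference")
    Ps = np.asarray(Ps, dtype=float)
    iref = invsqrtm(reference)
    return upper_vectorize(logm(_sym(iref @ Ps @ iref)))
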