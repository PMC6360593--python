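"""Synthetic motor-imagery-like EEG trials with covariance-coded classes.

The classifiers in this package act on spatial covariance matrices, so the
generator encodes class identity exactly there: each class has a distinct
SPD covariance (a shared Toeplitz background plus a class-specific rank-2
spatial power pattern), each trial draws its own covariance from a Wishart
distribution centred on the class covariance (within-class variability), and
the trial time series are zero-mean Gaussian samples band-limited to
8-30 Hz.  ``separation`` scales the between-class perturbations — 0 makes
all classes identically distributed (chance-level anchor), values around 5
give near-perfectly separable classes.

An ``unlabelled_fraction`` hides labels on a per-class uniform draw to
exercise the semi-supervised path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.stats

from . import preprocess
from .spd import UNLABELLED

__all__ = [
    "GeneratorConfig",
    "TrialSet",
    "make_class_covariances",
    "make_mixed_separability_covariances",
    "generate_trials",
]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    ``noise_df`` is the Wishart degrees of freedom of the trial-to-trial
    covariance jitter: larger means tighter classes.  Defaults mirror a
    22-channel-protocol scaled to 8 channels at 250 Hz with 2 s epochs and
    100 trials per class.
    """

    n_channels: int = 8
    fs: float = 250.0
    trial_seconds: float = 2.0
    classes: int = 4
    trials_per_class: int = 100
    separation: float = 5.0
    noise_df: float = 200.0
    unlabelled_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2 or self.classes < 1 or self.trials_per_class < 1:
            raise ValueError("counts must be >= 1 (and n_channels >= 2)")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 0 <= self.unlabelled_fraction < 1:
            raise ValueError("unlabelled_fraction must be in [0, 1)")
        if self.noise_df < self.n_channels:
            raise ValueError("noise_df must be >= n_channels")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_seconds * self.fs))


@dataclass
class TrialSet:
    """Generated trials: ``X`` is (I, n, Ts); ``y`` has -1 for hidden labels."""

    X: np.ndarray
    y: np.ndarray
    y_true: np.ndarray
    fs: float
    class_covariances: np.ndarray

    @property
    def labelled(self) -> np.ndarray:
        return self.y != UNLABELLED


def _toeplitz_background(n: int, rho: float = 0.5) -> np.ndarray:
    return scipy.linalg.toeplitz(rho ** np.arange(n))


def make_class_covariances(config: GeneratorConfig) -> np.ndarray:
    """Per-class SPD covariances: Toeplitz background + rank-2 class patterns.

    Class c adds ``separation * (u_c u_c' + v_c v_c')`` with class-specific
    orthonormal directions drawn reproducibly from the config seed, mimicking
    class-specific spatial power patterns.  The perturbation is positive
    semidefinite, so the result is SPD for any separation >= 0, and
    separation 0 gives identical classes.
    """
    n = config.n_channels
    rng = np.random.default_rng(config.seed)
    base = _toeplitz_background(n)
    covs = []
    for _ in range(config.classes):
        Q, _r = np.linalg.qr(rng.standard_normal((n, 2)))
        u, v = Q[:, 0], Q[:, 1]
        covs.append(base + config.separation * (np.outer(u, u) + np.outer(v, v)))
    return np.stack(covs)


def make_mixed_separability_covariances(
    n_channels: int = 8,
    sep_strong: float = 1.5,
    sep_weak: float = 0.3,
    sep_shared: float = 0.0,
    seed: int = 13,
) -> np.ndarray:
    """Four-class scenario with two separable and two overlapping classes.

    Classes 0 and 1 get distinct strong spatial patterns; classes 2 and 3
    share one pattern of strength ``sep_shared`` and differ only by a weak
    ``sep_weak`` differential, so they overlap heavily.  This is the
    constructed miniature of the situation the decision-tree framework is
    designed for: the separable classes can be peeled off by dedicated
    binary nodes before the hard pair is attacked.
    """
    rng = np.random.default_rng(seed)
    base = _toeplitz_background(n_channels)
    # 8 mutually orthonormal directions
    Q, _ = np.linalg.qr(rng.standard_normal((n_channels, n_channels)))
    covs = [
        base + sep_strong * (np.outer(Q[:, 0], Q[:, 0]) + np.outer(Q[:, 1], Q[:, 1])),
        base + sep_strong * (np.outer(Q[:, 2], Q[:, 2]) + np.outer(Q[:, 3], Q[:, 3])),
        base
        + sep_shared * np.outer(Q[:, 4], Q[:, 4])
        + sep_weak * np.outer(Q[:, 5], Q[:, 5]),
        base
        + sep_shared * np.outer(Q[:, 4], Q[:, 4])
        + sep_weak * np.outer(Q[:, 6], Q[:, 6]),
    ]
    return np.stack(covs)


def generate_trials(
    config: GeneratorConfig,
    class_covariances: np.ndarray | None = None,
    band_limit: bool = True,
) -> TrialSet:
    """Draw a labelled (and optionally partially unlabelled) trial set.

    Per trial of class c: the trial covariance is Wishart-distributed with
    mean equal to the class covariance (df = ``noise_df``), the time series
    are iid zero-mean Gaussian with that covariance, then band-limited to
    8-30 Hz.  Everything is reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    covs = (
        make_class_covariances(config)
        if class_covariances is None
        else np.asarray(class_covariances, dtype=float)
    )
    C = covs.shape[0]
    n = config.n_channels
    ts = config.n_samples
    X, y_true = [], []
    for c in range(C):
        wish = scipy.stats.wishart(df=config.noise_df, scale=covs[c] / config.noise_df)
        for _ in range(config.trials_per_class):
            W = wish.rvs(random_state=rng)
            L = np.linalg.cholesky(W)
            X.append(L @ rng.standard_normal((n, ts)))
            y_true.append(c)
    X = np.stack(X)
    y_true = np.asarray(y_true)
    if band_limit:
        X = preprocess.bandpass_array(X, config.fs)
    y = y_true.copy()
    if config.unlabelled_fraction > 0:
        for c in range(C):
            idx = np.flatnonzero(y_true == c)
            k = int(round(config.unlabelled_fraction * idx.size))
            hide = rng.choice(idx, size=k, replace=False)
            y[hide] = UNLABELLED
    return TrialSet(X=X, y=y, y_true=y_true, fs=config.fs, class_covariances=covs)
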