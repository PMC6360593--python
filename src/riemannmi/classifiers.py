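"""Covariance-based classifiers and agreement metrics.

Implements minimum distance to Riemannian mean (MDRM), Fisher geodesic
discriminant analysis filtering (FGDA) and its combination with MDRM
(FGMDRM), a deterministic k-nearest-neighbour classifier, and the accuracy /
Cohen's kappa metrics used to score motor-imagery decoders.

All estimators expose a small sklearn-like ``fit``/``predict`` surface so the
decision-tree framework can hold any of them at its nodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from . import spd

logger = logging.getLogger(__name__)

__all__ = [
    "MDRMModel",
    "FGDAFilter",
    "KNNModel",
    "mdrm_fit",
    "mdrm_predict",
    "mdrm_predict_many",
    "fgda_fit",
    "fgda_filter",
    "fgmdrm_fit",
    "fgmdrm_predict",
    "knn_fit",
    "knn_predict",
    "accuracy",
    "cohen_kappa",
    "MDRM",
    "FGMDRM",
    "KNNClassifier",
]


# ---------------------------------------------------------------------------
# MDRM
# ---------------------------------------------------------------------------

@dataclass
class MDRMModel:
    """Per-class Riemannian means.  ``classes`` fixes the tie-break order."""

    classes: np.ndarray
    means: np.ndarray  # (C, n, n)


def _class_order(labels: np.ndarray) -> np.ndarray:
    # sorted unique labels; this is the deterministic tie-break order
    return np.unique(np.asarray(labels))


def mdrm_fit(
    covs: np.ndarray,
    labels: np.ndarray,
    config: spd.MeanConfig | None = None,
) -> MDRMModel:
    """Fit one Riemannian mean per class.

    Raises ``ValueError`` if fewer than two classes are present or any class
    has no trials.
    """
    covs = np.asarray(covs, dtype=float)
    labels = np.asarray(labels)
    classes = _class_order(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    means = []
    for c in classes:
        sel = covs[labels == c]
        if sel.shape[0] == 0:
            raise ValueError(f"class {c} has no trials")
        means.append(spd.riemannian_mean(sel, config))
    return MDRMModel(classes=classes, means=np.stack(means))


def mdrm_predict(model: MDRMModel, P: np.ndarray) -> tuple[object, np.ndarray]:
    """Classify one covariance: nearest class mean in Riemannian distance.

    Returns ``(label, distances)`` with one distance per class in
    ``model.classes`` order.  Exact ties go to the first class in order.
    """
    P = spd.check_spd(P, "P")
    if P.shape != model.means.shape[1:]:
        raise ValueError("dimension mismatch with fitted model")
    d = np.array([spd.riemannian_distance(P, m) for m in model.means])
    idx = _argmin_with_ties(d)
    return model.classes[idx], d


_TIE_RTOL = 1e-10


def _argmin_with_ties(d: np.ndarray) -> int:
    """First index whose value is within relative tolerance of the minimum.

    Distances computed through eigendecompositions are equal only to
    rounding, so exact ties are resolved at a small relative tolerance;
    the winner is the first class in label order, and the event is logged.
    """
    dmin = d.min()
    tied = d <= dmin + _TIE_RTOL * max(dmin, 1.0)
    if tied.sum() > 1:
        logger.info("MDRM tie broken by class order")
    return int(np.argmax(tied))


def mdrm_predict_many(model: MDRMModel, Ps: np.ndarray) -> np.ndarray:
    """Vectorized prediction for a stack of covariances ``(I, n, n)``."""
    Ps = np.asarray(Ps, dtype=float)
    D = np.stack([spd.distances_to(m, Ps) for m in model.means], axis=1)
    dmin = D.min(axis=1, keepdims=True)
    tied = D <= dmin + _TIE_RTOL * np.maximum(dmin, 1.0)
    return model.classes[np.argmax(tied, axis=1)]


# ---------------------------------------------------------------------------
# FGDA / FGMDRM
# ---------------------------------------------------------------------------

@dataclass
class FGDAFilter:
    """Fisher geodesic filter: discriminant subspace in the tangent plane.

    ``basis`` has orthonormal columns spanning the most class-discriminant
    directions of the tangent vectors anchored at ``reference``.
    """

    reference: np.ndarray  # (n, n) tangent anchor
    basis: np.ndarray  # (D, r), orthonormal columns
    r: int


def _scatter_matrices(
    X: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Between- and within-class scatter of feature rows."""
    classes = _class_order(labels)
    gm = X.mean(axis=0)
    d = X.shape[1]
    Sb = np.zeros((d, d))
    Sw = np.zeros((d, d))
    for c in classes:
        Xc = X[labels == c]
        mc = Xc.mean(axis=0)
        diff = (mc - gm)[:, None]
        Sb += Xc.shape[0] * (diff @ diff.T)
        R = Xc - mc
        Sw += R.T @ R
    return Sb, Sw


def fgda_fit(
    tangent_vectors: np.ndarray,
    labels: np.ndarray,
    r: int | None = None,
    reference: np.ndarray | None = None,
) -> FGDAFilter:
    """Fisher discriminant directions of tangent vectors.

    Solves the generalized eigenproblem (between-class scatter, within-class
    scatter) on the tangent vectors and keeps the top ``r`` directions,
    orthonormalized.  ``r`` defaults to C-1; values up to the full tangent
    dimension are allowed (the extra directions then come from the same
    eigenbasis, and at full rank the filter is the identity projection).
    A ridge ``1e-9 tr(Sw)/D`` is added to the within-class scatter when it is
    ill-conditioned.
    """
    X = np.asarray(tangent_vectors, dtype=float)
    labels = np.asarray(labels)
    classes = _class_order(labels)
    C = classes.size
    D = X.shape[1]
    if C < 2:
        raise ValueError("need at least two classes")
    if r is None:
        r = C - 1
    if not 1 <= r <= D:
        raise ValueError(f"r must be in [1, {D}]")
    Sb, Sw = _scatter_matrices(X, labels)
    tr = np.trace(Sw)
    ridge = 1e-9 * tr / D if tr > 0 else 1e-9
    Sw_reg = Sw + ridge * np.eye(D)
    # escalate the ridge if the within scatter is numerically singular
    for _ in range(6):
        try:
            w, V = scipy.linalg.eigh(Sb, Sw_reg)
            break
        except scipy.linalg.LinAlgError:
            ridge *= 100
            Sw_reg = Sw + ridge * np.eye(D)
    else:  # pragma: no cover - extreme degeneracy
        raise np.linalg.LinAlgError("within-class scatter irreparably singular")
    order = np.argsort(w)[::-1]
    B = V[:, order[:r]]
    # generalized eigenvectors are Sw-orthogonal, not Euclidean-orthogonal
    Q, _ = np.linalg.qr(B)
    if reference is None:
        reference = np.eye(int((np.sqrt(8 * D + 1) - 1) / 2))
    return FGDAFilter(reference=np.asarray(reference, dtype=float), basis=Q, r=r)


def fgda_filter(filt: FGDAFilter, P: np.ndarray) -> np.ndarray:
    """Filter a covariance through the discriminant subspace.

    Tangent-vectorize at the filter's anchor, project onto the retained
    directions, and map back to the manifold, producing an SPD matrix whose
    non-discriminant tangent components are suppressed.
    """
    s = spd.tangent_vectorize(filt.reference, P)
    s_proj = filt.basis @ (filt.basis.T @ s)
    n = filt.reference.shape[0]
    # s lives in the whitened frame, so reconstruct as ref^1/2 exp(S) ref^1/2
    # (the inverse of the whitened log); with a full-rank basis this is an
    # exact round trip back to P
    h = spd.sqrtm(filt.reference)
    S = spd.upper_unvectorize(s_proj, n)
    return spd._sym(h @ spd.expm(S) @ h)


def _fgda_filter_many(filt: FGDAFilter, Ps: np.ndarray) -> np.ndarray:
    S = spd.tangent_vectorize_many(filt.reference, Ps)
    S_proj = S @ filt.basis @ filt.basis.T
    n = filt.reference.shape[0]
    h = spd.sqrtm(filt.reference)
    W = spd.upper_unvectorize(S_proj, n)
    return spd._sym(h @ spd.expm(W) @ h)


@dataclass
class FGMDRMModel:
    filter: FGDAFilter
    mdrm: MDRMModel


def fgmdrm_fit(
    covs: np.ndarray,
    labels: np.ndarray,
    r: int | None = None,
    mean_config: spd.MeanConfig | None = None,
) -> FGMDRMModel:
    """Fit FGDA filtering followed by MDRM on the filtered covariances.

    The tangent plane is anchored at the Riemannian mean of all training
    covariances.
    """
    covs = np.asarray(covs, dtype=float)
    anchor = spd.riemannian_mean(covs, mean_config)
    tvs = spd.tangent_vectorize_many(anchor, covs)
    filt = fgda_fit(tvs, labels, r=r, reference=anchor)
    filtered = _fgda_filter_many(filt, covs)
    return FGMDRMModel(filter=filt, mdrm=mdrm_fit(filtered, labels, mean_config))


def fgmdrm_predict(model: FGMDRMModel, P: np.ndarray):
    """Filter then classify; returns ``(label, distances)``."""
    return mdrm_predict(model.mdrm, fgda_filter(model.filter, P))


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------

@dataclass
class KNNModel:
    points: np.ndarray
    labels: np.ndarray
    k: int = 5


def knn_fit(points: np.ndarray, labels: np.ndarray, k: int = 5) -> KNNModel:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    if points.shape[0] == 0:
        raise ValueError("empty training set")
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be a positive odd integer")
    if k > points.shape[0]:
        raise ValueError("k exceeds number of training points")
    return KNNModel(points=points, labels=labels, k=k)


def knn_predict(model: KNNModel, x: np.ndarray):
    """Majority vote among the k Euclidean nearest training points.

    Vote ties are broken by the smallest summed distance to the query, then
    by label order.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    d2 = ((X[:, None, :] - model.points[None, :, :]) ** 2).sum(axis=2)
    out = []
    classes = _class_order(model.labels)
    for row in d2:
        nn = np.argsort(row, kind="stable")[: model.k]
        votes = model.labels[nn]
        counts = np.array([np.sum(votes == c) for c in classes])
        best = counts.max()
        tied = [i for i in range(classes.size) if counts[i] == best]
        if len(tied) > 1:
            sums = [row[nn][votes == classes[i]].sum() for i in tied]
            tied = [tied[int(np.argmin(sums))]]
        out.append(classes[tied[0]])
    out = np.asarray(out)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def accuracy(y_true, y_pred) -> float:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("label vectors must be non-empty and equal length")
    return float(np.mean(y_true == y_pred))


def cohen_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)``.

    ``p_e`` is the expected agreement from the marginal label frequencies.
    When both vectors are constant and identical, ``p_e = 1`` and kappa is
    defined as 0 with a warning (no chance correction is possible).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("label vectors must be non-empty and equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    n = y_true.size
    p_o = np.mean(y_true == y_pred)
    pt = np.array([np.mean(y_true == c) for c in classes])
    pp = np.array([np.mean(y_pred == c) for c in classes])
    p_e = float(pt @ pp)
    if p_e >= 1.0 - 1e-15:
        warnings.warn("kappa undefined (single class on both sides); returning 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


# ---------------------------------------------------------------------------
# estimator wrappers for the decision-tree framework
# ---------------------------------------------------------------------------

class MDRM:
    """Estimator wrapper: nearest Riemannian class mean."""

    sample_ndim = 2  # one sample is an (n, n) covariance

    def __init__(self, mean_config: spd.MeanConfig | None = None):
        self.mean_config = mean_config
        self.model_: MDRMModel | None = None

    def fit(self, covs, labels):
        self.model_ = mdrm_fit(covs, labels, self.mean_config)
        return self

    def predict(self, covs):
        return mdrm_predict_many(self.model_, np.asarray(covs, dtype=float))

    def clone(self):
        return MDRM(self.mean_config)


class FGMDRM:
    """Estimator wrapper: Fisher-geodesic filtered MDRM."""

    sample_ndim = 2

    def __init__(self, r: int | None = None, mean_config: spd.MeanConfig | None = None):
        self.r = r
        self.mean_config = mean_config
        self.model_: FGMDRMModel | None = None

    def fit(self, covs, labels):
        self.model_ = fgmdrm_fit(covs, labels, r=self.r, mean_config=self.mean_config)
        return self

    def predict(self, covs):
        filtered = _fgda_filter_many(self.model_.filter, np.asarray(covs, dtype=float))
        return mdrm_predict_many(self.model_.mdrm, filtered)

    def clone(self):
        return FGMDRM(self.r, self.mean_config)


class KNNClassifier:
    """Estimator wrapper: deterministic Euclidean k-nearest neighbours."""

    sample_ndim = 1  # one sample is a (d,) feature vector

    def __init__(self, k: int = 5):
        self.k = k
        self.model_: KNNModel | None = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        k = min(self.k, X.shape[0])
        if k % 2 == 0:
            k -= 1
        self.model_ = knn_fit(X, y, k=max(k, 1))
        return self

    def predict(self, X):
        return knn_predict(self.model_, np.asarray(X, dtype=float))

    def clone(self):
        return KNNClassifier(self.k)
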