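"""Semi-supervised joint-mutual-information ranking + kernel GDA ("SJGDA").

Tangent-space vectorization of EEG covariance matrices produces n(n+1)/2
features per trial — too many for the small trial counts of a BCI session.
This module implements the feature-reduction stack used on top of the
tangent vectors:

1.  greedy joint-mutual-information (JMI) feature ranking, optionally
    exploiting an unlabelled trial pool under a class-prior-change (MAR-C)
    missingness model;
2.  cross-validated selection of the retained length ``m``;
3.  generalized discriminant analysis (GDA): a kernel Fisher discriminant
    with a polynomial kernel, projecting to ``d`` dimensions (default 1);
4.  the SJGDA concatenation ``[f_G | f_SJ]`` of the GDA projection with the
    top-m ranked raw features.

Mutual information is estimated by the plug-in estimator on equal-frequency
discretized features (8 bins by default), in bits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .spd import UNLABELLED

logger = logging.getLogger(__name__)

__all__ = [
    "Discretizer",
    "Ranking",
    "GDAModel",
    "SJGDAModel",
    "discretize",
    "mutual_information",
    "jmi_rank",
    "select_length",
    "poly_kernel",
    "gda_fit",
    "gda_transform",
    "sjgda_fit",
    "sjgda_transform",
    "SJGDAKNN",
]


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class Discretizer:
    """Per-feature equal-frequency binning (monotone map, edges stored)."""

    edges: list[np.ndarray]
    bins: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape, dtype=np.int64)
        for j, e in enumerate(self.edges):
            out[:, j] = np.searchsorted(e, X[:, j], side="left")
        return out


def discretize(X: np.ndarray, bins: int = 8) -> tuple[np.ndarray, Discretizer]:
    """Fit equal-frequency bins on all rows and return codes + the fitted map.

    Quantile edges are interior (bins-1 of them); a constant feature
    collapses to a single bin with a warning.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    edges = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            warnings.warn(f"feature {j} is constant; using a single bin")
            edges.append(np.empty(0))
            continue
        q = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
        edges.append(np.unique(q))
    disc = Discretizer(edges=edges, bins=bins)
    return disc.transform(X), disc


# ---------------------------------------------------------------------------
# mutual information (plug-in, bits)
# ---------------------------------------------------------------------------

def _codes(a: np.ndarray) -> tuple[np.ndarray, int]:
    u, inv = np.unique(a, return_inverse=True)
    return inv, u.size


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information I(a;b) in bits from the empirical joint.

    ``a`` may be a 2-column array, in which case the joint variable
    ``(a1, a2)`` is used — this is the ``I(X_k, X_j; Y)`` form the JMI score
    needs.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.ndim == 2:
        c0, n0 = _codes(a[:, 0])
        c1, n1 = _codes(a[:, 1])
        a = c0 * n1 + c1
    if a.shape[0] != b.shape[0]:
        raise ValueError("length mismatch")
    ca, na = _codes(a)
    cb, nb = _codes(b)
    joint = np.bincount(ca * nb + cb, minlength=na * nb).astype(float)
    joint /= joint.sum()
    pa = joint.reshape(na, nb).sum(axis=1)
    pb = joint.reshape(na, nb).sum(axis=0)
    return max(_entropy(pa) + _entropy(pb) - _entropy(joint), 0.0)


# ---------------------------------------------------------------------------
# MAR-C semi-supervised MI
# ---------------------------------------------------------------------------

def _marc_priors(
    cond: np.ndarray, labelled_prior: np.ndarray, x_unlab: np.ndarray,
    n_iter: int = 100, tol: float = 1e-10,
) -> np.ndarray:
    """EM re-estimate of class priors from the unlabelled marginal.

    Under class-prior-change missingness the class-conditionals p(x|y) seen in
    the labelled set transfer to the full population, but the class priors do
    not.  Starting from the labelled frequencies, iterate posterior
    responsibilities over the unlabelled rows.  With no unlabelled rows the
    labelled priors are returned unchanged.
    """
    if x_unlab.size == 0:
        return labelled_prior
    pi = labelled_prior.copy()
    lik = cond[:, x_unlab]  # (C, N_u) = p(x_u | y)
    for _ in range(n_iter):
        w = pi[:, None] * lik
        tot = w.sum(axis=0)
        tot[tot == 0] = 1.0
        new = (w / tot).mean(axis=1)
        if np.max(np.abs(new - pi)) < tol:
            pi = new
            break
        pi = new
    return pi


def _marc_mi(x: np.ndarray, y: np.ndarray, labelled: np.ndarray) -> float:
    """I(x; y) in bits assembled from MAR-C-corrected distributions.

    p(x|y) comes from the labelled rows (Laplace 0.5 smoothing so unlabelled
    cells keep mass), priors are re-estimated by EM on the unlabelled
    marginal, and the joint is their product.
    """
    cx, nx = _codes(x)
    yl = y[labelled]
    classes, yc = np.unique(yl, return_inverse=True)
    C = classes.size
    counts = np.zeros((C, nx))
    np.add.at(counts, (yc, cx[labelled]), 1.0)
    cond = (counts + 0.5) / (counts.sum(axis=1, keepdims=True) + 0.5 * nx)
    prior_l = counts.sum(axis=1) / counts.sum()
    pi = _marc_priors(cond, prior_l, cx[~labelled])
    joint = pi[:, None] * cond  # (C, nx)
    px = joint.sum(axis=0)
    return max(_entropy(pi) + _entropy(px) - _entropy(joint.ravel()), 0.0)


def _mi_term(
    xcols: np.ndarray, y: np.ndarray, labelled: np.ndarray, semi: bool
) -> float:
    """One MI term of the JMI score; ``xcols`` is 1 or 2 discrete columns."""
    if xcols.ndim == 2:
        c0, _ = _codes(xcols[:, 0])
        c1, n1 = _codes(xcols[:, 1])
        x = c0 * n1 + c1
    else:
        x = xcols
    if semi and np.any(~labelled):
        return _marc_mi(x, y, labelled)
    return mutual_information(x[labelled], y[labelled])


# ---------------------------------------------------------------------------
# JMI ranking
# ---------------------------------------------------------------------------

@dataclass
class Ranking:
    """Feature ordering with the JMI score recorded at selection time."""

    order: np.ndarray  # permutation of feature indices
    scores: np.ndarray  # score of each feature when it was selected


def jmi_rank(
    X: np.ndarray,
    y: np.ndarray,
    use_unlabelled: bool = False,
    bins: int = 8,
) -> Ranking:
    """Greedy joint-mutual-information feature ranking.

    The first feature maximizes I(X_k; Y); each subsequent pick maximizes
    the JMI score sum_{X_j in selected} I(X_k, X_j; Y).  The full ordering
    is returned.  Rows with label ``UNLABELLED`` (-1) are ignored by the
    supervised path; with ``use_unlabelled`` they enter every MI term via the
    class-prior-change (MAR-C) correction.  Discretization is fitted on all
    rows either way.  Score ties keep the lower feature index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labelled = y != UNLABELLED
    if labelled.sum() == 0:
        raise ValueError("no labelled rows")
    if np.unique(y[labelled]).size < 2:
        raise ValueError("need at least two labelled classes")
    n_feat = X.shape[1]
    if n_feat < 2:
        raise ValueError("need at least two features")
    Xd, _ = discretize(X, bins=bins)
    semi = use_unlabelled and bool(np.any(~labelled))

    relevance = np.array(
        [_mi_term(Xd[:, k], y, labelled, semi) for k in range(n_feat)]
    )
    first = int(np.argmax(relevance))
    order = [first]
    scores = [relevance[first]]
    remaining = [k for k in range(n_feat) if k != first]
    cumulative = np.zeros(n_feat)
    while remaining:
        last = order[-1]
        for k in remaining:
            cumulative[k] += _mi_term(Xd[:, [k, last]], y, labelled, semi)
        best = max(remaining, key=lambda k: (cumulative[k], -k))
        order.append(best)
        scores.append(cumulative[best])
        remaining.remove(best)
    return Ranking(order=np.asarray(order), scores=np.asarray(scores))


# ---------------------------------------------------------------------------
# length selection
# ---------------------------------------------------------------------------

def select_length(
    X: np.ndarray,
    y: np.ndarray,
    ranking: Ranking,
    classifier_factory,
    grid,
    folds: int = 10,
    seed: int = 0,
) -> int:
    """Pick the retained feature-vector length ``m`` by cross-validation.

    For each ``m`` in the grid the top-m ranked features are scored by
    stratified k-fold CV accuracy of a fresh classifier; the best ``m`` wins,
    ties going to the smallest.  Grid values beyond the feature count are
    dropped with a warning.  Only labelled rows participate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    keep = y != UNLABELLED
    X, y = X[keep], y[keep]
    grid = sorted(set(int(m) for m in grid))
    if not grid:
        raise ValueError("empty grid")
    n_feat = X.shape[1]
    valid = [m for m in grid if 1 <= m <= n_feat]
    if len(valid) < len(grid):
        warnings.warn("grid values beyond the feature count were dropped")
    if not valid:
        raise ValueError("no valid grid values")
    min_count = np.bincount(np.unique(y, return_inverse=True)[1]).min()
    n_splits = max(2, min(folds, int(min_count)))
    if n_splits < folds:
        warnings.warn(f"reducing folds from {folds} to {n_splits}")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    best_m, best_acc = valid[0], -1.0
    for m in valid:
        cols = ranking.order[:m]
        correct = 0
        for tr, te in splits:
            clf = classifier_factory()
            clf.fit(X[np.ix_(tr, cols)], y[tr])
            correct += int(np.sum(clf.predict(X[np.ix_(te, cols)]) == y[te]))
        acc = correct / len(y)
        if acc > best_acc:  # strict: ties keep the smallest m
            best_m, best_acc = m, acc
    return best_m


# ---------------------------------------------------------------------------
# polynomial-kernel GDA (kernel Fisher discriminant)
# ---------------------------------------------------------------------------

def poly_kernel(
    x: np.ndarray,
    y: np.ndarray,
    degree: int = 2,
    coef0: float = 1.0,
    scale: float | None = None,
) -> np.ndarray:
    """Polynomial kernel ``(scale <x, y> + coef0)^degree``.

    ``scale`` defaults to 1/dim.  Accepts vectors or row-stacked matrices and
    returns the scalar / Gram matrix accordingly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if scale is None:
        scale = 1.0 / x.shape[-1]
    g = np.atleast_2d(x) @ np.atleast_2d(y).T
    out = (scale * g + coef0) ** degree
    if x.ndim == 1 and y.ndim == 1:
        return float(out[0, 0])
    if x.ndim == 1 or y.ndim == 1:
        return out.ravel()
    return out


@dataclass
class GDAModel:
    """Fitted kernel Fisher discriminant.

    The projection of a query ``z`` is ``sum_j beta[j] k(x_j, z) + offset``
    per output dimension; ``beta``/``offset`` fold the training-kernel
    centering into plain kernel sums.  Training projections are normalized to
    unit within-class variance per dimension.
    """

    support_points: np.ndarray  # (N, p)
    beta: np.ndarray  # (N, d) effective coefficients (centering folded in)
    offset: np.ndarray  # (d,)
    alphas: np.ndarray  # (N, d) raw coefficients on the centered kernel
    degree: int
    coef0: float
    scale: float
    d: int
    train_projections: np.ndarray = field(default=None, repr=False)


def gda_fit(
    X: np.ndarray,
    y: np.ndarray,
    degree: int = 2,
    coef0: float = 1.0,
    scale: float | None = None,
    d: int = 1,
    ridge: float = 1e-8,
) -> GDAModel:
    """Kernel Fisher discriminant with a polynomial kernel.

    Maximizes between-class over within-class scatter in the kernel-induced
    space via the double-centered Gram matrix.  Components with eigenvalue
    below ``1e-10`` of the largest are dropped; the ridge on the within-class
    scatter escalates tenfold (up to 1e-2) if the solve fails.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes, yc = np.unique(y, return_inverse=True)
    C = classes.size
    if C < 2:
        raise ValueError("need at least two classes")
    if not 1 <= d <= C - 1:
        raise ValueError(f"d must be in [1, {C - 1}]")
    N = X.shape[0]
    if scale is None:
        scale = 1.0 / X.shape[1]
    K = poly_kernel(X, X, degree, coef0, scale)
    J = np.eye(N) - np.full((N, N), 1.0 / N)
    Kc = J @ K @ J

    # between-class scatter of centered kernel columns
    B = np.zeros((N, N))
    W = np.zeros((N, N))
    for ci in range(C):
        idx = np.flatnonzero(yc == ci)
        mu = Kc[:, idx].mean(axis=1)
        B += idx.size * np.outer(mu, mu)
        R = Kc[:, idx] - mu[:, None]
        W += R @ R.T

    import scipy.linalg as sla

    last_err: Exception | None = None
    r = ridge
    while r <= 1e-2 + 1e-15:
        try:
            trW = np.trace(W)
            Wreg = W + r * (trW / N if trW > 0 else 1.0) * np.eye(N)
            w, V = sla.eigh(B, Wreg)
            if np.all(np.isfinite(w)) and np.all(np.isfinite(V)):
                break
            raise np.linalg.LinAlgError("non-finite eigensolution")
        except (sla.LinAlgError, np.linalg.LinAlgError) as err:  # escalate
            last_err = err
            r *= 10
    else:
        raise np.linalg.LinAlgError(
            f"GDA eigenproblem failed up to ridge 1e-2: {last_err}"
        )
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    keep = w > 1e-10 * max(w[0], 0) if w[0] > 0 else np.zeros_like(w, bool)
    if keep.sum() < d:
        keep[:d] = True  # degenerate spectra still yield the requested dims
    A = V[:, :d]

    t = Kc @ A  # training projections
    # normalize to unit within-class variance per output dimension
    wvar = np.zeros(d)
    for ci in range(C):
        Tc = t[yc == ci]
        wvar += ((Tc - Tc.mean(axis=0)) ** 2).sum(axis=0)
    wvar /= N
    sfac = 1.0 / np.sqrt(np.maximum(wvar, 1e-30))
    A = A * sfac
    t = t * sfac

    # fold the centering into plain kernel sums: f(z) = beta^T k(., z) + offset
    ones = np.ones(N)
    JA = J @ A  # because f(z) = A^T J (k - K 1/N)
    beta = JA
    offset = -(JA.T @ K @ ones) / N
    return GDAModel(
        support_points=X,
        beta=beta,
        offset=offset,
        alphas=A,
        degree=degree,
        coef0=coef0,
        scale=scale,
        d=d,
        train_projections=t,
    )


def gda_transform(model: GDAModel, x: np.ndarray) -> np.ndarray:
    """Project queries onto the fitted discriminant directions.

    Returns shape ``(d,)`` for a single vector, ``(N, d)`` for a stack.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    Xq = np.atleast_2d(x)
    if Xq.shape[1] != model.support_points.shape[1]:
        raise ValueError("dimension mismatch with training data")
    Kq = poly_kernel(Xq, model.support_points, model.degree, model.coef0, model.scale)
    out = Kq @ model.beta + model.offset
    return out[0] if single else out


# ---------------------------------------------------------------------------
# SJGDA
# ---------------------------------------------------------------------------

@dataclass
class SJGDAModel:
    """Ranking + selected length + fitted GDA; output layout [f_G | f_SJ].

    ``out_mean``/``out_scale`` standardize every output coordinate on the
    training rows so the GDA projection and the raw tangent features are
    scale-commensurate for distance-based classifiers.
    """

    ranking: Ranking
    m: int
    gda: GDAModel
    feature_idx: np.ndarray  # top-m ranked feature indices
    out_mean: np.ndarray = None
    out_scale: np.ndarray = None

    @property
    def output_length(self) -> int:
        return self.m + self.gda.d


def sjgda_fit(
    X: np.ndarray,
    y: np.ndarray,
    classifier_factory=None,
    grid=None,
    degree: int = 2,
    coef0: float = 1.0,
    scale: float | None = None,
    d: int = 1,
    bins: int = 8,
    use_unlabelled: bool = True,
    folds: int = 10,
    seed: int = 0,
) -> SJGDAModel:
    """Fit the full SJGDA stack on a feature table.

    Rows with label ``UNLABELLED`` participate only in the semi-supervised
    ranking; length selection and GDA use labelled rows.  ``grid`` defaults
    to an 8-point grid up to min(100, n_features).
    """
    from .classifiers import KNNClassifier

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if classifier_factory is None:
        classifier_factory = lambda: KNNClassifier(k=5)
    n_feat = X.shape[1]
    if grid is None:
        cap = min(100, n_feat)
        grid = sorted(set(np.linspace(1, cap, num=min(8, cap), dtype=int).tolist()))
    ranking = jmi_rank(X, y, use_unlabelled=use_unlabelled, bins=bins)
    m = select_length(X, y, ranking, classifier_factory, grid, folds=folds, seed=seed)
    idx = ranking.order[:m]
    keep = y != UNLABELLED
    gda = gda_fit(X[np.ix_(np.flatnonzero(keep), idx)], y[keep],
                  degree=degree, coef0=coef0, scale=scale, d=d)
    model = SJGDAModel(ranking=ranking, m=m, gda=gda, feature_idx=idx)
    Z = _raw_transform(model, X[keep])
    model.out_mean = Z.mean(axis=0)
    sd = Z.std(axis=0)
    model.out_scale = np.where(sd > 0, sd, 1.0)
    return model


def _raw_transform(model: SJGDAModel, X: np.ndarray) -> np.ndarray:
    Xt = np.atleast_2d(X)[:, model.feature_idx]
    fg = np.atleast_2d(gda_transform(model.gda, Xt))
    return np.concatenate([fg, Xt], axis=1)


def sjgda_transform(model: SJGDAModel, x: np.ndarray) -> np.ndarray:
    """Map full tangent vectors to ``[f_G | f_SJ]`` (length d + m).

    Coordinates are standardized with the training-row statistics so the
    two blocks contribute commensurately to Euclidean distances.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    out = _raw_transform(model, np.atleast_2d(x))
    if model.out_mean is not None:
        out = (out - model.out_mean) / model.out_scale
    return out[0] if single else out


class SJGDAKNN:
    """Estimator wrapper: SJGDA feature extraction + k-nearest neighbours.

    An optional unlabelled tangent-vector pool (fixed at construction) feeds
    the semi-supervised ranking path of every fit.
    """

    sample_ndim = 1

    def __init__(
        self,
        k: int = 5,
        grid=None,
        degree: int = 2,
        coef0: float = 1.0,
        scale: float | None = None,
        d: int = 1,
        bins: int = 8,
        use_unlabelled: bool = True,
        folds: int = 10,
        seed: int = 0,
        unlabelled_pool: np.ndarray | None = None,
    ):
        self.k = k
        self.grid = grid
        self.degree = degree
        self.coef0 = coef0
        self.scale = scale
        self.d = d
        self.bins = bins
        self.use_unlabelled = use_unlabelled
        self.folds = folds
        self.seed = seed
        self.unlabelled_pool = unlabelled_pool
        self.model_: SJGDAModel | None = None
        self.knn_ = None

    def fit(self, X, y):
        from .classifiers import KNNClassifier

        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if self.unlabelled_pool is not None and len(self.unlabelled_pool):
            Xfull = np.vstack([X, self.unlabelled_pool])
            yfull = np.concatenate(
                [y, np.full(len(self.unlabelled_pool), UNLABELLED, dtype=y.dtype)]
            )
        else:
            Xfull, yfull = X, y
        self.model_ = sjgda_fit(
            Xfull,
            yfull,
            classifier_factory=lambda: KNNClassifier(k=self.k),
            grid=self.grid,
            degree=self.degree,
            coef0=self.coef0,
            scale=self.scale,
            d=self.d,
            bins=self.bins,
            use_unlabelled=self.use_unlabelled,
            folds=self.folds,
            seed=self.seed,
        )
        self.knn_ = KNNClassifier(k=self.k).fit(sjgda_transform(self.model_, X), y)
        return self

    def predict(self, X):
        return self.knn_.predict(sjgda_transform(self.model_, np.atleast_2d(X)))

    def clone(self):
        return SJGDAKNN(
            k=self.k, grid=self.grid, degree=self.degree, coef0=self.coef0,
            scale=self.scale, d=self.d, bins=self.bins,
            use_unlabelled=self.use_unlabelled, folds=self.folds, seed=self.seed,
            unlabelled_pool=self.unlabelled_pool,
        )
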