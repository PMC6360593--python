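"""End-to-end motor-imagery classification pipelines.

Two assemblies are provided:

*  **Method 1 (SSDT-FGMDRM)** — band-pass, spatial covariance per trial,
   then a subject-specific decision tree whose nodes are Fisher-geodesic
   filtered minimum-distance-to-Riemannian-mean classifiers.
*  **Method 2 (SJGDA + SSDT-KNN)** — band-pass, covariances, tangent-space
   mapping at the Riemannian mean of the training covariances, then a
   decision tree whose nodes each fit their own SJGDA feature reduction and
   classify with k-nearest neighbours (k = 5).  An unlabelled trial pool, if
   given, feeds only the semi-supervised feature-ranking path.

``crossval`` runs stratified k-fold evaluation with all fitting (node
ranking, feature ranking, length selection, GDA, Riemannian means) confined
to the training fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml
from sklearn.model_selection import StratifiedKFold

from . import preprocess, spd, ssdt
from .classifiers import FGMDRM, accuracy, cohen_kappa
from .sjgda import SJGDAKNN

__all__ = [
    "PipelineConfig",
    "EvaluationReport",
    "Method1Model",
    "Method2Model",
    "method1_fit",
    "method1_predict",
    "method2_fit",
    "method2_predict",
    "flat_fit",
    "crossval",
]


@dataclass
class PipelineConfig:
    """Every tunable of both pipelines, serializable to YAML/JSON."""

    method: int = 1
    # preprocessing
    apply_bandpass: bool = True
    band_low: float = 8.0
    band_high: float = 30.0
    band_order: int = 5
    scm_regularization: float = 0.0
    # Riemannian mean
    mean_tolerance: float = 1e-8
    mean_max_iterations: int = 300
    # SSDT
    ssdt_folds: int = 10
    seed: int = 0
    final_all_classes: bool = True
    tree: bool = True  # False = flat (single multiclass base classifier)
    # FGDA (method 1)
    fgda_r: int | None = None
    # SJGDA (method 2)
    knn_k: int = 5
    bins: int = 8
    kernel_degree: int = 2
    kernel_coef0: float = 1.0
    kernel_scale: float | None = None
    gda_d: int = 1
    grid_cap: int = 100
    grid: list | None = None
    semi: bool = True
    m_folds: int = 10

    def mean_config(self) -> spd.MeanConfig:
        return spd.MeanConfig(
            tolerance=self.mean_tolerance, max_iterations=self.mean_max_iterations
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class EvaluationReport:
    """Cross-validation summary mirroring a per-subject results table."""

    fold_accuracies: list
    fold_kappas: list
    mean_accuracy: float
    mean_kappa: float
    confusion: np.ndarray  # classes x classes, rows = truth, summed over folds
    classes: np.ndarray
    node_orders: list  # per fold: [(target class, cv accuracy), ...]
    selected_m: list  # per fold: {node_id: m} (method 2 only)

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "fold_kappas": [float(k) for k in self.fold_kappas],
            "mean_accuracy": float(self.mean_accuracy),
            "mean_kappa": float(self.mean_kappa),
            "confusion": self.confusion.tolist(),
            "classes": [int(c) for c in np.asarray(self.classes).tolist()],
            "node_orders": [
                [[int(c), float(a)] for c, a in fold] for fold in self.node_orders
            ],
            "selected_m": self.selected_m,
        }
        text = json.dumps(payload, indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _trials_to_covs(X: np.ndarray, config: PipelineConfig, fs: float) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if config.apply_bandpass:
        X = preprocess.bandpass_array(
            X, fs, config.band_low, config.band_high, config.band_order
        )
    return spd.compute_scms(X, config.scm_regularization)


# ---------------------------------------------------------------------------
# method 1
# ---------------------------------------------------------------------------

@dataclass
class Method1Model:
    tree: ssdt.SSDTModel
    config: PipelineConfig
    fs: float


def _fgmdrm_factory(config: PipelineConfig):
    return lambda: FGMDRM(r=config.fgda_r, mean_config=config.mean_config())


def method1_fit(X: np.ndarray, y: np.ndarray, config: PipelineConfig,
                fs: float = 250.0) -> Method1Model:
    """Fit SSDT-FGMDRM on epoched trials ``(I, n, Ts)`` with labels ``y``."""
    covs = _trials_to_covs(X, config, fs)
    if config.tree:
        tree = ssdt.build_ssdt(
            covs, y, _fgmdrm_factory(config),
            folds=config.ssdt_folds, seed=config.seed,
            final_all_classes=config.final_all_classes, base_kind="fgmdrm",
        )
    else:
        tree = _flat_tree(covs, y, _fgmdrm_factory(config), "fgmdrm")
    return Method1Model(tree=tree, config=config, fs=fs)


def method1_predict(model: Method1Model, X: np.ndarray) -> np.ndarray:
    """Predict labels for one trial ``(n, Ts)`` or a stack ``(I, n, Ts)``."""
    single = np.asarray(X).ndim == 2
    covs = _trials_to_covs(X, model.config, model.fs)
    out = ssdt.ssdt_predict(model.tree, covs)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# method 2
# ---------------------------------------------------------------------------

@dataclass
class Method2Model:
    anchor: np.ndarray  # tangent anchor: Riemannian mean of training SCMs
    tree: ssdt.SSDTModel
    config: PipelineConfig
    fs: float


def _sjgda_factory(config: PipelineConfig, unlabelled_pool):
    def make():
        return SJGDAKNN(
            k=config.knn_k,
            grid=config.grid,
            degree=config.kernel_degree,
            coef0=config.kernel_coef0,
            scale=config.kernel_scale,
            d=config.gda_d,
            bins=config.bins,
            use_unlabelled=config.semi,
            folds=config.m_folds,
            seed=config.seed,
            unlabelled_pool=unlabelled_pool,
        )

    return make


def _default_grid(config: PipelineConfig, n_features: int) -> list:
    cap = min(config.grid_cap, n_features)
    return sorted(set(np.linspace(1, cap, num=min(8, cap), dtype=int).tolist()))


def method2_fit(
    X: np.ndarray,
    y: np.ndarray,
    config: PipelineConfig,
    fs: float = 250.0,
    X_unlabelled: np.ndarray | None = None,
) -> Method2Model:
    """Fit SJGDA + SSDT-KNN on epoched trials.

    ``X_unlabelled`` is an optional pool of trials without labels; its
    tangent vectors enter only the semi-supervised feature ranking.
    """
    covs = _trials_to_covs(X, config, fs)
    anchor = spd.riemannian_mean(covs, config.mean_config())
    tvs = spd.tangent_vectorize_many(anchor, covs)
    pool = None
    if X_unlabelled is not None and len(X_unlabelled):
        covs_u = _trials_to_covs(X_unlabelled, config, fs)
        pool = spd.tangent_vectorize_many(anchor, covs_u)
    cfg = config
    if cfg.grid is None:
        cfg = PipelineConfig(**{**asdict(config), "grid": _default_grid(config, tvs.shape[1])})
    factory = _sjgda_factory(cfg, pool)
    if cfg.tree:
        tree = ssdt.build_ssdt(
            tvs, y, factory, folds=cfg.ssdt_folds, seed=cfg.seed,
            final_all_classes=cfg.final_all_classes, base_kind="sjgda-knn",
        )
    else:
        tree = _flat_tree(tvs, y, factory, "sjgda-knn")
    return Method2Model(anchor=anchor, tree=tree, config=cfg, fs=fs)


def method2_predict(model: Method2Model, X: np.ndarray) -> np.ndarray:
    single = np.asarray(X).ndim == 2
    covs = _trials_to_covs(X, model.config, model.fs)
    tvs = spd.tangent_vectorize_many(model.anchor, covs)
    out = ssdt.ssdt_predict(model.tree, tvs)
    return out[0] if single else out


def _flat_tree(X, y, factory, kind: str) -> ssdt.SSDTModel:
    """A single multiclass node — the flat counterpart of the SSDT."""
    clf = factory()
    clf.fit(X, y)
    node = ssdt.NodeSpec(1, "final-multiclass", None, clf, float("nan"))
    return ssdt.SSDTModel(nodes=[node], classes=np.unique(np.asarray(y)), base_kind=kind)


def flat_fit(X, y, config: PipelineConfig, fs: float = 250.0,
             X_unlabelled=None):
    """Fit the flat (no-tree) counterpart of the configured method."""
    cfg = PipelineConfig(**{**asdict(config), "tree": False})
    if cfg.method == 1:
        return method1_fit(X, y, cfg, fs)
    return method2_fit(X, y, cfg, fs, X_unlabelled)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def crossval(
    X: np.ndarray,
    y: np.ndarray,
    config: PipelineConfig,
    folds: int = 10,
    seed: int = 0,
    fs: float = 250.0,
    X_unlabelled: np.ndarray | None = None,
) -> EvaluationReport:
    """Stratified k-fold evaluation of the configured pipeline.

    All model fitting happens inside each training fold; the held-out fold
    is only ever touched by ``predict``.  ``folds`` equal to the trial count
    gives leave-one-out.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    classes = np.unique(y)
    if folds >= len(y):
        # stratification is meaningless at leave-one-out
        from sklearn.model_selection import LeaveOneOut

        splits = LeaveOneOut().split(np.zeros(len(y)))
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = skf.split(np.zeros(len(y)), y)
    accs, kappas, orders, ms = [], [], [], []
    conf = np.zeros((classes.size, classes.size), dtype=int)
    cidx = {c: i for i, c in enumerate(classes)}
    for tr, te in splits:
        if config.method == 1:
            model = method1_fit(X[tr], y[tr], config, fs)
            pred = method1_predict(model, X[te])
        else:
            model = method2_fit(X[tr], y[tr], config, fs, X_unlabelled)
            pred = method2_predict(model, X[te])
        pred = np.asarray(pred)
        accs.append(accuracy(y[te], pred))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # single-class folds in LOO
            kappas.append(cohen_kappa(y[te], pred))
        orders.append(list(model.tree.ranking))
        fold_m = {}
        for node in model.tree.nodes:
            m = getattr(getattr(node.classifier, "model_", None), "m", None)
            if m is not None:
                fold_m[node.node_id] = int(m)
        ms.append(fold_m)
        for t, p in zip(y[te], pred):
            conf[cidx[t], cidx[p]] += 1
    return EvaluationReport(
        fold_accuracies=accs,
        fold_kappas=kappas,
        mean_accuracy=float(np.mean(accs)),
        mean_kappa=float(np.mean(kappas)),
        confusion=conf,
        classes=classes,
        node_orders=orders,
        selected_m=ms,
    )
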