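"""Subject-specific decision tree (SSDT) classification framework.

Multiclass motor-imagery decoders often fail in the region where class
distributions overlap.  The SSDT framework exploits the observation that the
most separable classes differ per subject: one-vs-rest separability is ranked
by cross-validation, the two best classes get dedicated binary nodes that
peel their trials off first, and everything that reaches the end — including
trials leaked past the binary nodes — is reclassified by a final multiclass
node.  A binary node can therefore only lose accuracy on trials it wrongly
captures, never on trials it passes down.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = ["NodeSpec", "SSDTModel", "rank_ovr", "build_ssdt", "ssdt_predict"]


@dataclass
class NodeSpec:
    """One tree node: a fitted base classifier plus its routing rule."""

    node_id: int  # 1-based; node 1 is consulted first
    kind: str  # "binary-ovr" or "final-multiclass"
    target_class: object | None
    classifier: object
    cv_accuracy: float


@dataclass
class SSDTModel:
    nodes: list[NodeSpec]
    classes: np.ndarray
    base_kind: str = ""
    ranking: list[tuple[object, float]] = field(default_factory=list)


def _select(X, idx):
    return np.asarray(X)[idx]


def _binary_labels(y: np.ndarray, target) -> np.ndarray:
    return np.where(y == target, 1, 0)


def _cv_accuracy(X, y, base_factory, folds: int, seed: int) -> float:
    """Stratified k-fold CV accuracy of a freshly built base classifier."""
    y = np.asarray(y)
    min_count = np.bincount(np.unique(y, return_inverse=True)[1]).min()
    if min_count < folds:
        warnings.warn(
            f"smallest class has {min_count} trials; reducing folds from "
            f"{folds} to {min_count}"
        )
        folds = max(int(min_count), 2)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(np.zeros(len(y)), y):
        clf = base_factory()
        clf.fit(_select(X, tr), y[tr])
        correct += int(np.sum(clf.predict(_select(X, te)) == y[te]))
    return correct / len(y)


def rank_ovr(
    X,
    labels,
    base_factory: Callable[[], object],
    folds: int = 10,
    seed: int = 0,
) -> list[tuple[object, float]]:
    """Rank classes by one-vs-rest cross-validated separability.

    For each class the base classifier is scored on the binary problem
    "class vs pooled rest" by stratified k-fold CV (plain accuracy, natural
    class imbalance kept).  Returns ``(class, cv_accuracy)`` pairs sorted by
    descending accuracy; ties keep class order.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    scores = []
    for c in classes:
        acc = _cv_accuracy(X, _binary_labels(y, c), base_factory, folds, seed)
        scores.append((c, acc))
    # stable sort on -accuracy keeps class order among ties
    order = sorted(range(len(scores)), key=lambda i: (-scores[i][1], i))
    return [scores[i] for i in order]


def build_ssdt(
    X,
    labels,
    base_factory: Callable[[], object],
    folds: int = 10,
    seed: int = 0,
    final_all_classes: bool = True,
    exclude_previous_targets: bool = True,
    base_kind: str = "",
) -> SSDTModel:
    """Build and fit the subject-specific decision tree.

    For C >= 3 classes: ``max(C - 2, 1)`` binary one-vs-rest nodes are chained
    in ranking order (two nodes for four classes, one for three), each trained
    as "target vs pooled rest"; by default the training pool of node i
    excludes the targets of nodes < i, which can no longer reach it correctly.
    The final node is a multiclass classifier over all C classes by default,
    so trials leaked past the binary nodes are still recoverable
    (``final_all_classes=False`` restricts it to the remaining classes).

    C = 2 degenerates to the base classifier alone, with a warning.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    C = classes.size
    if C < 2:
        raise ValueError("need at least two classes")
    if C == 2:
        warnings.warn("two-class problem: SSDT degenerates to the base classifier")
        clf = base_factory()
        clf.fit(X, y)
        node = NodeSpec(1, "final-multiclass", None, clf, float("nan"))
        return SSDTModel(nodes=[node], classes=classes, base_kind=base_kind)

    ranking = rank_ovr(X, y, base_factory, folds=folds, seed=seed)
    n_binary = max(C - 2, 1)
    nodes: list[NodeSpec] = []
    excluded: list[object] = []
    Xa = np.asarray(X)
    for i in range(n_binary):
        target, cv_acc = ranking[i]
        if exclude_previous_targets and excluded:
            keep = ~np.isin(y, excluded)
        else:
            keep = np.ones(len(y), dtype=bool)
        clf = base_factory()
        clf.fit(Xa[keep], _binary_labels(y[keep], target))
        nodes.append(NodeSpec(i + 1, "binary-ovr", target, clf, cv_acc))
        excluded.append(target)
        logger.info("SSDT node %d: class %r (cv accuracy %.3f)", i + 1, target, cv_acc)

    if final_all_classes:
        keep = np.ones(len(y), dtype=bool)
    else:
        keep = ~np.isin(y, excluded)
    final = base_factory()
    final.fit(Xa[keep], y[keep])
    nodes.append(NodeSpec(n_binary + 1, "final-multiclass", None, final, float("nan")))
    return SSDTModel(nodes=nodes, classes=classes, base_kind=base_kind, ranking=ranking)


def ssdt_predict(model: SSDTModel, X) -> np.ndarray:
    """Route samples through the tree.

    At each binary node, samples classified as the node's target class take
    that label and stop; everything else continues.  The final node's
    multiclass decision is returned as-is.  Accepts a single sample or a
    stack; routing is deterministic given the fitted model.
    """
    Xa = np.asarray(X)
    single = _is_single_sample(model, Xa)
    if single:
        Xa = Xa[None]
    n = Xa.shape[0]
    out = np.empty(n, dtype=model.classes.dtype)
    remaining = np.arange(n)
    for node in model.nodes[:-1]:
        if remaining.size == 0:
            break
        pred = np.asarray(node.classifier.predict(Xa[remaining]))
        captured = pred == 1
        out[remaining[captured]] = node.target_class
        remaining = remaining[~captured]
    if remaining.size:
        out[remaining] = np.asarray(model.nodes[-1].classifier.predict(Xa[remaining]))
    return out[0] if single else out


def _is_single_sample(model: SSDTModel, Xa: np.ndarray) -> bool:
    """A single covariance is (n, n); a single feature vector is (d,).

    Estimators advertise their per-sample rank through a ``sample_ndim``
    attribute (2 for covariance matrices, 1 for feature vectors); absent
    that, rank 3 input is taken to be a stack of matrices.
    """
    clf = model.nodes[-1].classifier
    sample_ndim = getattr(clf, "sample_ndim", None)
    if sample_ndim is not None:
        return Xa.ndim == sample_ndim
    return Xa.ndim < 3 and not (Xa.ndim == 2 and Xa.shape[0] != Xa.shape[1])
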