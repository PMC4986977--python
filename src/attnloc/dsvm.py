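"""Dendrogram multi-class SVM (DSVM) and the binary attended classifier.

The multi-class decoder descends a binary decision tree whose topology is
obtained by ascending (agglomerative) hierarchical clustering of the class
centroids — Ward linkage on Euclidean distances between class means of the
standardized training features.  A binary SVM sits at each internal node,
trained on the training samples of that node's class subset, labeled by
which side of the split their class falls on.  Prediction walks from the
root to a leaf, one binary decision per node (≤ n_classes − 1 evaluations).

"Quadratic SVM" is realized as an inhomogeneous degree-2 polynomial kernel
(gamma = 1/n_features, coef0 = 1, C = 1); an RBF kernel is available via
:class:`DSVMConfig`.  Feature standardization (zero mean, unit variance) is
fitted on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass(frozen=True)
class DSVMConfig:
    """Kernel and regularization settings shared by all node SVMs."""

    kernel: str = "poly"          # "poly" (degree 2) or "rbf"
    degree: int = 2
    C: float = 1.0
    coef0: float = 1.0
    linkage_method: str = "ward"
    #: imbalance handling for the binary attended task
    class_weight: str | None = "balanced"

    def make_svc(self, n_features: int, class_weight=None) -> SVC:
        return SVC(
            kernel=self.kernel,
            degree=self.degree,
            C=self.C,
            coef0=self.coef0,
            gamma=1.0 / n_features,
            class_weight=class_weight,
        )


@dataclass
class DendrogramTree:
    """Binary node over a class subset; leaves hold a single class."""

    classes: tuple[int, ...]
    left: "DendrogramTree | None" = None
    right: "DendrogramTree | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def internal_nodes(self) -> list["DendrogramTree"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()

    def splits(self) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
        """(left classes, right classes) per internal node, root first."""
        return [(n.left.classes, n.right.classes)
                for n in self.internal_nodes()]

    def validate(self) -> None:
        if self.is_leaf:
            if len(self.classes) != 1:
                raise ValueError("leaf must hold exactly one class")
            return
        if set(self.left.classes) | set(self.right.classes) != set(self.classes):
            raise ValueError("child subsets must partition the node's classes")
        if set(self.left.classes) & set(self.right.classes):
            raise ValueError("child subsets overlap")
        self.left.validate()
        self.right.validate()


def build_dendrogram(
    X: np.ndarray,
    y: np.ndarray,
    config: DSVMConfig | None = None,
) -> DendrogramTree:
    """Cluster class centroids agglomeratively into a binary decision tree.

    Features are standardized, class centroids computed, and Ward linkage
    applied.  Exact distance ties are broken lowest-class-index-first (the
    linkage is fed classes in ascending label order and SciPy merges the
    earliest minimal pair).  Deterministic given the inputs.
    """
    config = config or DSVMConfig()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    centroids = np.vstack([Xs[y == c].mean(axis=0) for c in classes])
    if not np.all(np.isfinite(centroids)):
        raise ValueError("non-finite class centroid")

    if len(classes) == 2:
        return DendrogramTree(
            classes=tuple(int(c) for c in classes),
            left=DendrogramTree((int(classes[0]),)),
            right=DendrogramTree((int(classes[1]),)),
        )

    Z = linkage(centroids, method=config.linkage_method)
    nodes: dict[int, DendrogramTree] = {
        i: DendrogramTree((int(c),)) for i, c in enumerate(classes)
    }
    for k, (a, b, _, _) in enumerate(Z):
        left, right = nodes[int(a)], nodes[int(b)]
        # present the lower smallest-class side first for a stable layout
        if min(right.classes) < min(left.classes):
            left, right = right, left
        nodes[len(classes) + k] = DendrogramTree(
            classes=tuple(sorted(left.classes + right.classes)),
            left=left, right=right,
        )
    root = nodes[len(classes) + len(Z) - 1]
    root.validate()
    return root


@dataclass
class TrainedDSVM:
    """Fitted dendrogram SVM: tree, per-node SVMs, and the feature scaler."""

    tree: DendrogramTree
    scaler: StandardScaler
    node_svms: list[SVC]          # aligned with tree.internal_nodes()
    config: DSVMConfig = field(default_factory=DSVMConfig)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


def train(
    tree: DendrogramTree,
    X: np.ndarray,
    y: np.ndarray,
    config: DSVMConfig | None = None,
) -> TrainedDSVM:
    """Fit one binary SVM per internal node of ``tree``.

    Each node's SVM sees only the training samples whose class belongs to
    the node's subset, labeled 0 for the left side and 1 for the right.
    """
    config = config or DSVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    svms = []
    for node in tree.internal_nodes():
        mask = np.isin(y, node.classes)
        side = np.isin(y[mask], node.right.classes).astype(int)
        if len(np.unique(side)) < 2:
            missing = "right" if side.sum() == 0 else "left"
            raise ValueError(
                f"no training samples on the {missing} side of node "
                f"{node.classes}")
        svm = config.make_svc(X.shape[1])
        svm.fit(Xs[mask], side)
        svms.append(svm)
    return TrainedDSVM(tree=tree, scaler=scaler, node_svms=svms, config=config)


def fit_dsvm(
    X: np.ndarray, y: np.ndarray, config: DSVMConfig | None = None
) -> TrainedDSVM:
    """Convenience: build the dendrogram and train the node SVMs."""
    tree = build_dendrogram(X, y, config)
    return train(tree, X, y, config)


def predict(model: TrainedDSVM, X: np.ndarray) -> np.ndarray:
    """Descend the tree from the root, one binary decision per node.

    Samples are routed in batch: each internal node classifies every sample
    that reached it, so any single sample sees at most n_classes − 1 SVMs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.scaler.mean_.shape[0]:
        raise ValueError(
            f"expected {model.scaler.mean_.shape[0]} features, "
            f"got {X.shape[1]}")
    Xs = model.scaler.transform(X)
    svm_of = {id(n): s for n, s in zip(model.tree.internal_nodes(),
                                       model.node_svms)}
    out = np.empty(len(Xs), dtype=int)

    def route(node: DendrogramTree, idx: np.ndarray) -> None:
        if len(idx) == 0:
            return
        if node.is_leaf:
            out[idx] = node.classes[0]
            return
        side = svm_of[id(node)].predict(Xs[idx])
        route(node.left, idx[side == 0])
        route(node.right, idx[side == 1])

    route(model.tree, np.arange(len(Xs)))
    return out


@dataclass
class TrainedBinarySVM:
    """Fitted attended-vs-unattended classifier."""

    scaler: StandardScaler
    svm: SVC

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svm.predict(self.scaler.transform(np.atleast_2d(X)))


def train_binary_attended(
    X: np.ndarray,
    attended: np.ndarray,
    config: DSVMConfig | None = None,
) -> TrainedBinarySVM:
    """Quadratic SVM for the attended/unattended task.

    The design yields a 1:3 attended:unattended imbalance; the default
    handling is inverse-frequency class weights.
    """
    config = config or DSVMConfig()
    attended = np.asarray(attended).astype(int)
    if len(np.unique(attended)) < 2:
        raise ValueError("both attended and unattended samples are required")
    X = np.asarray(X, dtype=float)
    scaler = StandardScaler().fit(X)
    svm = config.make_svc(X.shape[1], class_weight=config.class_weight)
    svm.fit(scaler.transform(X), attended)
    return TrainedBinarySVM(scaler=scaler, svm=svm)
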