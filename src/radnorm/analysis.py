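"""Downstream analyses of NRAD sets.

Group averaging with bootstrap confidence bands, classical multidimensional
scaling (cMDS) ordination, complete-linkage hierarchical clustering with
Newick export, and random-forest classification of NRADs evaluated with
accuracy and the chance-corrected kappa statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .distance import DistanceMatrix
from .normalize import NRAD

__all__ = [
    "GroupAverageNRAD",
    "OrdinationResult",
    "ClusterResult",
    "ClassifierReport",
    "average_nrads",
    "cmds",
    "hierarchical_cluster",
    "kappa",
    "classify_nrads",
    "oob_permutation_importance",
]


@dataclass(frozen=True)
class GroupAverageNRAD:
    """Rank-wise mean of a group of NRADs with bootstrap 90% CI bands.

    NRADs are closed under averaging: the mean of normalized, sorted vectors
    is itself normalized and sorted, so the mean can be treated as an NRAD
    with the same MaxRank.
    """

    group: str
    mean: NRAD
    n_members: int


def average_nrads(nrads, n_boot: int = 1000, seed=None, group: str = "") -> GroupAverageNRAD:
    """Average a group of NRADs sharing one R; CIs from member bootstrap.

    The 90% band per rank is the 5%/95% percentile interval of the rank-wise
    means of ``n_boot`` bootstrap resamples of the group members.
    """
    nrads = list(nrads)
    if not nrads:
        raise ValueError("cannot average an empty group")
    Rs = {n.R for n in nrads}
    if len(Rs) > 1:
        raise ValueError(f"incompatible MaxRank values in group: {sorted(Rs)}")
    X = np.vstack([n.abundances for n in nrads])
    mean = X.mean(axis=0)
    if len(nrads) == 1:
        lo, hi = mean.copy(), mean.copy()
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        idx = rng.integers(0, len(nrads), size=(n_boot, len(nrads)))
        boots = X[idx].mean(axis=1)
        lo, hi = np.percentile(boots, [5.0, 95.0], axis=0)
        lo = np.minimum(lo, mean)
        hi = np.maximum(hi, mean)
    nrad = NRAD(mean, lo, hi, n_reps=n_boot, seed=None, label=group or "group-mean")
    return GroupAverageNRAD(group=group, mean=nrad, n_members=len(nrads))


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k
    eigenvalues: np.ndarray    # all eigenvalues, descending
    explained_fraction: float  # top-k positive over all positive eigenvalues


def cmds(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical MDS (principal coordinates) of a distance matrix.

    Eigendecomposition of the double-centered squared-distance matrix; the
    embedding uses the top-k positive eigenvalues.  The explained fraction is
    the sum of the top-k positive eigenvalues over the sum of all positive
    eigenvalues (negative eigenvalues, the non-Euclidean residual, are
    excluded from the denominator).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = dm.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    n_pos = int((eigvals > tol).sum())
    if n_pos == 0:
        coords = np.zeros((n, k))
        explained = 1.0
    else:
        if k > n_pos:
            warnings.warn(
                f"requested {k} dimensions but only {n_pos} positive eigenvalues; reducing k"
            )
            k = n_pos
        coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
        explained = float(eigvals[:k].sum() / eigvals[:n_pos].sum())
    frame = pd.DataFrame(
        coords, index=list(dm.labels),
        columns=[f"coord{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(coordinates=frame, eigenvalues=eigvals, explained_fraction=explained)


@dataclass(frozen=True)
class ClusterResult:
    labels: tuple
    linkage_matrix: np.ndarray  # scipy hierarchy format
    method: str

    def to_newick(self) -> str:
        """Newick string; branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return walk(tree, tree.dist) + ";"


def hierarchical_cluster(dm: DistanceMatrix, linkage: str = "complete") -> ClusterResult:
    """Agglomerative clustering of a distance matrix (complete linkage default)."""
    if len(dm) < 2:
        raise ValueError("clustering needs at least two samples")
    Z = hierarchy.linkage(dm.condensed(), method=linkage)
    return ClusterResult(labels=dm.labels, linkage_matrix=Z, method=linkage)


def kappa(n_correct: int, N: int, n_pred, n_true) -> float:
    """Chance-corrected accuracy kappa = (ACC - ACC_exp) / (1 - ACC_exp).

    ACC_exp is the accuracy expected from guessing at the model's marginal
    prediction rates: sum over classes of (n_pred_c / N) * (n_true_c / N).
    Equals Cohen's kappa on the corresponding confusion table.
    """
    n_pred = np.asarray(n_pred, dtype=float)
    n_true = np.asarray(n_true, dtype=float)
    if N <= 0:
        raise ValueError("N must be positive")
    if n_pred.sum() != N or n_true.sum() != N:
        raise ValueError("marginals must each sum to N")
    acc = n_correct / N
    acc_exp = float((n_pred / N) @ (n_true / N))
    if acc_exp >= 1.0:
        raise ValueError("degenerate marginals: expected accuracy is 1, kappa undefined")
    return float((acc - acc_exp) / (1.0 - acc_exp))


@dataclass(frozen=True)
class ClassifierReport:
    acc: float
    acc_se: float
    kappa: float
    kappa_se: float
    importance: np.ndarray       # per-rank mean decrease in accuracy
    fold_assignments: np.ndarray
    classes: tuple
    seed: int | None
    n_folds: int


def oob_permutation_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    seed: int | None = None,
) -> np.ndarray:
    """Per-feature mean decrease in out-of-bag accuracy of a bagged forest.

    Classic random-forest permutation importance: each tree is grown on a
    bootstrap sample (sqrt-subsampled features per split) and scored on its
    own out-of-bag samples before and after permuting one feature; the drop
    in accuracy is averaged over all trees.  Tree-level averaging makes this
    estimator far less noisy than permuting features of a single model on one
    held-out set, especially when many informative features are correlated.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    importance = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31))
        )
        tree.fit(X[boot], y[boot])
        X_oob = X[oob]
        base = (tree.predict(X_oob) == y[oob]).mean()
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]  # -2 marks leaves
        for j in used:
            X_perm = X_oob.copy()
            X_perm[:, j] = X_perm[rng.permutation(oob.size), j]
            importance[j] += base - (tree.predict(X_perm) == y[oob]).mean()
    # features a tree never used contribute zero decrease for that tree
    return importance / n_trees


def classify_nrads(
    nrads,
    labels,
    n_folds: int = 3,
    n_trees: int = 500,
    seed: int | None = None,
) -> ClassifierReport:
    """Random-forest classification of NRADs with per-rank predictors.

    Stratified k-fold cross-validation: the model is trained on (k-1)/k of
    the data and evaluated on the held-out fold; ACC and kappa are reported
    as mean +/- standard error over folds.  Per-rank importance is the
    out-of-bag permutation importance of a forest grown on the full data
    (see :func:`oob_permutation_importance`).
    """
    nrads = list(nrads)
    y = np.asarray(labels)
    if len(nrads) != y.size:
        raise ValueError("labels must match the number of NRADs")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("classification needs at least two classes")
    Rs = {n.R for n in nrads}
    if len(Rs) > 1:
        raise ValueError(f"incompatible MaxRank values: {sorted(Rs)}")
    X = np.vstack([n.abundances for n in nrads])

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(y.size, dtype=int)
    accs, kappas = [], []
    for fold, (train, test) in enumerate(skf.split(X, y)):
        folds[test] = fold
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=None if seed is None else seed + fold,
            n_jobs=1,
        )
        forest.fit(X[train], y[train])
        pred = forest.predict(X[test])
        n_correct = int((pred == y[test]).sum())
        n_pred = np.array([(pred == c).sum() for c in classes])
        n_true = np.array([(y[test] == c).sum() for c in classes])
        accs.append(n_correct / y[test].size)
        kappas.append(kappa(n_correct, y[test].size, n_pred, n_true))

    importance = oob_permutation_importance(X, y, n_trees=n_trees, seed=seed)
    accs = np.asarray(accs)
    kappas = np.asarray(kappas)
    sqrt_n = np.sqrt(n_folds)
    return ClassifierReport(
        acc=float(accs.mean()), acc_se=float(accs.std(ddof=1) / sqrt_n),
        kappa=float(kappas.mean()), kappa_se=float(kappas.std(ddof=1) / sqrt_n),
        importance=importance,
        fold_assignments=folds, classes=tuple(classes), seed=seed, n_folds=n_folds,
    )
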