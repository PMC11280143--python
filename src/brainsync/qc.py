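"""Injection-site spatial-separability QC.

K-nearest-neighbor classification of 3-D coordinates with stratified
cross-validation; significance of the best cross-validated accuracy is
assessed against a label-shuffled null with the same best-k selection
applied inside every shuffle (so the selection step cannot inflate
significance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

__all__ = ["SeparabilityResult", "knn_separability"]

DEFAULT_K_GRID = tuple(range(1, 16, 2))


@dataclass(frozen=True)
class SeparabilityResult:
    k_grid: tuple
    best_k: int
    cv_accuracy: float
    null_accuracies: np.ndarray
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _cv_accuracy(
    coords: np.ndarray,
    labels: np.ndarray,
    k: int,
    folds: int,
    rng_seed: int,
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    accs = []
    for train, test in skf.split(coords, labels):
        clf = KNeighborsClassifier(n_neighbors=k)
        clf.fit(coords[train], labels[train])
        accs.append(float(np.mean(clf.predict(coords[test]) == labels[test])))
    return float(np.mean(accs))


def _best_k_accuracy(
    coords: np.ndarray,
    labels: np.ndarray,
    k_grid: tuple,
    folds: int,
    rng_seed: int,
) -> tuple[int, float]:
    best_k, best_acc = None, -1.0
    for k in k_grid:  # ties resolve to the smallest k
        acc = _cv_accuracy(coords, labels, k, folds, rng_seed)
        if acc > best_acc:
            best_k, best_acc = k, acc
    return best_k, best_acc


def knn_separability(
    coords: np.ndarray,
    labels: np.ndarray,
    k_grid: tuple = DEFAULT_K_GRID,
    folds: int = 5,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> SeparabilityResult:
    """Cross-validated KNN separability of labeled point clouds.

    ``coords`` is (n, 3) in micrometers; ``labels`` the group per point.
    The p-value is the fraction of label permutations whose best-k accuracy
    is at least the observed one (the observed comparison is inclusive:
    p = #(null >= obs) / n_shuffles).

    Raises for single-class input, classes smaller than the fold count, or
    k values not below the smallest class.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < folds:
        raise ValueError(f"every class needs >= {folds} points for {folds}-fold CV")
    k_grid = tuple(k for k in k_grid if k < counts.min())
    if not k_grid:
        raise ValueError("no k in k_grid is smaller than the minimum class size")

    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2**31 - 1))
    best_k, obs = _best_k_accuracy(coords, labels, k_grid, folds, fold_seed)

    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(labels)
        _, null[s] = _best_k_accuracy(coords, perm, k_grid, folds, fold_seed)
    p = float(np.mean(null >= obs))
    return SeparabilityResult(k_grid, best_k, obs, null, p)
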