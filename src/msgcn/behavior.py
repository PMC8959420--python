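"""Behavior prediction from parcellation topography via Dice-kernel regression.

The premise: subjects with similar parcellation topography perform
similarly, so a test subject's score is a similarity-weighted combination of
training subjects' scores, y ≈ Σ_i Dice(l, l_i) · y_i.  This is made
well-posed as kernel ridge regression in dual form with the mean-Dice
matrix as Gram matrix, scores mean-centered, and the l2 penalty λ chosen by
seeded k-fold cross-validation.  The Dice similarity is an empirical
kernel, not a Mercer kernel, so a small diagonal jitter is added when the
regularized Gram system is not solvable.

A ``raw_weighted_average`` baseline (weights normalized to sum to one, no
fitting) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.model_selection import KFold

from .evaluation import dice_parcellation
from .masked_training import ParcellationMap

__all__ = [
    "BehaviorModel",
    "dice_kernel_matrix",
    "fit_behavior",
    "predict_behavior",
    "evaluate_prediction",
    "raw_weighted_average",
]

_MAX_JITTER = 1e-6


@dataclass
class BehaviorModel:
    training_parcellations: list[ParcellationMap]
    training_scores: np.ndarray
    ridge_lambda: float
    dual_weights: np.ndarray
    score_centering: float
    cv_errors: dict[float, float] = field(default_factory=dict)
    fold_assignments: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")
        if len(self.dual_weights) != len(self.training_parcellations):
            raise ValueError("dual_weights length must equal training set size")


def dice_kernel_matrix(
    maps_a: list[ParcellationMap], maps_b: list[ParcellationMap]
) -> np.ndarray:
    """Mean-Dice similarity matrix between two lists of parcellations."""
    if not maps_a or not maps_b:
        raise ValueError("empty parcellation list")
    k = np.empty((len(maps_a), len(maps_b)))
    same = maps_a is maps_b
    for i, ma in enumerate(maps_a):
        j_start = i if same else 0
        for j in range(j_start, len(maps_b)):
            k[i, j] = dice_parcellation(ma, maps_b[j])[1]
            if same:
                k[j, i] = k[i, j]
    return k


def _solve_dual(gram: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """alpha = (K + lam I)^{-1} y, with bounded jitter for non-PSD Gram."""
    n = gram.shape[0]
    jitter = 0.0
    while True:
        try:
            reg = gram + (lam + jitter) * np.eye(n)
            alpha = np.linalg.solve(reg, y)
            # reject wildly ill-conditioned solves
            if np.isfinite(alpha).all():
                return alpha
        except np.linalg.LinAlgError:
            pass
        jitter = 1e-10 if jitter == 0.0 else jitter * 10.0
        if jitter > _MAX_JITTER:
            raise np.linalg.LinAlgError(
                "Gram matrix is not solvable even with diagonal jitter up to "
                f"{_MAX_JITTER:g}; the Dice kernel is not guaranteed positive "
                "semidefinite — increase the jitter cap or the ridge penalty"
            )


def fit_behavior(
    train_maps: list[ParcellationMap],
    train_scores: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> BehaviorModel:
    """Kernel ridge regression on the Dice kernel with CV-chosen penalty.

    Scores are mean-centered before fitting; λ is the grid value minimizing
    the mean cross-validated squared error over a seeded subject-level
    k-fold split.
    """
    scores = np.asarray(train_scores, dtype=float)
    if len(train_maps) != scores.shape[0]:
        raise ValueError("maps and scores lengths differ")
    if len(train_maps) < n_folds:
        raise ValueError(f"need >= {n_folds} subjects for {n_folds}-fold CV")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if lambda_grid is None:
        lambda_grid = np.logspace(-4, 3, 15)

    center = float(scores.mean())
    y = scores - center
    gram = dice_kernel_matrix(train_maps, train_maps)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(gram))
    fold_assignments = np.empty(len(train_maps), dtype=int)
    for f, (_, test_idx) in enumerate(folds):
        fold_assignments[test_idx] = f

    cv_errors: dict[float, float] = {}
    for lam in lambda_grid:
        sq = []
        for tr, te in folds:
            alpha = _solve_dual(gram[np.ix_(tr, tr)], y[tr], float(lam))
            pred = gram[np.ix_(te, tr)] @ alpha
            sq.append(np.mean((pred - y[te]) ** 2))
        cv_errors[float(lam)] = float(np.mean(sq))
    best_lam = min(cv_errors, key=cv_errors.get)

    alpha = _solve_dual(gram, y, best_lam)
    return BehaviorModel(
        training_parcellations=list(train_maps),
        training_scores=scores,
        ridge_lambda=best_lam,
        dual_weights=alpha,
        score_centering=center,
        cv_errors=cv_errors,
        fold_assignments=fold_assignments,
    )


def predict_behavior(
    model: BehaviorModel, test_maps: list[ParcellationMap]
) -> np.ndarray:
    """score(test) = Σ_i Dice(test, train_i) · α_i + centering offset."""
    n_train = model.training_parcellations[0].n_vertices
    for tm in test_maps:
        if tm.n_vertices != n_train:
            raise ValueError(
                f"test map has {tm.n_vertices} vertices, training maps "
                f"have {n_train}"
            )
    k_test = dice_kernel_matrix(test_maps, model.training_parcellations)
    return k_test @ model.dual_weights + model.score_centering


def raw_weighted_average(
    train_maps: list[ParcellationMap],
    train_scores: np.ndarray,
    test_maps: list[ParcellationMap],
) -> np.ndarray:
    """Baseline: Dice-weighted mean of training scores (weights sum to 1)."""
    scores = np.asarray(train_scores, dtype=float)
    k_test = dice_kernel_matrix(test_maps, train_maps)
    w = k_test / k_test.sum(axis=1, keepdims=True)
    return w @ scores


def evaluate_prediction(
    predicted: np.ndarray, observed: np.ndarray
) -> tuple[float, float]:
    """Pearson r and two-sided p between predicted and measured scores."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed lengths differ")
    r, p = scipy.stats.pearsonr(predicted, observed)
    return float(r), float(p)
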