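"""Turn-key synthetic studies: generate, train, parcellate, evaluate.

Two drivers cover the standard experiments end to end on synthetic cohorts:

* :func:`run_individualization_study` — the core pipeline: a cohort is
  generated, the masked network trained on a train/validation subject split,
  held-out subjects parcellated per session, and the full reliability /
  variability / homogeneity / task-alignment battery computed.
* :func:`run_behavior_study` — topography-linked scores on a larger cohort
  of ground-truth parcellations, Dice-kernel regression on a train split,
  held-out prediction r, and a permutation null.

Both are deterministic given their seeds and are what the example scripts
and the acceptance machinery call.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .behavior import evaluate_prediction, fit_behavior, predict_behavior
from .evaluation import (
    dice_parcellation,
    functional_homogeneity,
    intra_inter_dice,
    task_alignment,
    variability_maps,
)
from .masked_training import ParcellationMap, TrainingConfig
from .pipeline import prepare_cohort, predict_cohort, train_on_cohort
from .synthetic import (
    SyntheticCohort,
    SyntheticCohortConfig,
    make_behavior,
    make_cohort,
    make_group_atlas,
    make_mesh,
    make_subject_truth,
)
from .surface import build_adjacency

logger = logging.getLogger(__name__)

__all__ = [
    "IndividualizationResults",
    "BehaviorResults",
    "run_individualization_study",
    "run_behavior_study",
]


@dataclass
class IndividualizationResults:
    """Everything the core experiment measures on held-out subjects."""

    mask_coverage: float
    dice_truth_atlas: float          # how far subjects deviate from the atlas
    dice_pred_truth: float           # predicted maps vs subject ground truth
    dice_atlas_truth: float          # group atlas vs subject ground truth
    intra_dice_mean: float
    intra_dice_std: float
    inter_dice_mean: float
    inter_dice_std: float
    paired_t_p: float                # intra vs inter, per-subject paired test
    homogeneity_pred: float
    homogeneity_atlas: float
    cohens_d_association: float
    cohens_d_primary: float
    task_variability_pred: float
    task_variability_atlas: float
    history: dict = field(repr=False, default_factory=dict)
    predicted_maps: list = field(repr=False, default_factory=list)
    cohort: SyntheticCohort = field(repr=False, default=None)  # type: ignore


def _paired_intra_inter_p(maps: list[ParcellationMap]) -> float:
    """Two-sided paired t-test of per-subject mean intra vs inter Dice."""
    ids = [m.subject_id for m in maps]
    intra_by: dict[str, list[float]] = {}
    inter_by: dict[str, list[float]] = {}
    for i, j in itertools.combinations(range(len(maps)), 2):
        d = dice_parcellation(maps[i], maps[j])[1]
        if ids[i] == ids[j]:
            intra_by.setdefault(ids[i], []).append(d)
        else:
            inter_by.setdefault(ids[i], []).append(d)
            inter_by.setdefault(ids[j], []).append(d)
    subjects = sorted(set(intra_by) & set(inter_by))
    a = [float(np.mean(intra_by[s])) for s in subjects]
    b = [float(np.mean(inter_by[s])) for s in subjects]
    return float(scipy.stats.ttest_rel(a, b).pvalue)


def run_individualization_study(
    config: SyntheticCohortConfig | None = None,
    n_train: int = 16,
    n_val: int = 4,
    n_test: int = 10,
    training: TrainingConfig | None = None,
) -> IndividualizationResults:
    """Generate a cohort, train the masked network, evaluate held-out subjects.

    Subjects 0..n_train-1 train, the next n_val validate, the last n_test are
    held out entirely.  Held-out subjects are parcellated per session; the
    battery compares those individualized maps against the subjects' ground
    truths, the group atlas, and each other (intra/intersubject Dice,
    per-parcel Cohen's d by parcel class, resting-state homogeneity, and
    task-activation alignment with per-subject piecewise-constant beta maps
    drawn on the ground-truth parcels).
    """
    if config is None:
        config = SyntheticCohortConfig()
    needed = n_train + n_val + n_test
    if config.n_subjects < needed:
        config = SyntheticCohortConfig(
            **{**config.__dict__, "n_subjects": needed}
        )
    if training is None:
        training = TrainingConfig(seed=config.seed)

    logger.info("generating cohort (%d subjects, seed %d)",
                config.n_subjects, config.seed)
    cohort = make_cohort(config, with_behavior=False)
    features = prepare_cohort(cohort)
    atlas_map = ParcellationMap(labels=cohort.atlas.labels)

    train_idx = list(range(n_train))
    val_idx = list(range(n_train, n_train + n_val))
    test_idx = list(range(n_train + n_val, needed))

    logger.info("training on %d subjects, validating on %d", n_train, n_val)
    model, history = train_on_cohort(cohort, features, train_idx, val_idx, training)
    preds = predict_cohort(model, cohort, features, test_idx)
    flat_preds = [pm for group in preds for pm in group]

    dice_pred_truth = float(np.mean([
        dice_parcellation(preds[i][j], cohort.subject_truths[s])[1]
        for i, s in enumerate(test_idx) for j in range(len(preds[i]))
    ]))
    dice_atlas_truth = float(np.mean([
        dice_parcellation(atlas_map, cohort.subject_truths[s])[1]
        for s in test_idx
    ]))
    dice_truth_atlas = float(np.mean([
        dice_parcellation(t, atlas_map)[1] for t in cohort.subject_truths
    ]))

    sim = intra_inter_dice(flat_preds)
    paired_p = _paired_intra_inter_p(flat_preds)

    homog_pred = float(np.mean([
        functional_homogeneity(preds[i][j], cohort.sessions[s][j])[1]
        for i, s in enumerate(test_idx) for j in range(len(preds[i]))
    ]))
    homog_atlas = float(np.mean([
        functional_homogeneity(atlas_map, cohort.sessions[s][j])[1]
        for s in test_idx for j in range(config.n_sessions_per_subject)
    ]))

    vm = variability_maps(flat_preds, cohort.atlas.n_parcels)
    cls = cohort.atlas.parcel_class
    d_assoc = float(np.nanmean(vm.values[cls == "association"]))
    d_primary = float(np.nanmean(vm.values[cls == "primary"]))

    # task alignment: per-subject beta maps piecewise-constant on the truth
    beta_rng = np.random.default_rng(config.seed + 101)
    task_pred, task_atlas = [], []
    for i, s in enumerate(test_idx):
        levels = beta_rng.standard_normal(cohort.atlas.n_parcels + 1)
        levels[0] = 0.0
        beta = levels[cohort.subject_truths[s].labels]
        task_pred.append(task_alignment(preds[i][0], beta)[1])
        task_atlas.append(task_alignment(atlas_map, beta)[1])

    return IndividualizationResults(
        mask_coverage=float(np.mean([f.mask.coverage for f in features])),
        dice_truth_atlas=dice_truth_atlas,
        dice_pred_truth=dice_pred_truth,
        dice_atlas_truth=dice_atlas_truth,
        intra_dice_mean=float(sim.intra.mean()),
        intra_dice_std=float(sim.intra.std()),
        inter_dice_mean=float(sim.inter.mean()),
        inter_dice_std=float(sim.inter.std()),
        paired_t_p=paired_p,
        homogeneity_pred=homog_pred,
        homogeneity_atlas=homog_atlas,
        cohens_d_association=d_assoc,
        cohens_d_primary=d_primary,
        task_variability_pred=float(np.mean(task_pred)),
        task_variability_atlas=float(np.mean(task_atlas)),
        history=history,
        predicted_maps=preds,
        cohort=cohort,
    )


@dataclass
class BehaviorResults:
    r_heldout: float
    p_heldout: float
    ridge_lambda: float
    permuted_abs_r_mean: float
    scores: np.ndarray = field(repr=False, default=None)  # type: ignore
    predictions_all: np.ndarray = field(repr=False, default=None)  # type: ignore


def run_behavior_study(
    n_subjects: int = 60,
    n_train: int = 40,
    config: SyntheticCohortConfig | None = None,
    seed: int = 0,
    n_permutations: int = 100,
) -> BehaviorResults:
    """Dice-kernel behavior prediction on ground-truth parcellations.

    Generates ``n_subjects`` subject truths (sessions are not needed), draws
    topography-linked scores, fits kernel ridge regression on the first
    ``n_train`` subjects with 5-fold CV, and reports the held-out Pearson r.
    The permutation null correlates the model's predictions (all subjects)
    with seeded permutations of the observed scores and reports the mean
    absolute r, which should sit near zero when no subject-score link exists.
    """
    if config is None:
        config = SyntheticCohortConfig(seed=seed, behavior_noise=0.0)
    ss = np.random.SeedSequence(config.seed)
    s_atlas, s_subjects, s_behavior = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)
    )
    mesh = make_mesh(config.mesh_subdivisions,
                     medial_wall_angle_deg=config.medial_wall_angle_deg)
    graph = build_adjacency(mesh)
    atlas = make_group_atlas(
        mesh, config.n_parcels, seed=s_atlas,
        association_fraction=config.association_fraction, graph=graph,
    )
    sub_ss = np.random.SeedSequence(s_subjects).spawn(n_subjects)
    truths = [
        make_subject_truth(
            atlas, graph, config,
            subject_seed=int(c.generate_state(1)[0] % (2**31)),
            subject_id=f"sub{i:03d}",
        )
        for i, c in enumerate(sub_ss)
    ]
    scores, _ = make_behavior(truths, atlas, config, seed=s_behavior)

    model = fit_behavior(truths[:n_train], scores[:n_train], seed=seed)
    pred_test = predict_behavior(model, truths[n_train:])
    r, p = evaluate_prediction(pred_test, scores[n_train:])

    pred_all = predict_behavior(model, truths)
    perm_rng = np.random.default_rng(seed + 1)
    abs_rs = [
        abs(evaluate_prediction(pred_all, perm_rng.permutation(scores))[0])
        for _ in range(n_permutations)
    ]
    return BehaviorResults(
        r_heldout=float(r),
        p_heldout=float(p),
        ridge_lambda=float(model.ridge_lambda),
        permuted_abs_r_mean=float(np.mean(abs_rs)),
        scores=scores,
        predictions_all=pred_all,
    )
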