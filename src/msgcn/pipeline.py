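"""End-to-end glue: cohort -> fingerprints -> masks -> training -> maps.

These helpers wire the individual modules into the standard individualized
parcellation workflow so that tests, examples, the CLI and the acceptance
script all run the same path:

1. per-session connectivity fingerprints against the group atlas;
2. similarity-based initial parcellations and the subject confidence mask;
3. confidence-masked training of the two-layer ChebNet on train/validation
   subjects (atlas labels as targets, masked vertices only);
4. per-session individualized parcellation of any subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chebnet import MsgcnModel, init_model
from .masked_training import (
    ConfidenceMask,
    ParcellationMap,
    SubjectData,
    TrainingConfig,
    build_confidence_mask,
    predict_parcellation,
    train,
)
from .signals import (
    GraphSignals,
    GroupAtlas,
    SessionTimeSeries,
    connectivity_fingerprint,
    initial_parcellation,
)
from .synthetic import SyntheticCohort

__all__ = [
    "SubjectFeatures",
    "prepare_subject",
    "prepare_cohort",
    "train_on_cohort",
    "predict_cohort",
]


@dataclass
class SubjectFeatures:
    """Fingerprints, initial parcellations and confidence mask of a subject."""

    subject_id: str
    signals: list[GraphSignals]
    initial_maps: list[ParcellationMap]
    mask: ConfidenceMask


def prepare_subject(
    sessions: list[SessionTimeSeries],
    atlas: GroupAtlas,
    subject_id: str = "",
) -> SubjectFeatures:
    """Fingerprint each session, derive initial maps and the confidence mask."""
    signals, initial_maps = [], []
    for ts in sessions:
        sig = connectivity_fingerprint(ts, atlas)
        signals.append(sig)
        initial_maps.append(initial_parcellation(sig, atlas))
    mask = build_confidence_mask(initial_maps, atlas, subject_id=subject_id)
    return SubjectFeatures(
        subject_id=subject_id, signals=signals, initial_maps=initial_maps,
        mask=mask,
    )


def prepare_cohort(cohort: SyntheticCohort) -> list[SubjectFeatures]:
    return [
        prepare_subject(sessions, cohort.atlas, subject_id=f"sub{s:03d}")
        for s, sessions in enumerate(cohort.sessions)
    ]


def _to_subject_data(
    features: list[SubjectFeatures], atlas: GroupAtlas
) -> list[SubjectData]:
    targets = ParcellationMap(labels=atlas.labels)
    return [
        SubjectData(
            subject_id=f.subject_id, signals=f.signals, mask=f.mask,
            targets=targets,
        )
        for f in features
    ]


def train_on_cohort(
    cohort: SyntheticCohort,
    features: list[SubjectFeatures],
    train_idx: list[int],
    val_idx: list[int],
    config: TrainingConfig,
    model: MsgcnModel | None = None,
) -> tuple[MsgcnModel, dict]:
    """Train the network on the given subject split (indices into features)."""
    if model is None:
        model = init_model(
            n_features=cohort.atlas.n_parcels,
            n_classes=cohort.atlas.n_parcels + 1,
            dropout_rate=config.dropout,
            seed=config.seed,
        )
    data = _to_subject_data(features, cohort.atlas)
    return train(
        model,
        [data[i] for i in train_idx],
        [data[i] for i in val_idx],
        cohort.laplacian.L_scaled,
        config,
    )


def predict_cohort(
    model: MsgcnModel,
    cohort: SyntheticCohort,
    features: list[SubjectFeatures],
    subject_idx: list[int] | None = None,
) -> list[list[ParcellationMap]]:
    """Per-session individualized maps for the selected subjects."""
    if subject_idx is None:
        subject_idx = list(range(len(features)))
    out = []
    for s in subject_idx:
        f = features[s]
        out.append(
            [
                predict_parcellation(
                    model, sig, cohort.laplacian.L_scaled,
                    subject_id=f.subject_id, session_id=f"ses{j}",
                )
                for j, sig in enumerate(f.signals)
            ]
        )
    return out
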