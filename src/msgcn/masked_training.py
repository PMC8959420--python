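"""Confidence-masked semi-supervised training of the parcellation network.

The group atlas supplies labels, but only at vertices where a subject's own
data agree with it: the subject-specific *confidence mask* keeps a vertex
iff (1) the similarity-based initial parcellation assigns it a nonzero
label, (2) that label equals the group-atlas label, and (3) the assignment
agrees across every session of the subject.  On real cortical data such a
mask covers roughly half the cortex — vertices near parcel centers — and
leaves border vertices free, which is what lets the trained network express
individual topographic variability.

The training objective is the masked cross-entropy (KL divergence to the
one-hot atlas prior restricted to masked vertices)

    Loss = - sum_n sum_v w_{n,v} log p_{v, y_{n,v}}

minimized with Adam, one subject-session per step, l2 weight decay, and
early stopping on validation loss.  Gradients of the two-layer ChebNet are
computed analytically; Chebyshev operators T_k(L~) are symmetric, which
makes the backward pass a mirror of the forward recurrence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .chebnet import MsgcnModel, ProbabilityMap, chebyshev_basis, forward
from .signals import GraphSignals, GroupAtlas

logger = logging.getLogger(__name__)

__all__ = [
    "ParcellationMap",
    "ConfidenceMask",
    "TrainingConfig",
    "SubjectData",
    "build_confidence_mask",
    "masked_kl_loss",
    "train",
    "predict_parcellation",
]

_PROB_FLOOR = 1e-12


@dataclass
class ParcellationMap:
    """Per-vertex integer labels in {0..K}; 0 = unassigned/background."""

    labels: np.ndarray
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a vector")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def n_vertices(self) -> int:
        return self.labels.shape[0]


@dataclass
class ConfidenceMask:
    """Binary per-vertex weights w_{n,v} gating the training loss."""

    weights: np.ndarray
    subject_id: str = ""
    coverage: float = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        if not np.isin(self.weights, (0, 1)).all():
            raise ValueError("confidence weights must be binary")
        self.weights = self.weights.astype(np.float64)
        self.coverage = float(self.weights.mean()) if self.weights.size else 0.0


@dataclass
class TrainingConfig:
    epochs: int = 100
    batch_subjects: int = 1
    patience: int = 10
    weight_decay: float = 0.0005
    dropout: float = 0.5
    learning_rate: float = 0.001
    optimizer_name: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience > self.epochs:
            raise ValueError("patience must be <= epochs")
        if min(self.weight_decay, self.dropout, self.learning_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.optimizer_name != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer_name!r}")


@dataclass
class SubjectData:
    """Everything training needs for one subject: per-session node features,
    one confidence mask shared by the sessions, and atlas-derived targets."""

    subject_id: str
    signals: list[GraphSignals]
    mask: ConfidenceMask
    targets: ParcellationMap


def build_confidence_mask(
    session_initial_parcellations: list[ParcellationMap],
    atlas: GroupAtlas,
    subject_id: str = "",
) -> ConfidenceMask:
    """Three-step confidence mask from per-session initial parcellations.

    weight(v) = 1 iff in *every* session the initial label at v is nonzero
    and equals the group-atlas label at v (which also forces cross-session
    agreement); else 0.
    """
    if not session_initial_parcellations:
        raise ValueError("need at least one session's initial parcellation")
    ref = atlas.labels
    keep = ref > 0
    for pm in session_initial_parcellations:
        if pm.n_vertices != atlas.n_vertices:
            raise ValueError("parcellation/atlas vertex counts differ")
        keep = keep & (pm.labels > 0) & (pm.labels == ref)
    mask = ConfidenceMask(weights=keep.astype(float), subject_id=subject_id)
    logger.info(
        "confidence mask for subject %r: coverage %.3f",
        subject_id,
        mask.coverage,
    )
    return mask


def masked_kl_loss(
    probs: ProbabilityMap, targets: ParcellationMap, mask: ConfidenceMask
) -> float:
    """Masked negative log-likelihood  -sum_v w_v log p_{v, y_v}.

    Probabilities are floored at 1e-12 before the log, so the value is
    always finite and nonnegative.  Masked vertices must carry a nonzero
    target label.
    """
    p = probs.P
    y = targets.labels
    w = mask.weights
    if not (p.shape[0] == y.shape[0] == w.shape[0]):
        raise ValueError("probs/targets/mask vertex counts differ")
    if y.max(initial=0) >= p.shape[1]:
        raise ValueError("target label exceeds class count")
    masked = w > 0
    if not masked.any():
        return 0.0
    if (y[masked] == 0).any():
        raise ValueError(
            "confidence mask includes vertices with label 0; the mask must "
            "exclude unassigned vertices"
        )
    picked = p[masked, y[masked]]
    return float(-np.sum(np.log(np.maximum(picked, _PROB_FLOOR))))


def _loss_and_grads(
    model: MsgcnModel,
    L_scaled: sp.spmatrix,
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    rng: np.random.Generator,
    training: bool = True,
):
    """Mean masked cross-entropy and analytic gradients for the 2-layer net.

    Backward uses the symmetry of T_k(L~): the adjoint of Y = T_k X theta_k
    in X is T_k (dY theta_k^T).
    """
    _, cache = forward(
        model, L_scaled, X, training=training, rng=rng, return_cache=True
    )
    p = cache["P"]
    masked = w > 0
    m = int(masked.sum())
    if m == 0:
        return 0.0, None
    picked = p[masked, y[masked]]
    loss = float(-np.mean(np.log(np.maximum(picked, _PROB_FLOOR))))

    l1, l2 = model.layers
    n = X.shape[0]
    # d loss / d z2 for softmax + masked mean NLL
    dz2 = p.copy()
    dz2[np.arange(n), y] -= 1.0
    dz2 *= (w / m)[:, None]

    g2_theta = np.stack(
        [cache["basis2"][k].T @ dz2 for k in range(l2.order + 1)]
    )
    g2_bias = dz2.sum(axis=0) if l2.bias is not None else None

    # adjoint through layer-2 convolution back to the hidden features
    dh = np.zeros_like(cache["h_d"])
    back = chebyshev_basis(L_scaled, dz2, l2.order)
    for k in range(l2.order + 1):
        dh += back[k] @ l2.theta[k].T
    if cache["drop_mask"] is not None:
        dh *= cache["drop_mask"]
    dz1 = dh * (cache["z1"] > 0)

    g1_theta = np.stack(
        [cache["basis1"][k].T @ dz1 for k in range(l1.order + 1)]
    )
    g1_bias = dz1.sum(axis=0) if l1.bias is not None else None
    return loss, [(g1_theta, g1_bias), (g2_theta, g2_bias)]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _flatten_params(model: MsgcnModel) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for layer in model.layers:
        out.append(layer.theta)
        if layer.bias is not None:
            out.append(layer.bias)
    return out


def _mean_val_loss(
    model: MsgcnModel,
    L_scaled: sp.spmatrix,
    subjects: list[SubjectData],
) -> float:
    losses = []
    for sub in subjects:
        masked = sub.mask.weights > 0
        m = max(int(masked.sum()), 1)
        for sig in sub.signals:
            probs = forward(model, L_scaled, sig.X, training=False)
            losses.append(
                masked_kl_loss(probs, sub.targets, sub.mask) / m
            )
    return float(np.mean(losses))


def train(
    model: MsgcnModel,
    train_subjects: list[SubjectData],
    val_subjects: list[SubjectData],
    L_scaled: sp.spmatrix,
    config: TrainingConfig,
):
    """Train with one subject-session per optimizer step and early stopping.

    Per epoch, subject-sessions are visited in a seeded shuffled order; the
    objective per step is the mean masked cross-entropy of that session plus
    l2 weight decay.  Validation loss (mean masked cross-entropy over all
    validation sessions) is tracked each epoch; training stops once it fails
    to improve for ``config.patience`` epochs, and the parameters of the
    best validation epoch are returned.  Fully reproducible from
    ``config.seed``.

    Returns ``(best_model, history)`` where history has per-epoch
    ``train_loss`` / ``val_loss`` lists and ``best_epoch`` (1-based).
    """
    if not train_subjects:
        raise ValueError("empty training set")
    if not val_subjects:
        raise ValueError("empty validation set")
    for sub in train_subjects:
        if (sub.mask.weights > 0).sum() == 0:
            raise ValueError(f"subject {sub.subject_id!r} has an empty mask")

    model = model.copy()
    model.dropout_rate = config.dropout
    rng = np.random.default_rng(config.seed)
    params = _flatten_params(model)
    opt = _Adam(params, lr=config.learning_rate)

    samples = [
        (si, ki) for si, sub in enumerate(train_subjects)
        for ki in range(len(sub.signals))
    ]
    history = {"train_loss": [], "val_loss": [], "best_epoch": 0}
    best_val = np.inf
    best_state = [p.copy() for p in params]
    stall = 0

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(samples))
        epoch_losses = []
        for idx in order:
            si, ki = samples[idx]
            sub = train_subjects[si]
            loss, grads = _loss_and_grads(
                model,
                L_scaled,
                sub.signals[ki].X,
                sub.targets.labels,
                sub.mask.weights,
                rng=rng,
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, subject "
                    f"{sub.subject_id!r} session {ki}"
                )
            if grads is None:
                continue
            flat_grads: list[np.ndarray] = []
            for (g_theta, g_bias), layer in zip(grads, model.layers):
                flat_grads.append(g_theta + config.weight_decay * layer.theta)
                if layer.bias is not None:
                    flat_grads.append(g_bias)
            opt.step(params, flat_grads)
            epoch_losses.append(loss)

        val_loss = _mean_val_loss(model, L_scaled, val_subjects)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        logger.info(
            "epoch %d: train %.4f  val %.4f", epoch,
            history["train_loss"][-1], val_loss,
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = [p.copy() for p in params]
            history["best_epoch"] = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                logger.info("early stopping at epoch %d", epoch)
                break

    for p, b in zip(params, best_state):
        p[...] = b
    return model, history


def predict_parcellation(
    model: MsgcnModel,
    signals: GraphSignals,
    L_scaled: sp.spmatrix,
    subject_id: str = "",
    session_id: str = "",
) -> ParcellationMap:
    """Individualized parcellation: argmax class per vertex (0 = background).

    Ties break to the lowest class index.  Deterministic (no dropout).
    """
    if signals.n_features != model.n_features:
        raise ValueError(
            f"signals have {signals.n_features} features, model expects "
            f"{model.n_features}"
        )
    probs = forward(model, L_scaled, signals.X, training=False)
    labels = np.argmax(probs.P, axis=1)
    return ParcellationMap(
        labels=labels, subject_id=subject_id, session_id=session_id
    )
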