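"""Chebyshev spectral graph convolutions and the two-layer parcellation net.

A ChebNet layer filters node features X with a truncated Chebyshev expansion
of the rescaled Laplacian,

    Y = sum_{k=0..K} T_k(L~) X theta_k  (+ bias),

where T_0 = I, T_1 = L~, T_k = 2 L~ T_{k-1} - T_{k-2}.  Because T_k(L~) is a
degree-k polynomial in L~, a K-order layer is exactly K-hop localized on the
graph.  The default network stacks two third-order layers (F -> 64 -> K+1)
with a rectifier in between, dropout on the hidden features during training,
and a row-wise softmax that yields per-vertex parcel probabilities.

Everything here is plain NumPy over SciPy sparse operators; the backward
pass for training lives in :mod:`msgcn.masked_training`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph

__all__ = [
    "ChebLayerParams",
    "MsgcnModel",
    "ProbabilityMap",
    "chebyshev_basis",
    "cheb_conv",
    "forward",
    "receptive_field_check",
    "init_model",
]


@dataclass
class ChebLayerParams:
    """Parameters of one K-order Chebyshev convolution layer.

    theta has shape (K+1, n_in, n_out); bias is (n_out,) or None.
    """

    order: int
    theta: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 3 or self.theta.shape[0] != self.order + 1:
            raise ValueError(
                f"theta must be (order+1={self.order + 1}, n_in, n_out), "
                f"got {self.theta.shape}"
            )
        if not np.isfinite(self.theta).all():
            raise ValueError("theta contains non-finite entries")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=float)
            if self.bias.shape != (self.theta.shape[2],):
                raise ValueError("bias length must equal n_out")

    @property
    def n_in(self) -> int:
        return self.theta.shape[1]

    @property
    def n_out(self) -> int:
        return self.theta.shape[2]


@dataclass
class MsgcnModel:
    """Stacked ChebNet producing per-vertex class probabilities.

    Class 0 is the background/unassigned class; classes 1..K are parcels, so
    n_classes = n_parcels + 1.
    """

    layers: list[ChebLayerParams]
    dropout_rate: float = 0.5
    activation: str = "relu"

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("model needs at least one layer")
        for a, b in zip(self.layers, self.layers[1:]):
            if a.n_out != b.n_in:
                raise ValueError(
                    f"layer dimension mismatch: {a.n_out} -> {b.n_in}"
                )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")

    @property
    def n_features(self) -> int:
        return self.layers[0].n_in

    @property
    def n_classes(self) -> int:
        return self.layers[-1].n_out

    def copy(self) -> "MsgcnModel":
        return MsgcnModel(
            layers=[
                ChebLayerParams(
                    order=l.order,
                    theta=l.theta.copy(),
                    bias=None if l.bias is None else l.bias.copy(),
                )
                for l in self.layers
            ],
            dropout_rate=self.dropout_rate,
            activation=self.activation,
        )


@dataclass
class ProbabilityMap:
    """Per-vertex class probabilities p_{v,k}; rows sum to 1."""

    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2:
            raise ValueError("P must be 2-D")
        if (self.P < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")


def init_model(
    n_features: int,
    n_classes: int,
    hidden: int = 64,
    order: int = 3,
    dropout_rate: float = 0.5,
    use_bias: bool = True,
    seed: int = 0,
) -> MsgcnModel:
    """Seeded fan-in-scaled random initialization of the two-layer network."""
    rng = np.random.default_rng(seed)
    layers = []
    for n_in, n_out in [(n_features, hidden), (hidden, n_classes)]:
        scale = np.sqrt(1.0 / (n_in * (order + 1)))
        theta = rng.normal(0.0, scale, size=(order + 1, n_in, n_out))
        bias = np.zeros(n_out) if use_bias else None
        layers.append(ChebLayerParams(order=order, theta=theta, bias=bias))
    return MsgcnModel(layers=layers, dropout_rate=dropout_rate)


def chebyshev_basis(
    L_scaled: sp.spmatrix, X: np.ndarray, order: int
) -> list[np.ndarray]:
    """[T_0(L~)X, ..., T_K(L~)X] via the three-term recurrence.

    Only sparse matrix–dense matrix products are used, so cost is
    O(K · nnz(L~) · F).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if L_scaled.shape[0] != L_scaled.shape[1]:
        raise ValueError("L_scaled must be square")
    if L_scaled.shape[0] != X.shape[0]:
        raise ValueError(
            f"L_scaled is {L_scaled.shape[0]}x{L_scaled.shape[1]} but X has "
            f"{X.shape[0]} rows"
        )
    if order < 0:
        raise ValueError("order must be >= 0")
    terms = [X]
    if order >= 1:
        terms.append(L_scaled @ X)
    for _ in range(2, order + 1):
        terms.append(2.0 * (L_scaled @ terms[-1]) - terms[-2])
    return terms


def cheb_conv(
    layer: ChebLayerParams,
    L_scaled: sp.spmatrix,
    X: np.ndarray,
    basis: list[np.ndarray] | None = None,
) -> np.ndarray:
    """One Chebyshev graph convolution: Y = sum_k T_k(L~) X theta_k (+ bias).

    A precomputed ``basis`` (from :func:`chebyshev_basis`) may be passed to
    avoid recomputation when the same X is filtered repeatedly.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != layer.n_in:
        raise ValueError(
            f"X has {X.shape[1]} features but theta expects {layer.n_in}"
        )
    if basis is None:
        basis = chebyshev_basis(L_scaled, X, layer.order)
    y = np.zeros((X.shape[0], layer.n_out))
    for k in range(layer.order + 1):
        y += basis[k] @ layer.theta[k]
    if layer.bias is not None:
        y += layer.bias
    return y


def softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(
    model: MsgcnModel,
    L_scaled: sp.spmatrix,
    X: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Full forward pass: conv -> relu -> dropout -> conv -> softmax.

    Dropout is applied to the hidden features only when ``training`` is True
    (inverted dropout, so inference needs no rescaling); inference is fully
    deterministic.  With ``return_cache`` the intermediates needed for
    backprop are returned alongside the probabilities.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"input has {X.shape[1]} features, model expects {model.n_features}"
        )
    if len(model.layers) != 2:
        raise ValueError("forward supports the standard two-layer network")
    l1, l2 = model.layers

    basis1 = chebyshev_basis(L_scaled, X, l1.order)
    z1 = cheb_conv(l1, L_scaled, X, basis=basis1)
    if not np.isfinite(z1).all():
        raise FloatingPointError("non-finite values after layer 1 convolution")
    h = np.maximum(z1, 0.0)
    if training and model.dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        keep = 1.0 - model.dropout_rate
        drop_mask = (rng.random(h.shape) < keep) / keep
        h_d = h * drop_mask
    else:
        drop_mask = None
        h_d = h
    basis2 = chebyshev_basis(L_scaled, h_d, l2.order)
    z2 = cheb_conv(l2, L_scaled, h_d, basis=basis2)
    if not np.isfinite(z2).all():
        raise FloatingPointError("non-finite values after layer 2 convolution")
    p = softmax_rows(z2)
    prob = ProbabilityMap(P=p)
    if not return_cache:
        return prob
    cache = {
        "basis1": basis1,
        "z1": z1,
        "drop_mask": drop_mask,
        "h_d": h_d,
        "basis2": basis2,
        "P": p,
    }
    return prob, cache


def receptive_field_check(
    model: MsgcnModel,
    L_scaled: sp.spmatrix,
    v: int,
    hops: int,
    X: np.ndarray | None = None,
    seed: int = 0,
    tol: float = 1e-10,
) -> bool:
    """Test K-hop locality: perturb features strictly beyond ``hops`` of v.

    Returns True iff the (dropout-free) output row at vertex v is unchanged
    (max abs difference <= tol) after a random perturbation of every vertex
    whose hop distance from v exceeds ``hops``.  With ``hops`` equal to the
    sum of the layer orders this must always hold.
    """
    rng = np.random.default_rng(seed)
    n = L_scaled.shape[0]
    if X is None:
        X = rng.standard_normal((n, model.n_features))
    # hop distances on the sparsity pattern of L~ (off-diagonal entries)
    pattern = L_scaled.tocsr().copy()
    pattern.setdiag(0)
    pattern.eliminate_zeros()
    dist = csgraph.shortest_path(
        (abs(pattern) > 0).astype(float), method="D", unweighted=True, indices=v
    )
    far = dist > hops
    if not far.any():
        return True
    x_pert = X.copy()
    x_pert[far] += rng.standard_normal((int(far.sum()), model.n_features))
    p0 = forward(model, L_scaled, X, training=False).P[v]
    p1 = forward(model, L_scaled, x_pert, training=False).P[v]
    return bool(np.abs(p0 - p1).max() <= tol)
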