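"""Connectivity-fingerprint graph signals from per-vertex fMRI time series.

A vertex's connectivity fingerprint is its vector of Pearson correlations
with the mean time series of each region of interest (ROI) of a group atlas
(e.g. a few hundred parcels).  Fingerprints are the node features handed to
the graph convolutions, and they also drive the similarity-based initial
parcellation used to seed the subject-specific confidence mask.

Standard rs-fMRI post-processing ahead of the correlation step lives here
too: nuisance regression (white matter / CSF signals) and 0.01–0.1 Hz
band-pass filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

__all__ = [
    "SessionTimeSeries",
    "GroupAtlas",
    "GraphSignals",
    "bandpass_filter",
    "regress_nuisance",
    "connectivity_fingerprint",
    "initial_parcellation",
]


@dataclass
class SessionTimeSeries:
    """Per-vertex BOLD series for one scanning session.

    data is (n_vertices, n_timepoints); tr is the repetition time in seconds.
    """

    data: np.ndarray
    tr: float
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("data must be (n_vertices, n_timepoints>=2)")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contain NaN/inf")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class GroupAtlas:
    """Group-level parcellation: per-vertex labels in {0..K}, 0 = unassigned."""

    labels: np.ndarray
    n_parcels: int | None = None
    parcel_names: list[str] | None = None
    parcel_class: np.ndarray | None = None  # per-parcel tag, e.g. primary/association

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a vector")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if self.n_parcels is None:
            self.n_parcels = int(self.labels.max())
        if self.labels.max() > self.n_parcels:
            raise ValueError(
                f"label {self.labels.max()} exceeds n_parcels {self.n_parcels}"
            )
        present = np.unique(self.labels[self.labels > 0])
        missing = np.setdiff1d(np.arange(1, self.n_parcels + 1), present)
        if missing.size:
            raise ValueError(f"empty parcels: {missing[:10].tolist()}")

    @property
    def n_vertices(self) -> int:
        return self.labels.shape[0]

    def parcel_vertices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)


@dataclass
class GraphSignals:
    """Node-feature matrix X (n_vertices × n_rois) of connectivity fingerprints."""

    X: np.ndarray
    feature_meaning: np.ndarray  # ROI id per column
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.feature_meaning = np.asarray(self.feature_meaning)
        if self.X.shape[1] != self.feature_meaning.shape[0]:
            raise ValueError("feature_meaning length must match X columns")
        if self.zero_variance is None:
            self.zero_variance = np.zeros(self.X.shape[0], dtype=bool)
        self.zero_variance = np.asarray(self.zero_variance, dtype=bool)

    @property
    def n_vertices(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def bandpass_filter(
    ts: SessionTimeSeries, low_hz: float = 0.01, high_hz: float = 0.1, order: int = 4
) -> SessionTimeSeries:
    """Zero-phase Butterworth band-pass of every vertex series.

    The default 0.01–0.1 Hz band isolates the low-frequency fluctuations
    carrying resting-state connectivity.  The output is mean-free (DC sits
    below any valid band).
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy "
            f"0 < low < high < Nyquist ({nyquist:.4f} Hz at tr={ts.tr}s)"
        )
    sos = scipy.signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr, output="sos"
    )
    data = ts.data - ts.data.mean(axis=1, keepdims=True)
    filtered = scipy.signal.sosfiltfilt(sos, data, axis=1)
    filtered = filtered - filtered.mean(axis=1, keepdims=True)
    return SessionTimeSeries(
        data=filtered, tr=ts.tr, subject_id=ts.subject_id, session_id=ts.session_id
    )


def regress_nuisance(
    ts: SessionTimeSeries, confounds: np.ndarray | None
) -> SessionTimeSeries:
    """Residualize every vertex series against [intercept | confounds].

    Used to remove white-matter and CSF signals before connectivity is
    computed.  With no confounds this reduces to demeaning.
    """
    t = ts.n_timepoints
    if confounds is None or (hasattr(confounds, "size") and np.size(confounds) == 0):
        design = np.ones((t, 1))
    else:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        if confounds.shape[0] != t:
            raise ValueError(
                f"confound rows ({confounds.shape[0]}) != timepoints ({t})"
            )
        design = np.column_stack([np.ones(t), confounds])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # name the offending columns by leave-one-out rank recovery
            collinear = [
                c - 1
                for c in range(1, design.shape[1])
                if np.linalg.matrix_rank(np.delete(design, c, axis=1)) == rank
            ]
            raise ValueError(
                f"confound design is rank-deficient; collinear columns "
                f"(0-based, excluding intercept): {collinear}"
            )
    beta, *_ = np.linalg.lstsq(design, ts.data.T, rcond=None)
    resid = ts.data - (design @ beta).T
    return SessionTimeSeries(
        data=resid, tr=ts.tr, subject_id=ts.subject_id, session_id=ts.session_id
    )


def _standardize_rows(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows to zero mean / unit norm; returns (Z, zero_variance_mask)."""
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero_var = norms < 1e-12 * max(1.0, float(np.abs(data).max(initial=0.0)))
    safe = np.where(zero_var, 1.0, norms)
    return centered / safe[:, None], zero_var


def connectivity_fingerprint(
    ts: SessionTimeSeries, atlas: GroupAtlas
) -> GraphSignals:
    """Correlate every vertex with each atlas ROI's mean series.

    ``X[v, k-1]`` is the Pearson correlation between vertex v's series and
    the mean series of parcel k.  Vertices whose series have zero variance
    get an all-zero fingerprint row and are flagged.
    """
    if ts.n_vertices != atlas.n_vertices:
        raise ValueError(
            f"time series has {ts.n_vertices} vertices, atlas {atlas.n_vertices}"
        )
    k_tot = atlas.n_parcels
    roi_means = np.empty((k_tot, ts.n_timepoints))
    for k in range(1, k_tot + 1):
        idx = atlas.parcel_vertices(k)
        if idx.size == 0:
            raise ValueError(f"parcel {k} has no vertices")
        roi_means[k - 1] = ts.data[idx].mean(axis=0)

    z_vert, zero_var = _standardize_rows(ts.data)
    if zero_var.all():
        raise ValueError("all vertex series have zero variance")
    z_roi, roi_zero = _standardize_rows(roi_means)
    if roi_zero.any():
        raise ValueError(
            f"ROI mean series with zero variance: parcels "
            f"{(np.flatnonzero(roi_zero) + 1).tolist()}"
        )
    x = z_vert @ z_roi.T
    x[zero_var] = 0.0
    np.clip(x, -1.0, 1.0, out=x)
    return GraphSignals(
        X=x, feature_meaning=np.arange(1, k_tot + 1), zero_variance=zero_var
    )


def initial_parcellation(signals: GraphSignals, atlas: GroupAtlas):
    """Similarity-based first-pass parcellation of one session.

    Each vertex is assigned to the parcel whose centroid fingerprint (mean of
    the fingerprint rows of the atlas-labelled vertices of that parcel) is
    most correlated with the vertex's own fingerprint.  Ties break to the
    lowest parcel index; flagged zero-variance vertices get label 0.  This is
    the first of the three confidence-mask construction steps.
    """
    from .masked_training import ParcellationMap  # local import avoids cycle

    if signals.n_vertices != atlas.n_vertices:
        raise ValueError("signals and atlas vertex counts differ")
    k_tot = atlas.n_parcels
    centroids = np.empty((k_tot, signals.n_features))
    for k in range(1, k_tot + 1):
        idx = atlas.parcel_vertices(k)
        if idx.size == 0:
            raise ValueError(f"parcel {k} centroid is empty")
        centroids[k - 1] = signals.X[idx].mean(axis=0)

    z_x, x_zero = _standardize_rows(signals.X)
    z_c, c_zero = _standardize_rows(centroids)
    if c_zero.any():
        raise ValueError(
            f"constant centroid fingerprint for parcels "
            f"{(np.flatnonzero(c_zero) + 1).tolist()}"
        )
    sim = z_x @ z_c.T
    labels = np.argmax(sim, axis=1) + 1  # argmax takes lowest index on ties
    labels[x_zero | signals.zero_variance] = 0
    return ParcellationMap(labels=labels)
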