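"""Reliability, variability, homogeneity and task-alignment metrics.

All metrics operate on per-vertex parcellation maps (and, where needed, the
underlying time series or task activation maps):

* Dice overlap per parcel, 2|A∩B|/(|A|+|B|), averaged unweighted across
  parcels — the workhorse for test–retest reliability and intersubject
  similarity.
* Cohen's d between the intersubject and intrasubject distributions of a
  variability index (1 − Dice for topography, 1 − profile correlation for
  connectivity), with population variances:
  d = (μ_inter − μ_intra) / sqrt(σ²_inter + σ²_intra).
* Resting-state functional homogeneity: mean pairwise Pearson correlation
  of vertex series within a parcel, size-weighted to a global value.
* Task alignment: within-parcel standard deviation (variability) and mean
  (homogeneity) of a task activation beta map.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .masked_training import ParcellationMap
from .signals import GraphSignals, GroupAtlas, SessionTimeSeries, _standardize_rows

__all__ = [
    "PairwiseSimilarity",
    "VariabilityMap",
    "dice_parcellation",
    "cohens_d",
    "variability_maps",
    "connectivity_variability",
    "functional_homogeneity",
    "task_alignment",
    "correlate_maps",
    "intra_inter_dice",
]


@dataclass
class PairwiseSimilarity:
    """Dice values split into same-subject and different-subject pairs."""

    intra: np.ndarray
    inter: np.ndarray

    def __post_init__(self) -> None:
        self.intra = np.asarray(self.intra, dtype=float)
        self.inter = np.asarray(self.inter, dtype=float)
        for v in (self.intra, self.inter):
            if v.size and ((v < 0) | (v > 1)).any():
                raise ValueError("Dice values must lie in [0, 1]")


@dataclass
class VariabilityMap:
    """Per-parcel scalar statistic (e.g. Cohen's d); NaN marks missing."""

    values: np.ndarray  # indexed by parcel - 1
    index_meaning: str = "cohens_d"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def dice_parcellation(
    map_a: ParcellationMap, map_b: ParcellationMap
) -> tuple[dict[int, float], float]:
    """Per-parcel Dice overlap and its unweighted mean across parcels.

    For parcel k, dice_k = 2|A_k ∩ B_k| / (|A_k| + |B_k|) where A_k, B_k are
    the vertex sets labelled k in the two maps.  Label 0 is excluded; parcels
    absent from both maps are skipped.  Symmetric in its arguments.
    """
    a, b = map_a.labels, map_b.labels
    if a.shape != b.shape:
        raise ValueError(f"maps have different lengths {a.shape} vs {b.shape}")
    labels = np.union1d(np.unique(a), np.unique(b))
    labels = labels[labels > 0]
    k_max = int(labels.max(initial=0))
    count_a = np.bincount(a, minlength=k_max + 1)
    count_b = np.bincount(b, minlength=k_max + 1)
    both = a == b
    overlap = np.bincount(a[both], minlength=k_max + 1)
    per_parcel: dict[int, float] = {}
    for k in labels:
        denom = count_a[k] + count_b[k]
        per_parcel[int(k)] = 2.0 * overlap[k] / denom
    mean = float(np.mean(list(per_parcel.values()))) if per_parcel else np.nan
    return per_parcel, mean


def cohens_d(
    inter_values: np.ndarray,
    intra_values: np.ndarray,
    population_variance: bool = True,
) -> float:
    """Standardized mean difference between two value distributions.

    d = (μ_inter − μ_intra) / sqrt(σ²_inter + σ²_intra), population
    (denominator-n) variances by default.  Positive d means the intersubject
    values run higher than the intrasubject ones.
    """
    inter = np.asarray(inter_values, dtype=float)
    intra = np.asarray(intra_values, dtype=float)
    ddof = 0 if population_variance else 1
    var_inter = inter.var(ddof=ddof) if inter.size > ddof else 0.0
    var_intra = intra.var(ddof=ddof) if intra.size > ddof else 0.0
    num = inter.mean() - intra.mean()
    denom = np.sqrt(var_inter + var_intra)
    if denom == 0.0:
        if num == 0.0:
            return 0.0
        raise ValueError(
            "both variances are zero but the means differ: Cohen's d undefined"
        )
    return float(num / denom)


def _pair_indices(
    subject_ids: list[str],
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split all unordered map pairs into intra- and intersubject pairs."""
    intra, inter = [], []
    for i, j in itertools.combinations(range(len(subject_ids)), 2):
        (intra if subject_ids[i] == subject_ids[j] else inter).append((i, j))
    return intra, inter


def intra_inter_dice(
    parcellations: list[ParcellationMap],
) -> PairwiseSimilarity:
    """Mean-Dice reliability split by subject identity.

    Maps must carry subject_id; every unordered pair of maps contributes one
    mean Dice value, to the intra list when the two maps come from the same
    subject (different sessions) and to the inter list otherwise.
    """
    ids = [pm.subject_id for pm in parcellations]
    if any(not s for s in ids):
        raise ValueError("all parcellation maps need a subject_id")
    intra_idx, inter_idx = _pair_indices(ids)
    intra = [dice_parcellation(parcellations[i], parcellations[j])[1]
             for i, j in intra_idx]
    inter = [dice_parcellation(parcellations[i], parcellations[j])[1]
             for i, j in inter_idx]
    return PairwiseSimilarity(intra=np.array(intra), inter=np.array(inter))


def variability_maps(
    parcellations: list[ParcellationMap],
    n_parcels: int,
) -> VariabilityMap:
    """Per-parcel topographic variability as Cohen's d of 1 − Dice.

    For each parcel, 1 − dice_k is collected over all intersubject map pairs
    and all intrasubject (same subject, different session) pairs; the
    parcel's value is Cohen's d between the two collections, so larger d
    means the parcel's topography varies more between subjects than between
    repeated sessions.  Parcels absent from all maps are NaN.
    """
    ids = [pm.subject_id for pm in parcellations]
    if any(not s for s in ids):
        raise ValueError("all parcellation maps need a subject_id")
    intra_idx, inter_idx = _pair_indices(ids)
    if not intra_idx or not inter_idx:
        raise ValueError("need both intra- and intersubject pairs "
                         "(>= 2 subjects with >= 2 sessions each)")
    per_parcel_vals: dict[str, dict[int, list[float]]] = {
        "intra": {k: [] for k in range(1, n_parcels + 1)},
        "inter": {k: [] for k in range(1, n_parcels + 1)},
    }
    for group, pairs in (("intra", intra_idx), ("inter", inter_idx)):
        for i, j in pairs:
            per_k, _ = dice_parcellation(parcellations[i], parcellations[j])
            for k, dk in per_k.items():
                if k <= n_parcels:
                    per_parcel_vals[group][k].append(1.0 - dk)
    values = np.full(n_parcels, np.nan)
    for k in range(1, n_parcels + 1):
        inter_v = per_parcel_vals["inter"][k]
        intra_v = per_parcel_vals["intra"][k]
        if not inter_v and not intra_v:
            continue  # parcel absent everywhere -> NaN
        values[k - 1] = cohens_d(np.array(inter_v), np.array(intra_v))
    return VariabilityMap(values=values, index_meaning="cohens_d(1 - dice)")


def connectivity_variability(
    fingerprints: list[GraphSignals],
    subject_ids: list[str],
    atlas: GroupAtlas,
) -> VariabilityMap:
    """Per-parcel functional-connectivity variability as Cohen's d.

    A run's parcel profile is the mean fingerprint row over the atlas
    vertices of that parcel.  For each unordered run pair the variability
    index is 1 − Pearson correlation of the two profiles; Cohen's d between
    the intersubject and intrasubject collections is reported per parcel.
    """
    if len(fingerprints) != len(subject_ids):
        raise ValueError("fingerprints and subject_ids lengths differ")
    intra_idx, inter_idx = _pair_indices(list(subject_ids))
    if not intra_idx or not inter_idx:
        raise ValueError("need both intra- and intersubject run pairs")
    k_tot = atlas.n_parcels
    profiles = np.stack(
        [
            np.stack(
                [sig.X[atlas.parcel_vertices(k)].mean(axis=0)
                 for k in range(1, k_tot + 1)]
            )
            for sig in fingerprints
        ]
    )  # (runs, parcels, F)
    values = np.full(k_tot, np.nan)
    for k in range(k_tot):
        groups = {}
        for group, pairs in (("intra", intra_idx), ("inter", inter_idx)):
            vals = []
            for i, j in pairs:
                pi, pj = profiles[i, k], profiles[j, k]
                if pi.std() < 1e-12 or pj.std() < 1e-12:
                    warnings.warn(
                        f"zero-variance profile for parcel {k + 1}; pair "
                        f"({i},{j}) skipped",
                        stacklevel=2,
                    )
                    continue
                vals.append(1.0 - float(np.corrcoef(pi, pj)[0, 1]))
            groups[group] = np.array(vals)
        if groups["intra"].size and groups["inter"].size:
            values[k] = cohens_d(groups["inter"], groups["intra"])
    return VariabilityMap(values=values, index_meaning="cohens_d(1 - profile r)")


def functional_homogeneity(
    parcellation: ParcellationMap, ts: SessionTimeSeries
) -> tuple[dict[int, float], float]:
    """Within-parcel mean pairwise correlation and its size-weighted global.

    h_k = mean over unordered vertex pairs in parcel k of the Pearson
    correlation of their series;  H = Σ n_k h_k / Σ n_k over parcels with at
    least two vertices.  Higher H means parcels bundle vertices with similar
    BOLD dynamics.
    """
    if parcellation.n_vertices != ts.n_vertices:
        raise ValueError("parcellation and time series vertex counts differ")
    z, zero_var = _standardize_rows(ts.data)
    per_parcel: dict[int, float] = {}
    sizes: dict[int, int] = {}
    for k in np.unique(parcellation.labels):
        if k == 0:
            continue
        idx = np.flatnonzero((parcellation.labels == k) & ~zero_var)
        n_k = idx.size
        if n_k < 2:
            continue
        zk = z[idx]
        corr_sum = float(np.sum(zk @ zk.T)) - n_k  # off-diagonal sum
        per_parcel[int(k)] = corr_sum / (n_k * (n_k - 1))
        sizes[int(k)] = n_k
    if not per_parcel:
        raise ValueError("no parcel has >= 2 vertices with variance")
    total = sum(sizes.values())
    global_h = sum(sizes[k] * per_parcel[k] for k in per_parcel) / total
    return per_parcel, float(global_h)


def task_alignment(
    parcellation: ParcellationMap, beta_map: np.ndarray
) -> tuple[dict[int, tuple[float, float]], float, float]:
    """Within-parcel spread and strength of a task activation map.

    Per parcel k: variability = population std of the betas inside k,
    homogeneity = their mean.  Returns (per-parcel {k: (std, mean)},
    whole-brain size-weighted mean std, whole-brain size-weighted mean
    activation).  Lower whole-brain std means activation boundaries align
    better with the parcel borders.
    """
    beta = np.asarray(beta_map, dtype=float)
    if beta.shape[0] != parcellation.n_vertices:
        raise ValueError("beta map length differs from parcellation")
    cortical = parcellation.labels > 0
    if np.isnan(beta[cortical]).any():
        raise ValueError("NaN betas at cortical vertices")
    per_parcel: dict[int, tuple[float, float]] = {}
    sizes: dict[int, int] = {}
    for k in np.unique(parcellation.labels):
        if k == 0:
            continue
        vals = beta[parcellation.labels == k]
        per_parcel[int(k)] = (float(vals.std()), float(vals.mean()))
        sizes[int(k)] = vals.size
    total = sum(sizes.values())
    wb_var = sum(sizes[k] * per_parcel[k][0] for k in per_parcel) / total
    wb_mean = sum(sizes[k] * per_parcel[k][1] for k in per_parcel) / total
    return per_parcel, float(wb_var), float(wb_mean)


def correlate_maps(
    map_x: np.ndarray, map_y: np.ndarray
) -> tuple[float, float]:
    """Pearson r and two-sided p between two per-parcel maps.

    Parcels missing (NaN) in either map are dropped pairwise; at least three
    complete pairs are required.
    """
    x = np.asarray(map_x, dtype=float)
    y = np.asarray(map_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("maps have different lengths")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError(f"only {int(ok.sum())} complete pairs; need >= 3")
    r, p = scipy.stats.pearsonr(x[ok], y[ok])
    return float(r), float(p)
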