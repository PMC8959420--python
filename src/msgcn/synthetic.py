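"""Synthetic cortices, atlases, individual parcellations and BOLD sessions.

The generator emulates the statistical structure the parcellation pipeline
is built for, at desk scale:

* a closed triangulated "cortex" (an icosphere, 100 mm radius);
* a K-parcel group atlas of contiguous parcels grown from farthest-point
  seeds, with a spatially contiguous block of parcels tagged
  ``association`` and the rest ``primary``;
* per-subject ground-truth parcellations that deviate from the atlas only
  at parcel borders, with stronger boundary warping in association parcels
  than primary parcels (a sensory-fugal variability gradient);
* per-session vertex time series that are parcel-shared smooth latents
  (band-limited to 0.01–0.1 Hz) plus independent vertex noise at a
  controllable SNR — sessions of one subject share the subject's
  parcellation but draw independent signals;
* behavioral scores that are a noisy linear function of the subject's
  parcellation topography (per-parcel Dice to the atlas).

Everything is bit-reproducible from ``(config, seed)`` via named
SeedSequence substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
import scipy.sparse.csgraph as csgraph
import trimesh

from .masked_training import ParcellationMap
from .signals import GroupAtlas, SessionTimeSeries
from .surface import (
    GraphLaplacian,
    SurfaceGraph,
    SurfaceMesh,
    build_adjacency,
    estimate_lambda_max,
    normalized_laplacian,
    scale_laplacian,
)

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "make_mesh",
    "make_group_atlas",
    "make_subject_truth",
    "make_session",
    "make_behavior",
    "make_cohort",
]


@dataclass
class SyntheticCohortConfig:
    """Study-condition knobs for one synthetic cohort.

    Defaults give a desk-scale cohort: a subdivision-4 icosphere
    (2,562 vertices), 50 parcels, 20 subjects x 2 sessions of 400 timepoints
    at the usual fast-TR 0.72 s.  ``snr`` is the ratio of the parcel-latent
    signal standard deviation to the vertex noise standard deviation;
    ``warp_steps_*`` are expected boundary label-flip rounds per vertex
    (association parcels warp harder than primary ones).
    """

    mesh_subdivisions: int = 4
    n_parcels: int = 50
    n_subjects: int = 20
    n_sessions_per_subject: int = 2
    n_timepoints: int = 400
    tr: float = 0.72
    snr: float = 3.0
    warp_steps_primary: float = 0.15
    warp_steps_association: float = 0.45
    subject_scale_range: tuple[float, float] = (0.5, 1.5)
    association_fraction: float = 0.5
    behavior_effect: float = 1.0
    behavior_noise: float = 0.1
    medial_wall_angle_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_parcels,
            self.n_subjects,
            self.n_sessions_per_subject,
            self.n_timepoints,
        )
        if min(counts) < 1:
            raise ValueError("all counts must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not (0.0 <= self.association_fraction <= 1.0):
            raise ValueError("association_fraction must be in [0, 1]")
        if min(self.warp_steps_primary, self.warp_steps_association) < 0:
            raise ValueError("warp steps must be >= 0")
        lo, hi = self.subject_scale_range
        if not (0.0 <= lo <= hi):
            raise ValueError("subject_scale_range must satisfy 0 <= lo <= hi")


@dataclass
class SyntheticCohort:
    """A fully generated cohort plus the shared graph operators."""

    config: SyntheticCohortConfig
    mesh: SurfaceMesh
    graph: SurfaceGraph
    laplacian: GraphLaplacian
    atlas: GroupAtlas
    subject_truths: list[ParcellationMap]
    sessions: list[list[SessionTimeSeries]]  # [subject][session]
    behavior_scores: np.ndarray = field(default=None)  # type: ignore[assignment]
    behavior_contrasts: np.ndarray = field(default=None)  # type: ignore[assignment]


def make_mesh(
    subdivisions: int,
    radius: float = 100.0,
    medial_wall_angle_deg: float = 0.0,
) -> SurfaceMesh:
    """Icosphere stand-in for a cortical hemisphere surface.

    An icosahedron subdivided ``subdivisions`` times, vertices on a sphere of
    ``radius`` mm.  A polar cap of half-angle ``medial_wall_angle_deg`` (from
    the +z pole) can be excluded from the cortex mask to emulate the medial
    wall.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if subdivisions > 7:
        raise ValueError("subdivisions > 7 refused (mesh would be huge)")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    coords = np.asarray(ico.vertices, dtype=float)
    tris = np.asarray(ico.faces, dtype=np.int64)
    mask = np.ones(coords.shape[0], dtype=bool)
    if medial_wall_angle_deg > 0.0:
        cos_polar = coords[:, 2] / np.linalg.norm(coords, axis=1)
        mask = np.degrees(np.arccos(np.clip(cos_polar, -1, 1))) > medial_wall_angle_deg
    return SurfaceMesh(coordinates=coords, triangles=tris, cortex_mask=mask)


def _multi_source_bfs(graph: SurfaceGraph, seeds: np.ndarray) -> np.ndarray:
    """Grow parcels from seed vertices; each vertex takes its discoverer's
    label, so every parcel is connected by construction.  Deterministic."""
    n = graph.n_vertices
    indptr, indices = graph.adjacency.indptr, graph.adjacency.indices
    labels = np.zeros(n, dtype=np.int64)
    frontier = list(seeds)
    for k, s in enumerate(seeds, start=1):
        labels[s] = k
    while frontier:
        nxt = []
        for v in frontier:
            for u in indices[indptr[v]:indptr[v + 1]]:
                if labels[u] == 0:
                    labels[u] = labels[v]
                    nxt.append(u)
        frontier = nxt
    return labels


def make_group_atlas(
    mesh: SurfaceMesh,
    n_parcels: int,
    seed: int = 0,
    association_fraction: float = 0.5,
    graph: SurfaceGraph | None = None,
) -> GroupAtlas:
    """Contiguous K-parcel atlas from farthest-point seeds on the graph.

    Seeds are picked greedily to maximize the minimum hop distance to the
    existing seeds (first seed random); parcels are grown by multi-source
    breadth-first search, so every parcel is connected.  Parcels whose seed
    lies farthest along a random spatial direction form a contiguous
    ``association`` zone; the rest are ``primary``.
    """
    if graph is None:
        graph = build_adjacency(mesh)
    n = graph.n_vertices
    if n_parcels > n:
        raise ValueError(f"n_parcels {n_parcels} exceeds cortical vertices {n}")
    rng = np.random.default_rng(seed)
    adj = graph.adjacency

    seeds = [int(rng.integers(n))]
    dist = csgraph.dijkstra(adj, indices=seeds[0], unweighted=True)
    for _ in range(1, n_parcels):
        nxt = int(np.argmax(dist))
        seeds.append(nxt)
        dist = np.minimum(
            dist, csgraph.dijkstra(adj, indices=nxt, unweighted=True)
        )
    labels_graph = _multi_source_bfs(graph, np.array(seeds))

    labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    labels[graph.vertex_map] = labels_graph

    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    seed_proj = mesh.coordinates[graph.vertex_map[seeds]] @ direction
    n_assoc = int(round(association_fraction * n_parcels))
    order = np.argsort(-seed_proj)  # farthest along direction first
    parcel_class = np.array(["primary"] * n_parcels, dtype=object)
    parcel_class[order[:n_assoc]] = "association"
    return GroupAtlas(
        labels=labels, n_parcels=n_parcels, parcel_class=parcel_class
    )


def make_subject_truth(
    atlas: GroupAtlas,
    graph: SurfaceGraph,
    config: SyntheticCohortConfig,
    subject_seed: int,
    subject_id: str = "",
) -> ParcellationMap:
    """Subject ground truth: atlas with stochastically warped parcel borders.

    Runs ``R = ceil(max(warp_steps))`` rounds; in each round every boundary
    vertex adopts the label of a random differently-labelled neighbor with
    probability ``warp_steps_class / R`` (class of the vertex's current
    parcel), so the expected number of flip opportunities per boundary
    vertex equals the configured warp steps.  A flip that would empty a
    parcel is skipped.  Interior vertices never move, so deviations stay at
    the borders.

    Each subject additionally draws a global warp multiplier from
    ``config.subject_scale_range``: subjects genuinely differ in how far
    their topography departs from the atlas, which is what makes
    topography-linked behavior recoverable at the cohort level.
    """
    rng = np.random.default_rng(subject_seed)
    labels = atlas.labels.copy()
    scale = rng.uniform(*config.subject_scale_range)
    r_max = scale * max(config.warp_steps_primary, config.warp_steps_association)
    if r_max == 0:
        return ParcellationMap(labels=labels, subject_id=subject_id)
    rounds = int(np.ceil(r_max))
    p_class = {
        "primary": min(1.0, scale * config.warp_steps_primary / rounds),
        "association": min(1.0, scale * config.warp_steps_association / rounds),
    }
    if atlas.parcel_class is None:
        p_class = {None: min(1.0, r_max / rounds)}
    indptr, indices = graph.adjacency.indptr, graph.adjacency.indices
    vmap = graph.vertex_map
    # graph-local labels for neighbor queries
    glab = labels[vmap]
    counts = np.bincount(glab, minlength=atlas.n_parcels + 1)

    for _ in range(rounds):
        neigh_diff = [
            indices[indptr[v]:indptr[v + 1]][
                (glab[indices[indptr[v]:indptr[v + 1]]] != glab[v])
                & (glab[indices[indptr[v]:indptr[v + 1]]] > 0)
            ]
            for v in range(graph.n_vertices)
        ]
        boundary = [v for v in range(graph.n_vertices)
                    if glab[v] > 0 and neigh_diff[v].size]
        for v in rng.permutation(boundary):
            k_old = glab[v]
            if atlas.parcel_class is None:
                p = p_class[None]
            else:
                p = p_class[str(atlas.parcel_class[k_old - 1])]
            if rng.random() >= p:
                continue
            if counts[k_old] <= 1:
                continue  # never empty a parcel
            # re-check neighbors against the evolving labels
            nb = indices[indptr[v]:indptr[v + 1]]
            cand = nb[(glab[nb] != k_old) & (glab[nb] > 0)]
            if cand.size == 0:
                continue
            k_new = int(glab[cand[rng.integers(cand.size)]])
            glab[v] = k_new
            counts[k_old] -= 1
            counts[k_new] += 1

    labels = np.zeros_like(atlas.labels)
    labels[vmap] = glab
    return ParcellationMap(labels=labels, subject_id=subject_id)


def make_session(
    subject_truth: ParcellationMap,
    config: SyntheticCohortConfig,
    session_seed: int,
    subject_id: str = "",
    session_id: str = "",
) -> SessionTimeSeries:
    """One session of parcel-structured vertex time series.

    Each parcel draws an independent latent series — white noise band-passed
    to 0.01–0.1 Hz at the configured TR and standardized — and every vertex
    observes its parcel's latent plus independent white noise with standard
    deviation 1/snr.  Unassigned (label 0) vertices are pure noise.
    """
    if config.n_timepoints < 50:
        raise ValueError("need n_timepoints >= 50 for a usable band-pass")
    rng = np.random.default_rng(session_seed)
    t = config.n_timepoints
    k_tot = int(subject_truth.labels.max())
    sos = scipy.signal.butter(
        4, [0.01, 0.1], btype="bandpass", fs=1.0 / config.tr, output="sos"
    )
    latents = scipy.signal.sosfiltfilt(
        sos, rng.standard_normal((k_tot + 1, t)), axis=1
    )
    latents = latents - latents.mean(axis=1, keepdims=True)
    latents /= latents.std(axis=1, keepdims=True)
    latents[0] = 0.0  # background has no shared signal

    data = latents[subject_truth.labels]
    noise_std = np.where(subject_truth.labels > 0, 1.0 / config.snr, 1.0)
    data = data + noise_std[:, None] * rng.standard_normal((subject_truth.n_vertices, t))
    return SessionTimeSeries(
        data=data, tr=config.tr, subject_id=subject_id, session_id=session_id
    )


def make_behavior(
    subject_truths: list[ParcellationMap],
    atlas: GroupAtlas,
    config: SyntheticCohortConfig,
    seed: int = 0,
    contrast_sign: str = "positive",
) -> tuple[np.ndarray, np.ndarray]:
    """Scores as a noisy linear function of parcellation topography.

    score_s = effect · Σ_k c_k · dice_k(subject_s, atlas) + noise, with
    fixed seeded per-parcel contrasts c_k.  By default the contrasts are
    positive (uniform on [0.5, 1.5]), so the score loads on the subject's
    overall topographic deviation — the component of topography a global
    Dice similarity can see.  ``contrast_sign="signed"`` draws c_k ~ N(0,1)
    instead, producing a region-specific contrast that a whole-cortex Dice
    kernel has little power to recover.  Returns (scores, contrasts).
    """
    from .evaluation import dice_parcellation

    if len(subject_truths) < 2:
        raise ValueError("need >= 2 subjects")
    rng = np.random.default_rng(seed)
    if contrast_sign == "positive":
        contrasts = rng.uniform(0.5, 1.5, atlas.n_parcels)
    elif contrast_sign == "signed":
        contrasts = rng.standard_normal(atlas.n_parcels)
    else:
        raise ValueError("contrast_sign must be 'positive' or 'signed'")
    atlas_map = ParcellationMap(labels=atlas.labels)
    scores = np.empty(len(subject_truths))
    for s, truth in enumerate(subject_truths):
        per_k, _ = dice_parcellation(truth, atlas_map)
        dice_vec = np.array(
            [per_k.get(k, 0.0) for k in range(1, atlas.n_parcels + 1)]
        )
        scores[s] = config.behavior_effect * float(contrasts @ dice_vec)
    scores += config.behavior_noise * rng.standard_normal(len(subject_truths))
    return scores, contrasts


def make_cohort(
    config: SyntheticCohortConfig, with_behavior: bool = True
) -> SyntheticCohort:
    """Generate the full cohort: mesh, graph operators, atlas, truths,
    sessions and (optionally) behavior, all from named substreams of
    ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    s_atlas, s_subjects, s_sessions, s_behavior, s_lmax = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    )
    mesh = make_mesh(
        config.mesh_subdivisions,
        medial_wall_angle_deg=config.medial_wall_angle_deg,
    )
    graph = build_adjacency(mesh)
    lap = normalized_laplacian(graph)
    estimate_lambda_max(lap, seed=s_lmax)
    scale_laplacian(lap)
    atlas = make_group_atlas(
        mesh,
        config.n_parcels,
        seed=s_atlas,
        association_fraction=config.association_fraction,
        graph=graph,
    )
    sub_ss = np.random.SeedSequence(s_subjects).spawn(config.n_subjects)
    ses_ss = np.random.SeedSequence(s_sessions).spawn(
        config.n_subjects * config.n_sessions_per_subject
    )
    truths, sessions = [], []
    for s in range(config.n_subjects):
        sid = f"sub{s:03d}"
        truth = make_subject_truth(
            atlas,
            graph,
            config,
            subject_seed=int(sub_ss[s].generate_state(1)[0] % (2**31)),
            subject_id=sid,
        )
        truths.append(truth)
        subject_sessions = []
        for j in range(config.n_sessions_per_subject):
            seed_j = int(
                ses_ss[s * config.n_sessions_per_subject + j]
                .generate_state(1)[0] % (2**31)
            )
            subject_sessions.append(
                make_session(
                    truth, config, session_seed=seed_j,
                    subject_id=sid, session_id=f"ses{j}",
                )
            )
        sessions.append(subject_sessions)
    cohort = SyntheticCohort(
        config=config,
        mesh=mesh,
        graph=graph,
        laplacian=lap,
        atlas=atlas,
        subject_truths=truths,
        sessions=sessions,
    )
    if with_behavior:
        scores, contrasts = make_behavior(truths, atlas, config, seed=s_behavior)
        cohort.behavior_scores = scores
        cohort.behavior_contrasts = contrasts
    return cohort
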