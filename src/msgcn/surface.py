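"""Vertex-level brain graph construction from cortical surface meshes.

The cortical surface is a closed triangle mesh on a standard template; all
subjects share the template, so one binary graph serves the whole cohort.
Two vertices are adjacent iff they co-occur in at least one mesh triangle,
restricted to vertices inside the cortical mask (medial-wall vertices are
removed and the remaining vertices compactly re-indexed).

The spectral operators built here — the symmetric normalized Laplacian
``L = I - D^{-1/2} A D^{-1/2}`` and its rescaled form
``L~ = 2L/lambda_max - I`` — are what the Chebyshev graph convolutions in
:mod:`msgcn.chebnet` act on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceMesh",
    "SurfaceGraph",
    "GraphLaplacian",
    "build_adjacency",
    "normalized_laplacian",
    "estimate_lambda_max",
    "scale_laplacian",
]


@dataclass
class SurfaceMesh:
    """A triangulated cortical surface.

    Parameters
    ----------
    coordinates : (n_vertices, 3) float array
        Vertex positions in mm.
    triangles : (n_triangles, 3) int array
        Vertex-index triples.
    cortex_mask : (n_vertices,) bool array, optional
        True for cortical vertices, False for medial wall / excluded.
        Defaults to all-True.
    """

    coordinates: np.ndarray
    triangles: np.ndarray
    cortex_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_vertices, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (n_triangles, 3)")
        n = self.coordinates.shape[0]
        if self.cortex_mask is None:
            self.cortex_mask = np.ones(n, dtype=bool)
        self.cortex_mask = np.asarray(self.cortex_mask, dtype=bool)
        if self.cortex_mask.shape != (n,):
            raise ValueError(
                f"cortex_mask length {self.cortex_mask.shape} does not match "
                f"vertex count {n}"
            )
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= n:
                raise ValueError(
                    "triangle references out-of-range vertex index "
                    f"(max {self.triangles.max()}, n_vertices {n})"
                )
            t = self.triangles
            degenerate = (
                (t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])
            )
            if degenerate.any():
                raise ValueError(
                    f"degenerate triangles (repeated vertex index) at rows "
                    f"{np.flatnonzero(degenerate)[:10].tolist()}"
                )

    @property
    def n_vertices(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class SurfaceGraph:
    """Binary adjacency over cortical vertices.

    ``adjacency`` is restricted to cortical vertices in compact order;
    ``vertex_map`` holds the original mesh index of each graph node so file
    writers can restore full-mesh indexing.
    """

    adjacency: sp.csr_matrix
    vertex_map: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)


@dataclass
class GraphLaplacian:
    """Symmetric normalized Laplacian and its Chebyshev rescaling."""

    L: sp.csr_matrix
    lambda_max: float | None = None
    L_scaled: sp.csr_matrix | None = None
    # dense spectrum for oracle checks on small graphs only
    eigenvalues: np.ndarray | None = field(default=None, repr=False)
    eigenvectors: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_vertices(self) -> int:
        return self.L.shape[0]

    def dense_spectrum(self, max_n: int = 2000) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition of L for small graphs (oracle use)."""
        if self.n_vertices > max_n:
            raise ValueError(
                f"dense spectrum refused for n={self.n_vertices} > {max_n}"
            )
        if self.eigenvalues is None:
            w, u = np.linalg.eigh(self.L.toarray())
            self.eigenvalues, self.eigenvectors = w, u
        return self.eigenvalues, self.eigenvectors


def build_adjacency(mesh: SurfaceMesh) -> SurfaceGraph:
    """Build the binary vertex graph from shared mesh triangles.

    Two vertices are connected iff both lie inside the cortical mask and
    appear together in at least one triangle.  Non-cortical vertices are
    dropped and the survivors re-indexed compactly.
    """
    if not mesh.cortex_mask.any():
        raise ValueError("cortex_mask is empty: no cortical vertices")
    t = mesh.triangles
    if t.size == 0:
        raise ValueError("mesh has no triangles")
    # undirected edge candidates from each triangle side
    i = np.concatenate([t[:, 0], t[:, 1], t[:, 0]])
    j = np.concatenate([t[:, 1], t[:, 2], t[:, 2]])
    keep = mesh.cortex_mask[i] & mesh.cortex_mask[j]
    i, j = i[keep], j[keep]
    if i.size == 0:
        raise ValueError("no triangle edge has both endpoints inside cortex_mask")

    vertex_map = np.flatnonzero(mesh.cortex_mask)
    full_to_compact = -np.ones(mesh.n_vertices, dtype=np.int64)
    full_to_compact[vertex_map] = np.arange(vertex_map.size)
    i, j = full_to_compact[i], full_to_compact[j]

    n = vertex_map.size
    data = np.ones(i.size, dtype=np.int8)
    a = sp.coo_matrix((data, (i, j)), shape=(n, n)).tocsr()
    a = a + a.T
    a.data[:] = 1  # collapse multiplicity
    a.setdiag(0)
    a.eliminate_zeros()
    a = a.astype(np.float64)

    n_comp, _ = csgraph.connected_components(a, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"surface graph has {n_comp} connected components", stacklevel=2
        )
        logger.warning("surface graph has %d connected components", n_comp)
    return SurfaceGraph(adjacency=a.tocsr(), vertex_map=vertex_map)


def normalized_laplacian(graph: SurfaceGraph) -> GraphLaplacian:
    """Symmetric normalized Laplacian ``L = I - D^{-1/2} A D^{-1/2}``."""
    deg = graph.degrees
    isolated = np.flatnonzero(deg == 0)
    if isolated.size:
        raise ValueError(
            f"isolated vertices (degree 0) at graph indices "
            f"{isolated[:10].tolist()}; prune or reconnect them before "
            "building the Laplacian"
        )
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg.astype(float)))
    lap = sp.eye(graph.n_vertices, format="csr") - d_inv_sqrt @ graph.adjacency @ d_inv_sqrt
    # symmetrize away roundoff
    lap = ((lap + lap.T) * 0.5).tocsr()
    return GraphLaplacian(L=lap)


def estimate_lambda_max(
    laplacian: GraphLaplacian,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    seed: int = 0,
) -> float:
    """Largest eigenvalue of L by power iteration.

    L is positive semidefinite, so its largest eigenvalue is also largest in
    magnitude and plain power iteration converges.  The start vector is drawn
    from ``seed`` for reproducibility.  On non-convergence the error suggests
    the spectral upper bound 2.0 as a fallback.
    """
    lap = laplacian.L
    n = lap.shape[0]
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(max_iter):
        w = lap @ v
        norm = np.linalg.norm(w)
        if norm == 0.0:  # L == 0 (cannot occur for a connected edge, guard anyway)
            return 0.0
        v_new = w / norm
        lam_new = float(v_new @ (lap @ v_new))
        if abs(lam_new - lam) <= tol * max(abs(lam_new), 1.0):
            laplacian.lambda_max = lam_new
            return lam_new
        lam, v = lam_new, v_new
    raise RuntimeError(
        f"power iteration did not converge within {max_iter} iterations "
        "(tol {tol}); consider the normalized-Laplacian upper bound "
        "lambda_max = 2.0 as a fallback"
    )


def scale_laplacian(
    laplacian: GraphLaplacian, lambda_max: float | None = None
) -> GraphLaplacian:
    """Rescale L to ``L~ = 2 L / lambda_max - I`` for Chebyshev filtering.

    With the exact lambda_max the spectrum of L~ lies in [-1, 1], the domain
    on which Chebyshev polynomials are bounded.
    """
    if lambda_max is not None:
        laplacian.lambda_max = float(lambda_max)
    if laplacian.lambda_max is None:
        estimate_lambda_max(laplacian)
    if laplacian.lambda_max <= 0:
        raise ValueError(f"lambda_max must be positive, got {laplacian.lambda_max}")
    n = laplacian.n_vertices
    laplacian.L_scaled = (
        (2.0 / laplacian.lambda_max) * laplacian.L - sp.eye(n, format="csr")
    ).tocsr()
    return laplacian
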