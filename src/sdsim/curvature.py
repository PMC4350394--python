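"""Discrete curvature by osculating-paraboloid fits, with robust outlier
handling and hot-spot detection.

Per vertex, the neighbourhood is rotated into a local frame (vertex at the
origin, averaged normal along +z) and the canonical paraboloid
``z = a x^2 + b x y + c y^2`` is fitted by least squares.  Curvatures follow
directly: mean ``H = a + c``, Gaussian ``K = 4ac - b^2``, principal
``kappa_{1,2} = H +/- sqrt(H^2 - K)``, and the signed magnitude
``kappa_geo = sign(K) sqrt(|K|)`` used for visualisation.

Real (MRI-derived) surfaces are uneven at voxel scale; to avoid
overestimating curvature from such artifacts, a second estimate from the
ring of next-to-nearest neighbours is compared with the one-ring estimate,
and Chauvenet's criterion on the differences flags vertices where the two
disagree improbably much.  At flagged vertices the conservative
(smaller-magnitude) estimate is kept.

Regions of large negative Gaussian curvature ("hot spots") carry a lowered
nucleation barrier for spreading-depression waves; :func:`find_hot_spots`
extracts them as thinned local minima of K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.sparse.csgraph import dijkstra
from scipy.special import erfc

from .surfaces import SurfaceError, TriSurface


@dataclass(frozen=True)
class ParaboloidFit:
    """Least-squares coefficients of z = a x^2 + b x y + c y^2 at a vertex."""

    a: float
    b: float
    c: float
    vertex_id: int
    ring_order: int
    n_points: int
    degenerate: bool = False


@dataclass
class CurvatureField:
    """Per-vertex curvature estimates and the robustification diagnostics.

    ``H``, ``K`` are the selected (robust) values; ``H1/K1`` the raw one-ring
    estimates, ``H2/K2`` ("H-tilde") the two-ring estimates; ``dH = H1 - H2``
    etc.; ``outlier_H/outlier_K`` mark vertices where Chauvenet's criterion
    rejected the ring difference.
    """

    H: np.ndarray
    K: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    k_geo: np.ndarray
    H1: np.ndarray
    K1: np.ndarray
    H2: np.ndarray
    K2: np.ndarray
    dH: np.ndarray
    dK: np.ndarray
    mu_dH: float
    sigma_dH: float
    mu_dK: float
    sigma_dK: float
    outlier_H: np.ndarray
    outlier_K: np.ndarray

    @property
    def outlier_fraction_H(self) -> float:
        return float(self.outlier_H.mean())

    @property
    def outlier_fraction_K(self) -> float:
        return float(self.outlier_K.mean())


# ---------------------------------------------------------------------------
# Normals and rings
# ---------------------------------------------------------------------------

def vertex_normals(surface: TriSurface) -> np.ndarray:
    """Unit vertex normals: normalised unweighted mean of incident-face
    unit normals."""
    fn = surface.face_normals
    norms = np.linalg.norm(fn, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    fn = fn / norms
    acc = np.zeros_like(surface.vertices)
    cnt = np.zeros(surface.n_vertices)
    for k in range(3):
        np.add.at(acc, surface.faces[:, k], fn)
        np.add.at(cnt, surface.faces[:, k], 1.0)
    if (cnt == 0).any():
        raise SurfaceError("surface has isolated vertices")
    acc /= cnt[:, None]
    n = np.linalg.norm(acc, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return acc / n


def vertex_normal(surface: TriSurface, vertex: int) -> np.ndarray:
    return vertex_normals(surface)[vertex]


def _neighbor_lists(surface: TriSurface) -> List[np.ndarray]:
    adj = surface.vertex_adjacency(folded=False)
    return [adj.indices[adj.indptr[i]:adj.indptr[i + 1]]
            for i in range(surface.n_vertices)]


def _ring(neighbors: List[np.ndarray], vertex: int, order: int) -> np.ndarray:
    """Ring-1: nearest neighbours.  Ring-2: next-to-nearest only (graph
    distance exactly 2; excludes the vertex and its one-ring)."""
    one = neighbors[vertex]
    if order == 1:
        return one
    two = np.unique(np.concatenate([neighbors[j] for j in one]))
    mask = np.isin(two, one, invert=True)
    return two[mask][two[mask] != vertex]


# ---------------------------------------------------------------------------
# Paraboloid fitting
# ---------------------------------------------------------------------------

def _local_frame(normal: np.ndarray) -> np.ndarray:
    """Rotation taking the normal to +z; rows are the frame axes."""
    n = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ref, n)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return np.vstack([e1, e2, n])


def fit_osculating_paraboloid(surface: TriSurface, vertex: int,
                              ring_order: int = 1,
                              _normals: np.ndarray = None,
                              _neighbors: List[np.ndarray] = None,
                              ) -> ParaboloidFit:
    """Fit z = a x^2 + b x y + c y^2 to the vertex and its ring.

    The neighbourhood is translated so the vertex sits at the origin and
    rotated so its averaged normal is +z; the fit is exact whenever the
    points lie on a paraboloid of that form.  A rank-deficient system is
    returned as a flagged degenerate fit with zero coefficients.
    """
    normals = vertex_normals(surface) if _normals is None else _normals
    neighbors = _neighbor_lists(surface) if _neighbors is None else _neighbors
    ring = _ring(neighbors, vertex, ring_order)
    frame = _local_frame(normals[vertex])
    local = (surface.vertices[ring] - surface.vertices[vertex]) @ frame.T
    x, y, z = local[:, 0], local[:, 1], local[:, 2]
    # the target vertex itself contributes the (0,0,0) equation, which is
    # satisfied identically by the model class; only the ring constrains it
    A = np.column_stack([x * x, x * y, y * y])
    if len(ring) < 3:
        return ParaboloidFit(0.0, 0.0, 0.0, vertex, ring_order, len(ring) + 1,
                             degenerate=True)
    coef, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    if rank < 3:
        return ParaboloidFit(0.0, 0.0, 0.0, vertex, ring_order, len(ring) + 1,
                             degenerate=True)
    return ParaboloidFit(float(coef[0]), float(coef[1]), float(coef[2]),
                         vertex, ring_order, len(ring) + 1)


def curvatures_from_fit(fit: ParaboloidFit
                        ) -> Tuple[float, float, float, float, float]:
    """(H, K, kappa1, kappa2, kappa_geo) from paraboloid coefficients."""
    return _curvatures(fit.a, fit.b, fit.c)


def _curvatures(a, b, c):
    H = a + c
    K = 4.0 * a * c - b * b
    disc = np.maximum(H * H - K, 0.0)   # clip tiny negatives from round-off
    root = np.sqrt(disc)
    k1, k2 = H + root, H - root
    k_geo = np.sign(K) * np.sqrt(np.abs(K))
    return H, K, k1, k2, k_geo


# ---------------------------------------------------------------------------
# Chauvenet outlier criterion
# ---------------------------------------------------------------------------

def chauvenet_flags(values: Sequence[float]) -> np.ndarray:
    """Flag outliers by Chauvenet's criterion, n * erfc(|x - mu| / sigma) < 1/2.

    ``mu`` and ``sigma`` are the sample mean and standard deviation of the
    full list (the candidate point included, standard Chauvenet practice).
    With ``sigma = 0`` nothing is flagged.  Flags are invariant under affine
    rescaling of the values.
    """
    x = np.asarray(values, dtype=np.float64)
    n = len(x)
    if n < 2:
        raise ValueError("Chauvenet's criterion needs at least two values")
    mu = x.mean()
    sigma = x.std(ddof=1)
    if sigma == 0:
        return np.zeros(n, dtype=bool)
    return n * erfc(np.abs(x - mu) / sigma) < 0.5


# ---------------------------------------------------------------------------
# Whole-surface robust field
# ---------------------------------------------------------------------------

def robust_curvature_field(surface: TriSurface,
                           selection: str = "abs") -> CurvatureField:
    """Per-vertex robust curvatures from ring-1 and ring-2 paraboloid fits.

    At regular vertices the one-ring estimates are used.  Where the
    Chauvenet flag on dH = H - H_tilde (resp. dK) is set, the estimate of
    smaller magnitude is kept — a conservative value suppressing local
    artifacts (``selection="signed"`` instead keeps the algebraically
    smaller one).  H and K decisions are independent; the principal
    curvatures derive from the selected pair.
    """
    if selection not in ("abs", "signed"):
        raise ValueError("selection must be 'abs' or 'signed'")
    normals = vertex_normals(surface)
    neighbors = _neighbor_lists(surface)
    n = surface.n_vertices
    abc1 = np.zeros((n, 3))
    abc2 = np.zeros((n, 3))
    n_degenerate = 0
    for v in range(n):
        for order, abc in ((1, abc1), (2, abc2)):
            fit = fit_osculating_paraboloid(surface, v, order,
                                            _normals=normals,
                                            _neighbors=neighbors)
            if fit.degenerate:
                n_degenerate += 1
            abc[v] = (fit.a, fit.b, fit.c)
    if n_degenerate:
        warnings.warn(f"{n_degenerate} degenerate paraboloid fits set to "
                      "zero curvature", stacklevel=2)

    H1, K1, *_ = _curvatures(abc1[:, 0], abc1[:, 1], abc1[:, 2])
    H2, K2, *_ = _curvatures(abc2[:, 0], abc2[:, 1], abc2[:, 2])
    dH, dK = H1 - H2, K1 - K2
    out_H = chauvenet_flags(dH)
    out_K = chauvenet_flags(dK)

    if selection == "abs":
        use_tilde_H = out_H & (np.abs(H2) < np.abs(H1))
        use_tilde_K = out_K & (np.abs(K2) < np.abs(K1))
    else:
        use_tilde_H = out_H & (H2 < H1)
        use_tilde_K = out_K & (K2 < K1)
    H = np.where(use_tilde_H, H2, H1)
    K = np.where(use_tilde_K, K2, K1)

    disc = np.maximum(H * H - K, 0.0)
    root = np.sqrt(disc)
    return CurvatureField(
        H=H, K=K, k1=H + root, k2=H - root,
        k_geo=np.sign(K) * np.sqrt(np.abs(K)),
        H1=H1, K1=K1, H2=H2, K2=K2, dH=dH, dK=dK,
        mu_dH=float(dH.mean()), sigma_dH=float(dH.std(ddof=1)),
        mu_dK=float(dK.mean()), sigma_dK=float(dK.std(ddof=1)),
        outlier_H=out_H, outlier_K=out_K,
    )


def total_curvature(field: CurvatureField, surface: TriSurface) -> float:
    """Vertex-area-weighted integral of K over a closed surface.

    By Gauss–Bonnet this approximates 2*pi*chi; an open surface (boundary
    geodesic-curvature terms missing) is rejected.
    """
    from .surfaces import validate_surface
    report = validate_surface(surface)
    if not report.closed:
        raise SurfaceError("total_curvature requires a closed surface "
                           "(boundary terms are out of scope)")
    return float(np.dot(field.K, surface.vertex_areas(folded=False)))


def find_hot_spots(field: CurvatureField, surface: TriSurface,
                   k_threshold: float, min_separation: float = 0.0
                   ) -> np.ndarray:
    """Vertices of strongly negative Gaussian curvature (nucleation spots).

    Local minima of K with K < ``k_threshold``, greedily thinned so returned
    vertices are at least ``min_separation`` apart in geodesic (edge-graph)
    distance; sorted by ascending K (most negative first).
    """
    if k_threshold >= 0:
        raise ValueError("k_threshold must be negative")
    K = field.K
    adj = surface.vertex_adjacency(folded=False)
    candidates = []
    for v in range(surface.n_vertices):
        nbrs = adj.indices[adj.indptr[v]:adj.indptr[v + 1]]
        if K[v] < k_threshold and len(nbrs) and (K[v] <= K[nbrs]).all():
            candidates.append(v)
    if not candidates:
        return np.array([], dtype=np.int64)
    candidates = sorted(candidates, key=lambda v: K[v])
    if min_separation <= 0:
        return np.array(candidates, dtype=np.int64)

    # greedy thinning by geodesic separation
    from .paths import _edge_graph
    g = _edge_graph(surface)
    kept: List[int] = []
    for v in candidates:
        if not kept:
            kept.append(v)
            continue
        dist = dijkstra(g, directed=False, indices=v, limit=min_separation)
        if all(dist[u] >= min_separation for u in kept):
            kept.append(v)
    return np.array(kept, dtype=np.int64)
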