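"""Triangulated surfaces: container, validation, and synthetic fixtures.

Everything downstream (diffusion operators, curvature estimation, geodesics,
scattering experiments) runs on a :class:`TriSurface` — an embedded triangle
mesh with optional periodic vertex identification.  The synthetic generators
cover the domains used throughout: a flat sheet with a single rotationally
symmetric bump (the model sulcal indent), canonical curvature fixtures
(sphere, torus, saddle), and a randomly ondulated "gyrified" sheet standing
in for real cortex.

Length units are dimensionless model units; when a mesh represents cortex an
``mm_per_unit`` scale may be attached as metadata, but no computation uses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components


class SurfaceError(ValueError):
    """Raised for invalid mesh construction arguments or broken invariants."""


# ---------------------------------------------------------------------------
# Core container
# ---------------------------------------------------------------------------

@dataclass
class TriSurface:
    """An embedded triangle mesh.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions.
    faces : (m, 3) int array
        0-based vertex index triples, right-handed winding with outward
        (closed surfaces) or +z (sheets) normals.
    dof_map : (n,) int array, optional
        Maps each vertex to a degree-of-freedom index.  Periodic boundaries
        are realised by identifying vertices: ghost vertices on one seam map
        to the dof of their partner on the opposite seam, so solvers see a
        closed operator.  Defaults to the identity.
    grid_shape : (nx, ny) tuple, optional
        For structured sheets, the cell counts of the generating grid; used
        by the experiment protocols to translate fields by whole cells.
    grid_extent : (Lx, Ly) tuple, optional
        Physical extent of the generating sheet.
    mm_per_unit : float, optional
        Metadata only: physical scale when the mesh represents cortex.
    """

    vertices: np.ndarray
    faces: np.ndarray
    dof_map: Optional[np.ndarray] = None
    grid_shape: Optional[Tuple[int, int]] = None
    grid_extent: Optional[Tuple[float, float]] = None
    mm_per_unit: Optional[float] = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise SurfaceError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise SurfaceError("faces must be an (m, 3) array")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise SurfaceError("face indices out of range")
        if self.dof_map is not None:
            self.dof_map = np.ascontiguousarray(self.dof_map, dtype=np.int64)
            if self.dof_map.shape != (len(self.vertices),):
                raise SurfaceError("dof_map must have one entry per vertex")

    # -- basic sizes -------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_dofs(self) -> int:
        if self.dof_map is None:
            return self.n_vertices
        return int(self.dof_map.max()) + 1 if len(self.dof_map) else 0

    @property
    def folded_faces(self) -> np.ndarray:
        """Faces with vertex indices mapped through ``dof_map``."""
        if self.dof_map is None:
            return self.faces
        return self.dof_map[self.faces]

    @property
    def dof_positions(self) -> np.ndarray:
        """Representative coordinates for each dof (first mapped vertex)."""
        if self.dof_map is None:
            return self.vertices
        pos = np.empty((self.n_dofs, 3))
        # reversed so the first occurrence wins
        pos[self.dof_map[::-1]] = self.vertices[::-1]
        return pos

    # -- geometry ----------------------------------------------------------

    @property
    def face_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return n

    @property
    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals, axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    def vertex_areas(self, folded: bool = True) -> np.ndarray:
        """Barycentric vertex areas: one third of incident triangle areas.

        Positive, and a partition of unity of the total area.  With
        ``folded=True`` areas accumulate onto dofs (periodic seams counted
        once per triangle, as they should be).
        """
        fa = self.face_areas
        faces = self.folded_faces if folded else self.faces
        n = self.n_dofs if folded else self.n_vertices
        out = np.zeros(n)
        np.add.at(out, faces.ravel(), np.repeat(fa / 3.0, 3))
        return out

    def edges(self, folded: bool = True) -> np.ndarray:
        """Unique undirected edges as an (e, 2) sorted-index array."""
        faces = self.folded_faces if folded else self.faces
        e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                            faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def vertex_adjacency(self, folded: bool = False) -> csr_matrix:
        e = self.edges(folded=folded)
        n = self.n_dofs if folded else self.n_vertices
        data = np.ones(2 * len(e), dtype=np.int8)
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()

    def with_heights(self, z: np.ndarray) -> "TriSurface":
        v = self.vertices.copy()
        v[:, 2] = z
        return replace(self, vertices=v)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class SurfaceReport:
    """Result of :func:`validate_surface` — problems are reported, not thrown."""

    n_vertices: int
    n_faces: int
    n_components: int
    euler_characteristics: Tuple[int, ...]   # per component, V - E + F
    closed: bool                             # no boundary edges anywhere
    n_boundary_loops: int
    manifold: bool                           # every edge in <= 2 faces
    oriented: bool                           # shared edges wound oppositely
    n_zero_area_faces: int

    @property
    def euler_characteristic(self) -> int:
        return sum(self.euler_characteristics)

    @property
    def ok(self) -> bool:
        return self.manifold and self.oriented and self.n_zero_area_faces == 0


def validate_surface(surface: TriSurface, area_tol: float = 1e-12) -> SurfaceReport:
    """Check manifoldness, orientation, Euler characteristic and boundaries.

    Pure function; operates on the folded (periodic-identified) connectivity,
    so a periodic sheet reports as a closed torus-topology component.
    """
    faces = surface.folded_faces
    n = surface.n_dofs

    directed = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                               faces[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    manifold = bool((counts <= 2).all())

    # orientation: an interior edge must appear once in each direction
    dir_uniq, dir_counts = np.unique(directed, axis=0, return_counts=True)
    oriented = bool((dir_counts == 1).all())

    boundary_edges = uniq[counts == 1]
    closed = len(boundary_edges) == 0

    n_loops = _count_boundary_loops(boundary_edges, n)

    # per-component Euler characteristic
    n_comp, labels = connected_components(surface.vertex_adjacency(folded=True),
                                          directed=False)
    chis = []
    for c in range(n_comp):
        vc = int((labels == c).sum())
        ec = int((labels[uniq[:, 0]] == c).sum())
        fc = int((labels[faces[:, 0]] == c).sum())
        chis.append(vc - ec + fc)

    return SurfaceReport(
        n_vertices=surface.n_vertices,
        n_faces=surface.n_faces,
        n_components=n_comp,
        euler_characteristics=tuple(chis),
        closed=closed,
        n_boundary_loops=n_loops,
        manifold=manifold,
        oriented=oriented,
        n_zero_area_faces=int((surface.face_areas <= area_tol).sum()),
    )


def _count_boundary_loops(boundary_edges: np.ndarray, n: int) -> int:
    if len(boundary_edges) == 0:
        return 0
    data = np.ones(2 * len(boundary_edges), dtype=np.int8)
    rows = np.concatenate([boundary_edges[:, 0], boundary_edges[:, 1]])
    cols = np.concatenate([boundary_edges[:, 1], boundary_edges[:, 0]])
    g = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    n_comp, labels = connected_components(g, directed=False)
    on_boundary = np.zeros(n, dtype=bool)
    on_boundary[boundary_edges.ravel()] = True
    return len(np.unique(labels[on_boundary]))


# ---------------------------------------------------------------------------
# Bump profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BumpSpec:
    """Rotationally symmetric cosine-squared bump, h(r) = A cos^2(pi r / 2R).

    Defaults (amplitude 20, support radius 20) are the published sulcal-indent
    profile; the scattering study also uses much lower altitudes.
    """

    center: Tuple[float, float] = (0.0, 0.0)
    amplitude: float = 20.0
    support_radius: float = 20.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise SurfaceError("bump amplitude must be >= 0")
        if self.support_radius <= 0:
            raise SurfaceError("bump support_radius must be > 0")


def bump_height(r, spec: BumpSpec = BumpSpec()):
    """Height of the bump profile at radial distance ``r`` from its center.

    ``A * cos^2(pi * r / (2 * R))`` for ``r <= R``, zero beyond; continuous
    at the support edge.  Accepts scalars or arrays; negative ``r`` is an
    error.
    """
    r_arr = np.asarray(r, dtype=np.float64)
    if np.any(r_arr < 0):
        raise SurfaceError("radial distance r must be >= 0")
    h = np.where(
        r_arr <= spec.support_radius,
        spec.amplitude * np.cos(np.pi * r_arr / (2.0 * spec.support_radius)) ** 2,
        0.0,
    )
    if np.isscalar(r) or r_arr.ndim == 0:
        return float(h)
    return h


# ---------------------------------------------------------------------------
# Sheet generators
# ---------------------------------------------------------------------------

def _grid_sheet(extent: Tuple[float, float], resolution: float,
                boundary: str) -> TriSurface:
    """Structured triangulated rectangle centred at the origin.

    ``boundary`` is ``"no_flux"`` (open sheet, natural boundary) or
    ``"periodic"`` (opposite seams identified through ``dof_map``; the
    solver then sees a torus-topology operator that mimics an infinite
    domain).  A uniform diagonal split keeps every interior vertex on six
    triangles, so the cotangent operator reduces exactly to the standard
    five-point Laplacian on the flat sheet.
    """
    if boundary not in ("no_flux", "periodic"):
        raise SurfaceError(f"unknown boundary kind {boundary!r}")
    if resolution <= 0:
        raise SurfaceError("resolution must be > 0")
    Lx, Ly = float(extent[0]), float(extent[1])
    nx = max(2, int(round(Lx / resolution)))
    ny = max(2, int(round(Ly / resolution)))
    xs = np.linspace(-Lx / 2, Lx / 2, nx + 1)
    ys = np.linspace(-Ly / 2, Ly / 2, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    vertices = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])

    def vid(i, j):
        return i * (ny + 1) + j

    faces = []
    for i in range(nx):
        for j in range(ny):
            v00, v10 = vid(i, j), vid(i + 1, j)
            v11, v01 = vid(i + 1, j + 1), vid(i, j + 1)
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    faces = np.array(faces, dtype=np.int64)

    dof_map = None
    if boundary == "periodic":
        ii, jj = np.meshgrid(np.arange(nx + 1), np.arange(ny + 1),
                             indexing="ij")
        key = (ii.ravel() % nx) * ny + (jj.ravel() % ny)
        _, dof_map = np.unique(key, return_inverse=True)
        dof_map = dof_map.astype(np.int64)

    return TriSurface(vertices, faces, dof_map=dof_map,
                      grid_shape=(nx, ny), grid_extent=(Lx, Ly))


def make_bump_sheet(extent: Tuple[float, float] = (120.0, 80.0),
                    resolution: float = 1.0,
                    spec: BumpSpec = BumpSpec(),
                    boundary: str = "periodic") -> TriSurface:
    """Flat sheet carrying a single bump; exactly flat outside the support.

    The sheet must strictly contain the bump support so periodic seams stay
    flat (heights then agree at identified vertices).
    """
    cx, cy = spec.center
    if (abs(cx) + spec.support_radius >= extent[0] / 2
            or abs(cy) + spec.support_radius >= extent[1] / 2):
        raise SurfaceError("bump support must lie strictly inside the extent")
    sheet = _grid_sheet(extent, resolution, boundary)
    r = np.hypot(sheet.vertices[:, 0] - cx, sheet.vertices[:, 1] - cy)
    return sheet.with_heights(bump_height(r, spec))


def make_flat_sheet(extent: Tuple[float, float] = (120.0, 80.0),
                    resolution: float = 1.0,
                    boundary: str = "periodic") -> TriSurface:
    """Flat rectangular sheet (degenerate bump sheet)."""
    return _grid_sheet(extent, resolution, boundary)


def make_ondulated_sheet(extent: Tuple[float, float] = (100.0, 100.0),
                         resolution: float = 1.0,
                         seed: int = 0,
                         n_bumps: int = 12,
                         amplitude_range: Tuple[float, float] = (2.0, 6.0),
                         support_range: Tuple[float, float] = (5.0, 12.0),
                         boundary: str = "no_flux") -> TriSurface:
    """Randomly ondulated sheet emulating smaller gyral folds and sulci.

    A superposition of ``n_bumps`` randomly placed cosine-squared profiles
    with random sign (gyral fold up, sulcal indent down); overlapping
    supports add.  Deterministic for a fixed ``seed``.
    """
    if amplitude_range[0] < 0 or support_range[0] <= 0:
        raise SurfaceError("amplitude and support ranges must be positive")
    rng = np.random.default_rng(seed)
    sheet = _grid_sheet(extent, resolution, boundary)
    z = np.zeros(sheet.n_vertices)
    for _ in range(n_bumps):
        cx = rng.uniform(-extent[0] / 2, extent[0] / 2)
        cy = rng.uniform(-extent[1] / 2, extent[1] / 2)
        amp = rng.uniform(*amplitude_range) * rng.choice([-1.0, 1.0])
        sup = rng.uniform(*support_range)
        r = np.hypot(sheet.vertices[:, 0] - cx, sheet.vertices[:, 1] - cy)
        prof = np.where(r <= sup, np.cos(np.pi * r / (2 * sup)) ** 2, 0.0)
        z += amp * prof
    return sheet.with_heights(z)


# ---------------------------------------------------------------------------
# Canonical closed / curved fixtures
# ---------------------------------------------------------------------------

def _icosahedron() -> Tuple[np.ndarray, np.ndarray]:
    phi = (1 + np.sqrt(5)) / 2
    v = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=np.float64)
    v /= np.linalg.norm(v[0])
    f = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    return v, f


def _subdivide(v: np.ndarray, f: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """One loop of 1->4 midpoint subdivision."""
    cache: dict = {}
    verts = list(v)

    def midpoint(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        if key not in cache:
            cache[key] = len(verts)
            verts.append((verts[a] + verts[b]) / 2.0)
        return cache[key]

    new_f = []
    for a, b, c in f:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_f += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    return np.array(verts), np.array(new_f, dtype=np.int64)


def make_sphere(radius: float = 10.0, subdivisions: int = 3) -> TriSurface:
    """Icosphere of the given radius; watertight with outward normals."""
    if radius <= 0:
        raise SurfaceError("sphere radius must be > 0")
    v, f = _icosahedron()
    for _ in range(subdivisions):
        v, f = _subdivide(v, f)
    v = radius * v / np.linalg.norm(v, axis=1, keepdims=True)
    return TriSurface(v, f)


def make_torus(major_radius: float = 3.0, minor_radius: float = 1.0,
               n_major: int = 64, n_minor: int = 24) -> TriSurface:
    """Parametric torus, closed by index wrapping; outward normals."""
    R, r = major_radius, minor_radius
    if r <= 0 or R <= r:
        raise SurfaceError("torus needs major_radius > minor_radius > 0")
    u = 2 * np.pi * np.arange(n_major) / n_major        # around the hole
    t = 2 * np.pi * np.arange(n_minor) / n_minor        # around the tube
    U, T = np.meshgrid(u, t, indexing="ij")
    x = (R + r * np.cos(T)) * np.cos(U)
    y = (R + r * np.cos(T)) * np.sin(U)
    z = r * np.sin(T)
    vertices = np.column_stack([x.ravel(), y.ravel(), z.ravel()])

    def vid(i, j):
        return (i % n_major) * n_minor + (j % n_minor)

    faces = []
    for i in range(n_major):
        for j in range(n_minor):
            v00, v10 = vid(i, j), vid(i + 1, j)
            v11, v01 = vid(i + 1, j + 1), vid(i, j + 1)
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    return TriSurface(vertices, np.array(faces, dtype=np.int64))


def make_saddle_patch(half_extent: float = 10.0, resolution: float = 0.5,
                      curvature_scale: float = 20.0) -> TriSurface:
    """Saddle z = (x^2 - y^2)/s over a square patch (negative K everywhere)."""
    if curvature_scale <= 0:
        raise SurfaceError("curvature_scale must be > 0")
    sheet = _grid_sheet((2 * half_extent, 2 * half_extent), resolution,
                        "no_flux")
    x, y = sheet.vertices[:, 0], sheet.vertices[:, 1]
    return sheet.with_heights((x ** 2 - y ** 2) / curvature_scale)


def make_canonical_surface(kind: str, resolution: float = 0.5,
                           **params) -> TriSurface:
    """Dispatch constructor for the canonical fixtures.

    ``kind`` is ``sphere`` (param ``radius``), ``torus`` (``major_radius``,
    ``minor_radius``) or ``saddle_patch`` (``half_extent``,
    ``curvature_scale``).
    """
    if kind == "sphere":
        radius = params.get("radius", 10.0)
        # pick subdivisions so the edge length roughly matches resolution
        subdiv = params.get("subdivisions")
        if subdiv is None:
            edge0 = radius * 1.1          # icosahedron edge ~ 1.05 R
            subdiv = max(1, int(np.ceil(np.log2(edge0 / resolution))))
            subdiv = min(subdiv, 6)
        return make_sphere(radius, subdiv)
    if kind == "torus":
        R = params.get("major_radius", 3.0)
        r = params.get("minor_radius", 1.0)
        n_major = params.get("n_major", max(16, int(2 * np.pi * R / resolution)))
        n_minor = params.get("n_minor", max(12, int(2 * np.pi * r / resolution)))
        return make_torus(R, r, n_major, n_minor)
    if kind == "saddle_patch":
        return make_saddle_patch(params.get("half_extent", 10.0), resolution,
                                 params.get("curvature_scale", 20.0))
    raise SurfaceError(f"unknown canonical surface kind {kind!r}")
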