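"""Mesh containers, synthetic test geometry, and pairwise distances.

Triangulated surfaces and tetrahedral volumes are the discretized domains on
which scalar brain maps live.  Coordinates are always millimetres and all
connectivity is 0-based.  Synthetic generators (icospheres, bumpy spheres,
tetrahedral balls) stand in for cortical and subcortical meshes in tests and
benchmarks; they are pure functions of their arguments and seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
import warnings

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial.distance import pdist

__all__ = [
    "TriangleMesh",
    "TetMesh",
    "SurfaceMap",
    "make_icosphere",
    "make_bumpy_sphere",
    "make_tet_ball",
    "extract_submesh",
    "pairwise_distances",
    "PairDistances",
]


def _as_f64(a) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(a, dtype=np.float64))


@dataclass(frozen=True)
class TriangleMesh:
    """Triangulated surface: vertex coordinates (mm) and 0-based face triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = _as_f64(self.vertices)
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (N, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError(f"faces must be (F, 3), got {f.shape}")
        if v.shape[0] < 4:
            raise ValueError(f"need at least 4 vertices, got {v.shape[0]}")
        if f.size and (f.min() < 0 or f.max() >= v.shape[0]):
            bad = np.unique(np.nonzero((f < 0) | (f >= v.shape[0]))[0])
            raise ValueError(f"face indices out of range [0, {v.shape[0]}) in faces {bad.tolist()}")
        if f.size:
            dup = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            if dup.any():
                raise ValueError(f"degenerate faces (repeated vertex): {np.nonzero(dup)[0].tolist()}")
            areas = triangle_areas(v, f)
            bad = np.nonzero(areas <= 0)[0]
            if bad.size:
                raise ValueError(f"zero-area faces: {bad.tolist()}")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, sorted pairs."""
        f = self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    @property
    def boundary_edges(self) -> np.ndarray:
        """Edges belonging to exactly one face (empty for closed surfaces)."""
        f = self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + len(self.faces)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.vertices.tobytes())
        h.update(self.faces.tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class TetMesh:
    """Tetrahedral volume mesh: coordinates (mm) and 0-based tet quadruples.

    Tets are canonicalized to positive signed volume on construction.
    """

    vertices: np.ndarray
    tets: np.ndarray

    def __post_init__(self):
        v = _as_f64(self.vertices)
        t = np.ascontiguousarray(np.asarray(self.tets, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (N, 3), got {v.shape}")
        if t.ndim != 2 or t.shape[1] != 4:
            raise ValueError(f"tets must be (T, 4), got {t.shape}")
        if t.size and (t.min() < 0 or t.max() >= v.shape[0]):
            raise ValueError("tet indices out of range")
        vol = tet_volumes(v, t)
        flip = vol < 0
        if flip.any():
            t = t.copy()
            t[flip] = t[flip][:, [0, 2, 1, 3]]
            vol = np.abs(vol)
        bad = np.nonzero(vol <= 0)[0]
        if bad.size:
            raise ValueError(f"zero-volume tets: {bad.tolist()}")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "tets", np.ascontiguousarray(t))

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.vertices.tobytes())
        h.update(self.tets.tobytes())
        return h.hexdigest()[:16]


@dataclass
class SurfaceMap:
    """Per-vertex scalar map with a validity mask (False = medial wall / NaN)."""

    values: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        v = _as_f64(self.values).ravel()
        if self.mask is None:
            m = np.isfinite(v)
        else:
            m = np.asarray(self.mask, dtype=bool).ravel()
            if m.shape != v.shape:
                raise ValueError(f"mask length {m.size} != values length {v.size}")
            m = m & np.isfinite(v)
        self.values = v
        self.mask = m

    @property
    def n_vertices(self) -> int:
        return self.values.size

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


def triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    p = vertices[faces]
    return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


def tet_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = vertices[tets]
    return np.einsum("ij,ij->i", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), p[:, 3] - p[:, 0]) / 6.0


def surface_area(mesh: TriangleMesh) -> float:
    return float(triangle_areas(mesh.vertices, mesh.faces).sum())


def mean_edge_length(mesh: TriangleMesh) -> float:
    e = mesh.edges
    return float(np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1).mean())


# ---------------------------------------------------------------------------
# synthetic generators

def make_icosphere(subdivisions: int, radius: float = 1.0) -> TriangleMesh:
    """Icosahedron subdivided `subdivisions` times, vertices on the sphere.

    Vertex count is 10*4**s + 2, face count 20*4**s.
    """
    if not 0 <= subdivisions <= 8:
        raise ValueError("subdivisions must be in [0, 8]")
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces))


def make_bumpy_sphere(
    subdivisions: int, radius: float = 1.0, bump_amplitude: float = 0.1, seed: int = 0
) -> TriangleMesh:
    """Icosphere with a band-limited random radial displacement field.

    The displacement is a random combination of the sphere's first few
    non-constant Laplace eigenmodes, scaled so its maximum equals
    ``bump_amplitude * radius``.  Breaks the exact eigenvalue degeneracy of
    the sphere while keeping the mesh valid.
    """
    if not 0 <= bump_amplitude < 0.5:
        raise ValueError("bump_amplitude must be in [0, 0.5)")
    base = make_icosphere(subdivisions, radius)
    if bump_amplitude == 0:
        return base
    from .laplace import assemble_fem, compute_eigenbasis

    basis = compute_eigenbasis(assemble_fem(base), n_modes=16)
    rng = np.random.default_rng(seed)
    # skip the constant mode; weight coarse modes more heavily
    coeffs = rng.standard_normal(basis.modes.shape[1] - 1) / np.sqrt(np.arange(1, basis.modes.shape[1]))
    disp = basis.modes[:, 1:] @ coeffs
    disp *= bump_amplitude * radius / np.max(np.abs(disp))
    unit = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)
    return TriangleMesh(base.vertices + disp[:, None] * unit, base.faces)


def _icosphere_subdiv_for_edge(radius: float, target_edge: float) -> int:
    # icosahedron edge ~1.0515 r, halved per subdivision
    s = 0
    while 1.0515 * radius / (2**s) > target_edge and s < 7:
        s += 1
    return s


def make_tet_ball(radius: float, target_edge: float) -> TetMesh:
    """Delaunay-tetrahedralized ball from concentric icosphere shells.

    The boundary approximates the sphere of the given radius; shell spacing
    and surface resolution both track ``target_edge``.
    """
    if not 0 < target_edge < radius:
        raise ValueError("require 0 < target_edge < radius")
    from scipy.spatial import Delaunay

    n_shells = max(2, int(round(radius / target_edge)))
    pts = [np.zeros((1, 3))]
    for k in range(1, n_shells + 1):
        r_k = radius * k / n_shells
        s = _icosphere_subdiv_for_edge(r_k, target_edge)
        pts.append(make_icosphere(s, r_k).vertices)
    points = np.vstack(pts)
    tri = Delaunay(points, qhull_options="QJ")
    tets = tri.simplices
    vols = np.abs(tet_volumes(points, tets))
    tets = tets[vols > 1e-10 * vols.mean()]  # drop joggle slivers
    used = np.zeros(len(points), dtype=bool)
    used[np.unique(tets)] = True
    remap = np.cumsum(used) - 1
    return TetMesh(points[used], remap[tets])


# ---------------------------------------------------------------------------
# submesh extraction

def extract_submesh(mesh: TriangleMesh, keep: np.ndarray, largest_component_only: bool = False):
    """Restrict a mesh to the vertices flagged in `keep`.

    Faces survive iff all three corners are kept.  Returns the open submesh
    and the old->new index table (−1 for dropped vertices).  Warns when the
    result has several connected components.
    """
    keep = np.asarray(keep, dtype=bool)
    if keep.size != mesh.n_vertices:
        raise ValueError("keep mask length mismatch")
    face_keep = keep[mesh.faces].all(axis=1)
    faces = mesh.faces[face_keep]
    used = np.zeros(mesh.n_vertices, dtype=bool)
    used[np.unique(faces)] = True
    # isolated kept vertices (no surviving face) are dropped too
    new_index = np.full(mesh.n_vertices, -1, dtype=np.int64)
    new_index[used] = np.arange(used.sum())
    sub = TriangleMesh(mesh.vertices[used], new_index[faces])

    e = sub.edges
    g = sp.coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(sub.n_vertices, sub.n_vertices)
    )
    n_comp, labels = sp.csgraph.connected_components(g, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        warnings.warn(f"submesh has {n_comp} components with sizes {sizes.tolist()}")
        if largest_component_only:
            comp_keep = labels == np.argmax(sizes)
            full_keep = np.zeros(mesh.n_vertices, dtype=bool)
            full_keep[np.nonzero(used)[0][comp_keep]] = True
            return extract_submesh(mesh, full_keep)
    return sub, new_index


def polar_cap_mask(mesh: TriangleMesh, axis: int = 2, cap_fraction: float = 0.2) -> np.ndarray:
    """Boolean keep-mask that removes the top `cap_fraction` of vertices along
    an axis — a synthetic stand-in for cutting away a medial wall."""
    coord = mesh.vertices[:, axis]
    thresh = np.quantile(coord, 1.0 - cap_fraction)
    return coord < thresh


# ---------------------------------------------------------------------------
# pairwise distances

@dataclass
class PairDistances:
    """Condensed set of vertex pairs with separations in mm."""

    pairs: np.ndarray       # (P, 2) vertex indices, i < j
    distances: np.ndarray   # (P,) mm
    metric: str
    vertex_subset: np.ndarray = None  # indices sampled, if subsampled

    def __len__(self):
        return len(self.distances)


class HeatGeodesics:
    """Single-source geodesic distances on a triangle mesh (heat method).

    Prefactorizes the heat and Poisson solves so repeated sources are cheap.
    Distances are clipped from below by the Euclidean chord, which is a true
    lower bound on the geodesic.
    """

    def __init__(self, mesh: TriangleMesh):
        from .laplace import assemble_fem

        self.mesh = mesh
        fem = assemble_fem(mesh)
        A = fem.stiffness.tocsc()
        mass_lumped = np.asarray(fem.mass.sum(axis=1)).ravel()
        t = mean_edge_length(mesh) ** 2
        self._heat = spla.factorized((sp.diags(mass_lumped) + t * A).tocsc())
        shift = 1e-8 * mass_lumped.mean()
        self._poisson = spla.factorized((A + shift * sp.eye(mesh.n_vertices)).tocsc())
        self._precompute_face_geometry()

    def _precompute_face_geometry(self):
        v, f = self.mesh.vertices, self.mesh.faces
        p = v[f]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        self._double_area = np.linalg.norm(n, axis=1)
        self._normal = n / self._double_area[:, None]
        # edge vectors opposite each corner
        self._e = np.stack([p[:, 2] - p[:, 1], p[:, 0] - p[:, 2], p[:, 1] - p[:, 0]], axis=1)
        self._faces = f

    def distance_from(self, source: int) -> np.ndarray:
        n = self.mesh.n_vertices
        delta = np.zeros(n)
        delta[source] = 1.0
        u = self._heat(delta)
        # per-face gradient of u, negated and normalized
        uf = u[self._faces]
        grad = np.einsum("fc,fce->fe", uf, np.cross(self._normal[:, None, :], self._e)) / self._double_area[:, None]
        norm = np.linalg.norm(grad, axis=1)
        norm[norm == 0] = 1.0
        x = -grad / norm[:, None]
        # integrated divergence at vertices via per-corner cotangent weights
        div = np.zeros(n)
        p = self.mesh.vertices[self._faces]
        for c in range(3):
            i = self._faces[:, c]
            e1 = p[:, (c + 1) % 3] - p[:, c]
            e2 = p[:, (c + 2) % 3] - p[:, c]
            o1 = p[:, (c + 1) % 3] - p[:, (c + 2) % 3]
            cot1 = _cotangent(p[:, c] - p[:, (c + 2) % 3], -o1)   # angle at corner c+2
            cot2 = _cotangent(p[:, c] - p[:, (c + 1) % 3], o1)    # angle at corner c+1
            contrib = 0.5 * (cot1 * np.einsum("fe,fe->f", e1, x) + cot2 * np.einsum("fe,fe->f", e2, x))
            np.add.at(div, i, contrib)
        phi = self._poisson(div)
        phi -= phi[source]
        if phi.mean() < 0:
            phi = -phi
        chord = np.linalg.norm(self.mesh.vertices - self.mesh.vertices[source], axis=1)
        return np.maximum(phi, chord)


def _cotangent(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cotangent of the angle between row vectors a and b."""
    cross = np.linalg.norm(np.cross(a, b), axis=-1)
    cross = np.maximum(cross, 1e-300)
    return np.einsum("...e,...e->...", a, b) / cross


def pairwise_distances(
    mesh,
    metric: str = "euclidean",
    subsample: int | None = None,
    seed: int = 0,
) -> PairDistances:
    """Condensed pairwise vertex distances.

    ``metric='geodesic'`` (triangle meshes only) uses the heat method;
    ``'euclidean'`` uses straight-line distances and is the only option for
    tetrahedral meshes.  Above 5,000 vertices a seeded uniform vertex
    subsample (default 500) is taken; pass ``subsample`` to control it.
    """
    n = mesh.n_vertices
    if subsample is None and n > 5000:
        subsample = 500
    if subsample is not None:
        if subsample > n:
            raise ValueError(f"subsample {subsample} exceeds vertex count {n}")
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=subsample, replace=False))
    else:
        idx = np.arange(n)

    ii, jj = np.triu_indices(len(idx), k=1)
    pairs = np.column_stack([idx[ii], idx[jj]])

    if metric == "euclidean":
        d = pdist(mesh.vertices[idx])
    elif metric == "geodesic":
        if not isinstance(mesh, TriangleMesh):
            raise ValueError("geodesic distances require a triangle mesh")
        solver = HeatGeodesics(mesh)
        m = len(idx)
        dmat = np.empty((m, m))
        for a, s in enumerate(idx):
            dmat[a] = solver.distance_from(int(s))[idx]
        dmat = 0.5 * (dmat + dmat.T)  # symmetrize the solver output
        d = dmat[ii, jj]
        chord = pdist(mesh.vertices[idx])
        d = np.maximum(d, chord)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return PairDistances(pairs=pairs, distances=d, metric=metric,
                         vertex_subset=idx if subsample is not None else None)
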