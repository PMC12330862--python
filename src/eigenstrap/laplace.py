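"""Linear FEM Laplace-Beltrami operators and their eigenmodes.

The generalized eigenproblem  A psi = lambda B psi  with the P1 cotangent
stiffness A and consistent mass B discretizes the Helmholtz equation
Delta psi = -lambda psi on a triangle or tetrahedral mesh.  Meshes with
boundary get the natural (Neumann) condition for free: no constraint rows
are added, so the normal derivative is weakly zero along the boundary.

Eigenmodes are B-orthonormal, ordered by ascending eigenvalue, and carry a
deterministic sign convention (largest-magnitude entry positive).  The first
mode of a connected mesh is the constant with eigenvalue 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import SurfaceMap, TetMesh, TriangleMesh, tet_volumes, triangle_areas

__all__ = ["FemPair", "EigenBasis", "assemble_fem", "compute_eigenbasis",
           "mass_inner_product", "save_eigenbasis", "load_eigenbasis"]

# dense solve below this size: the benchmark meshes all qualify, and the
# dense path returns the full spectrum in one shot
_DENSE_LIMIT = 4096


@dataclass(frozen=True)
class FemPair:
    """Stiffness A (PSD, cotangent weights) and mass B (SPD) matrices."""

    stiffness: sp.csr_matrix
    mass: sp.csr_matrix
    mesh_id: str
    is_volume: bool = False

    @property
    def n(self) -> int:
        return self.stiffness.shape[0]


@dataclass(frozen=True)
class EigenBasis:
    """Mass-orthonormal LBO eigenmodes with ascending eigenvalues (mm^-2)."""

    modes: np.ndarray        # (N, M)
    eigenvalues: np.ndarray  # (M,)
    mass: sp.csr_matrix      # kept for inner products and reconstruction
    boundary_tag: str        # 'closed' | 'neumann-open'
    mesh_id: str

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def subset(self, n_modes: int) -> "EigenBasis":
        return EigenBasis(self.modes[:, :n_modes], self.eigenvalues[:n_modes],
                          self.mass, self.boundary_tag, self.mesh_id)


def _check_degenerate(measure: np.ndarray, kind: str):
    mean = measure.mean()
    bad = np.nonzero(measure < 1e-12 * mean)[0]
    if bad.size:
        raise ValueError(f"near-degenerate {kind} elements (<1e-12 of mean): {bad.tolist()}")


def assemble_fem(mesh) -> FemPair:
    """Assemble the P1 stiffness/mass pair for a triangle or tet mesh."""
    if isinstance(mesh, TriangleMesh):
        return _assemble_triangles(mesh)
    if isinstance(mesh, TetMesh):
        return _assemble_tets(mesh)
    raise TypeError(f"unsupported mesh type {type(mesh).__name__}")


def _assemble_triangles(mesh: TriangleMesh) -> FemPair:
    v, f = mesh.vertices, mesh.faces
    areas = triangle_areas(v, f)
    _check_degenerate(areas, "triangle")
    n = mesh.n_vertices

    rows, cols, a_vals, b_vals = [], [], [], []
    p = v[f]
    for c in range(3):
        i = f[:, (c + 1) % 3]
        j = f[:, (c + 2) % 3]
        # cotangent of the angle at corner c, opposite edge (i, j)
        e1 = p[:, (c + 1) % 3] - p[:, c]
        e2 = p[:, (c + 2) % 3] - p[:, c]
        cot = np.einsum("fe,fe->f", e1, e2) / (2.0 * areas)
        w = 0.5 * cot
        rows += [i, j, i, j]
        cols += [j, i, i, j]
        a_vals += [-w, -w, w, w]
        # consistent P1 mass: area/6 off-diagonal contribution per edge,
        # area/12 ... assembled below from the standard element matrix
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    a_vals = np.concatenate(a_vals)
    A = sp.coo_matrix((a_vals, (rows, cols)), shape=(n, n)).tocsr()

    # element mass matrix (area/12) * [[2,1,1],[1,2,1],[1,1,2]]
    br, bc, bv = [], [], []
    for ci in range(3):
        for cj in range(3):
            br.append(f[:, ci])
            bc.append(f[:, cj])
            bv.append(areas * (2.0 if ci == cj else 1.0) / 12.0)
    B = sp.coo_matrix((np.concatenate(bv), (np.concatenate(br), np.concatenate(bc))),
                      shape=(n, n)).tocsr()
    return FemPair(A, B, mesh.content_hash(), is_volume=False)


def _assemble_tets(mesh: TetMesh) -> FemPair:
    v, t = mesh.vertices, mesh.tets
    vols = tet_volumes(v, t)
    _check_degenerate(vols, "tet")
    n = mesh.n_vertices
    p = v[t]  # (T, 4, 3)

    # P1 shape-function gradients: solve for each tet the 4x3 gradient matrix
    # grad_k constant per element; stiffness entry = vol * grad_i . grad_j
    e = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=1)  # (T,3,3)
    inv = np.linalg.inv(e)  # rows: gradients of barycentric coords 1..3 wrt x
    g = np.empty((len(t), 4, 3))
    g[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)

    br, bc, av, bv = [], [], [], []
    for ci in range(4):
        for cj in range(4):
            br.append(t[:, ci])
            bc.append(t[:, cj])
            av.append(vols * np.einsum("te,te->t", g[:, ci], g[:, cj]))
            bv.append(vols * (2.0 if ci == cj else 1.0) / 20.0)
    rows = np.concatenate(br)
    cols = np.concatenate(bc)
    A = sp.coo_matrix((np.concatenate(av), (rows, cols)), shape=(n, n)).tocsr()
    B = sp.coo_matrix((np.concatenate(bv), (rows, cols)), shape=(n, n)).tocsr()
    return FemPair(A, B, mesh.content_hash(), is_volume=True)


def _fix_signs(modes: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(modes), axis=0)
    signs = np.sign(modes[idx, np.arange(modes.shape[1])])
    signs[signs == 0] = 1.0
    return modes * signs


def compute_eigenbasis(
    fem: FemPair,
    n_modes: int,
    solver_tolerance: float = 1e-10,
    boundary_tag: str | None = None,
) -> EigenBasis:
    """Solve A psi = lambda B psi for the `n_modes` smallest eigenvalues.

    If the requested cut falls inside a degenerate cluster (relative gap
    < 1e-8), the basis is extended to the cluster end so eigengroup
    rotations never see a split subspace.
    """
    n = fem.n
    if not 1 <= n_modes <= n:
        raise ValueError(f"n_modes must be in [1, {n}], got {n_modes}")
    A, B = fem.stiffness, fem.mass

    if n <= _DENSE_LIMIT:
        lam, vec = scipy.linalg.eigh(A.toarray(), B.toarray())
        lam = lam[: min(n_modes + 8, n)]
        vec = vec[:, : min(n_modes + 8, n)]
    else:
        k = min(n_modes + 8, n - 2)
        sigma = -1e-4 * A.diagonal().sum() / B.diagonal().sum()
        lam, vec = spla.eigsh(A, k=k, M=B, sigma=sigma, which="LM", tol=solver_tolerance)
        order = np.argsort(lam)
        lam, vec = lam[order], vec[:, order]

    lam = np.maximum(lam, 0.0)  # clip tiny negative roundoff on the null space
    # cluster completion
    m = n_modes
    scale = max(lam[min(m, len(lam)) - 1], 1e-300)
    while m < len(lam) and (lam[m] - lam[m - 1]) < 1e-8 * max(lam[m], scale):
        m += 1
    lam, vec = lam[:m], vec[:, :m]

    vec = _fix_signs(vec)
    if boundary_tag is None:
        boundary_tag = "closed"
    return EigenBasis(np.ascontiguousarray(vec), lam, B.tocsr(), boundary_tag, fem.mesh_id)


def eigenbasis_for_mesh(mesh, n_modes: int, _cache={}) -> EigenBasis:
    """Compute (and memoize per mesh-content hash) an eigenbasis for a mesh."""
    tag = "closed" if (isinstance(mesh, TetMesh) or len(mesh.boundary_edges) == 0) else "neumann-open"
    key = (mesh.content_hash(), n_modes, tag)
    if key not in _cache:
        _cache[key] = compute_eigenbasis(assemble_fem(mesh), n_modes, boundary_tag=tag)
    return _cache[key]


def mass_inner_product(basis: EigenBasis, surface_map) -> np.ndarray:
    """Modal coefficients beta = Psi^T B y for a fully valid map."""
    y = surface_map.values if isinstance(surface_map, SurfaceMap) else np.asarray(surface_map, float)
    if isinstance(surface_map, SurfaceMap) and not surface_map.mask.all():
        raise ValueError("map has masked vertices; use eigenstrap decomposition instead")
    if y.shape[0] != basis.modes.shape[0]:
        raise ValueError(f"map length {y.shape[0]} != basis vertex count {basis.modes.shape[0]}")
    return basis.modes.T @ (basis.mass @ y)


# ---------------------------------------------------------------------------
# serialization

def save_eigenbasis(basis: EigenBasis, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "modes.txt", basis.modes)
    np.savetxt(d / "eigenvalues.txt", basis.eigenvalues)
    # the mass matrix is re-derivable from the mesh; store only provenance
    (d / "provenance.json").write_text(json.dumps({
        "mesh_id": basis.mesh_id,
        "boundary_tag": basis.boundary_tag,
        "n_modes": int(basis.n_modes),
    }, indent=2))


def load_eigenbasis(directory, mass: sp.csr_matrix) -> EigenBasis:
    d = Path(directory)
    prov = json.loads((d / "provenance.json").read_text())
    modes = np.loadtxt(d / "modes.txt")
    eigenvalues = np.atleast_1d(np.loadtxt(d / "eigenvalues.txt"))
    if modes.ndim == 1:
        modes = modes[:, None]
    return EigenBasis(modes, eigenvalues, mass, prov["boundary_tag"], prov["mesh_id"])
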