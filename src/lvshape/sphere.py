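"""Area-preserving spherical parameterization of genus-0 surfaces.

The map is initialized by solving two Laplace problems on the mesh graph:

* a colatitude field between two poles placed at extremal vertices, with the
  harmonic level values redistributed so that the surface area above each
  latitude matches the corresponding spherical-cap area;
* a longitude field obtained by cutting the mesh along a pole-to-pole path
  (the "date line") and solving a Dirichlet problem with boundary values 0
  and 2*pi on the two sides of the cut.

The initial map is then refined by projected gradient descent on a per-face
area-distortion energy, with local Laplacian untangling of folded spherical
triangles.  The optimizer terminates when the energy stagnates (or the
iteration cap is reached); any remaining folded triangle is an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.sparse.linalg import spsolve

from .meshing import MeshError, SurfaceMesh


class ParameterizationError(RuntimeError):
    """Raised when the spherical map cannot be made bijective."""


@dataclass
class SphericalParam:
    """Per-vertex spherical coordinates of a parameterized surface."""

    theta: np.ndarray  # colatitude in [0, pi]
    phi: np.ndarray  # longitude in [0, 2*pi)
    points: np.ndarray  # (n, 3) unit vectors, redundant with (theta, phi)
    n_folded: int
    max_area_ratio: float
    median_area_ratio: float
    iterations: int
    converged: bool

    @property
    def n_vertices(self) -> int:
        return len(self.theta)


def sphere_to_angles(p: np.ndarray):
    """Unit vectors -> (colatitude, longitude in [0, 2*pi))."""
    theta = np.arccos(np.clip(p[:, 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(p[:, 1], p[:, 0]), 2.0 * np.pi)
    return theta, phi


def angles_to_sphere(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    st = np.sin(theta)
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def signed_spherical_areas(p: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Signed solid angles of spherical triangles (van Oosterom-Strackee)."""
    a, b, c = p[faces[:, 0]], p[faces[:, 1]], p[faces[:, 2]]
    num = np.einsum("ij,ij->i", a, np.cross(b, c))
    den = (
        1.0
        + np.einsum("ij,ij->i", a, b)
        + np.einsum("ij,ij->i", b, c)
        + np.einsum("ij,ij->i", c, a)
    )
    return 2.0 * np.arctan2(num, den)


def _euclidean_face_areas(p: np.ndarray, faces: np.ndarray):
    n = np.cross(p[faces[:, 1]] - p[faces[:, 0]], p[faces[:, 2]] - p[faces[:, 0]])
    return n, 0.5 * np.linalg.norm(n, axis=1)


def _laplacian(mesh: SurfaceMesh) -> sparse.csr_matrix:
    adj = mesh.vertex_adjacency()
    adj.data[:] = 1.0
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return sparse.diags(deg) - adj


def _solve_dirichlet(L: sparse.csr_matrix, fixed_idx, fixed_val, n: int) -> np.ndarray:
    free = np.setdiff1d(np.arange(n), fixed_idx)
    u = np.zeros(n)
    u[fixed_idx] = fixed_val
    A = L[np.ix_(free, free)].tocsc()
    b = -L[np.ix_(free, fixed_idx)] @ np.asarray(fixed_val, dtype=float)
    u[free] = spsolve(A, b)
    return u


def _pick_poles(mesh: SurfaceMesh):
    v = mesh.vertices - mesh.vertices.mean(axis=0)
    _, _, vt = np.linalg.svd(v, full_matrices=False)
    proj = v @ vt[0]
    return int(proj.argmax()), int(proj.argmin())


def _area_remapped_theta(mesh: SurfaceMesh, u: np.ndarray, north: int, south: int):
    """Map harmonic levels to colatitudes equalizing spherical-cap area."""
    _, fa = _euclidean_face_areas(mesh.vertices, mesh.faces)
    va = np.zeros(mesh.n_vertices)
    np.add.at(va, mesh.faces.ravel(), np.repeat(fa / 3.0, 3))
    order = np.argsort(u, kind="stable")
    cum = np.cumsum(va[order])
    frac = (cum - 0.5 * va[order]) / cum[-1]
    theta = np.empty(mesh.n_vertices)
    theta[order] = np.arccos(np.clip(1.0 - 2.0 * frac, -1.0, 1.0))
    theta[north], theta[south] = 0.0, np.pi
    return theta


def _directed_edge_faces(faces: np.ndarray) -> dict:
    """Map directed edge (a, b) -> index of the face containing it."""
    he = {}
    for fi, (a, b, c) in enumerate(faces):
        he[(a, b)] = fi
        he[(b, c)] = fi
        he[(c, a)] = fi
    return he


def _cut_path(mesh: SurfaceMesh, north: int, south: int) -> list:
    e = mesh.edges()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    g = sparse.coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
    g = (g + g.T).tocsr()
    _, pred = dijkstra(g, indices=north, return_predecessors=True)
    path = [south]
    while path[-1] != north:
        p = pred[path[-1]]
        if p < 0:
            raise ParameterizationError("mesh graph is disconnected")
        path.append(int(p))
    return path[::-1]  # north ... south


def _side_a_neighbours(mesh: SurfaceMesh, path: list) -> dict:
    """For each interior cut-path vertex, the set of neighbours on side A.

    Side A is the fan of faces swept counter-clockwise (in face orientation)
    from the outgoing path edge to the incoming one.
    """
    he = _directed_edge_faces(mesh.faces)
    faces = mesh.faces
    side_a: dict[int, set] = {}
    for i in range(1, len(path) - 1):
        v, p_prev, p_next = path[i], path[i - 1], path[i + 1]
        nbrs = set()
        w = p_next
        for _ in range(len(faces)):
            fi = he[(v, w)]
            tri = faces[fi]
            k = int(np.where(tri == v)[0][0])
            third = int(tri[(k + 2) % 3])  # vertex after w in cyclic order
            nbrs.add(w)
            nbrs.add(third)
            if third == p_prev:
                break
            w = third
        else:  # pragma: no cover
            raise ParameterizationError("fan walk around cut vertex did not close")
        side_a[v] = nbrs
    return side_a


def _initial_longitude(
    mesh: SurfaceMesh, L: sparse.csr_matrix, path: list
) -> np.ndarray:
    n = mesh.n_vertices
    north, south = path[0], path[-1]
    path_set = set(path)
    side_a = _side_a_neighbours(mesh, path)
    fixed = sorted(path_set)
    free = np.setdiff1d(np.arange(n), fixed)
    # adjacency restricted to free vertices, with path neighbours as boundary
    adj = mesh.vertex_adjacency()
    adj.data[:] = 1.0
    deg = np.asarray(adj.sum(axis=1)).ravel()
    b = np.zeros(n)
    rows = []
    for v in path[1:-1]:
        nbrs_a = side_a[v]
        cols = adj[v].indices
        for u in cols:
            if u in path_set:
                continue
            if u not in nbrs_a:
                b[u] += 2.0 * np.pi  # side B boundary value
    # poles connect both sides; drop them from the system entirely
    for pole in (north, south):
        for u in adj[pole].indices:
            if u not in path_set:
                deg[u] -= 1.0
    A = (sparse.diags(deg) - adj)[np.ix_(free, free)].tocsc()
    phi = np.zeros(n)
    phi[free] = spsolve(A, b[free])
    return np.mod(phi, 2.0 * np.pi)


def _fold_mask(p: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = p[faces[:, 0]], p[faces[:, 1]], p[faces[:, 2]]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) <= 0.0


def _untangle(p, faces, adj, max_rounds=80):
    """Laplacian-smooth vertices of folded faces until folds stop decreasing."""
    for _ in range(max_rounds):
        folded = _fold_mask(p, faces)
        nf = int(folded.sum())
        if nf == 0:
            return p, 0
        bad = np.zeros(len(p), dtype=bool)
        bad[faces[folded].ravel()] = True
        centroid = adj @ p
        centroid /= np.linalg.norm(centroid, axis=1, keepdims=True)
        p = p.copy()
        p[bad] = 0.4 * p[bad] + 0.6 * centroid[bad]
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return p, int(_fold_mask(p, faces).sum())


def _area_energy(p, faces, target_frac):
    """KL divergence sum(tau * log(tau / alpha)) of target vs realized area
    fractions; infinite barrier against collapsing spherical triangles."""
    _, a = _euclidean_face_areas(p, faces)
    a = np.maximum(a, 1e-300)
    frac = a / a.sum()
    return float((target_frac * np.log(target_frac / frac)).sum()), a


def _area_gradient(p, faces, target_frac):
    n, a = _euclidean_face_areas(p, faces)
    a = np.maximum(a, 1e-300)
    S = a.sum()
    w = -target_frac / a + 1.0 / S  # dE/da_f for the KL energy
    nhat = n / np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-300)
    g = np.zeros_like(p)
    v0, v1, v2 = p[faces[:, 0]], p[faces[:, 1]], p[faces[:, 2]]
    np.add.at(g, faces[:, 0], w[:, None] * 0.5 * np.cross(nhat, v2 - v1))
    np.add.at(g, faces[:, 1], w[:, None] * 0.5 * np.cross(nhat, v0 - v2))
    np.add.at(g, faces[:, 2], w[:, None] * 0.5 * np.cross(nhat, v1 - v0))
    return g


def distortion_ratios(mesh: SurfaceMesh, p: np.ndarray) -> np.ndarray:
    """Per-face ratio max(r, 1/r) of spherical / surface area fractions."""
    sph = np.abs(signed_spherical_areas(p, mesh.faces)) / (4.0 * np.pi)
    _, fa = _euclidean_face_areas(mesh.vertices, mesh.faces)
    surf = fa / fa.sum()
    r = np.where(sph > 0, sph / surf, np.inf)
    return np.maximum(r, 1.0 / r)


def spherical_parameterize(
    mesh: SurfaceMesh,
    max_iter: int = 10_000,
    tol_ratio: float = 1.5,
    stall_tol: float = 1e-6,
    step0: float = 0.05,
) -> SphericalParam:
    """Compute a bijective, area-distortion-minimizing map to the unit sphere."""
    mesh.validate_closed_manifold()
    if mesh.genus() != 0:
        raise MeshError(f"genus {mesh.genus()} surface cannot map to the sphere")

    north, south = _pick_poles(mesh)
    L = _laplacian(mesh)
    u = _solve_dirichlet(L, [north, south], [0.0, 1.0], mesh.n_vertices)
    theta = _area_remapped_theta(mesh, u, north, south)
    path = _cut_path(mesh, north, south)
    phi = _initial_longitude(mesh, L, path)
    p = angles_to_sphere(theta, phi)

    adj = mesh.vertex_adjacency()
    adj.data[:] = 1.0
    deg = np.asarray(adj.sum(axis=1)).ravel()
    adj = sparse.diags(1.0 / deg) @ adj

    _, fa = _euclidean_face_areas(mesh.vertices, mesh.faces)
    target = fa / fa.sum()

    p, _ = _untangle(p, mesh.faces, adj)
    E, _ = _area_energy(p, mesh.faces, target)
    best_p, best_E = p.copy(), E if not _fold_mask(p, mesh.faces).any() else np.inf
    eta = step0
    it = 0
    stall = 0
    for it in range(1, max_iter + 1):
        if _fold_mask(p, mesh.faces).any():
            p, _ = _untangle(p, mesh.faces, adj)
            E, _ = _area_energy(p, mesh.faces, target)
        if not _fold_mask(p, mesh.faces).any() and E < best_E:
            best_p, best_E = p.copy(), E
        g = _area_gradient(p, mesh.faces, target)
        g -= p * np.einsum("ij,ij->i", g, p)[:, None]  # tangent projection
        gmax = np.linalg.norm(g, axis=1).max()
        if gmax == 0:
            break
        step = g / gmax  # largest vertex moves by eta (radians-scale units)
        accepted = False
        for _ in range(30):
            q = p - eta * step
            q /= np.linalg.norm(q, axis=1, keepdims=True)
            Eq, _ = _area_energy(q, mesh.faces, target)
            if Eq < E:
                accepted = True
                break
            eta *= 0.5
            if eta < 1e-9:
                break
        if not accepted:
            break
        rel = (E - Eq) / max(abs(E), 1e-300)
        p, E = q, Eq
        eta = min(eta * 1.3, 0.25)
        stall = stall + 1 if rel < stall_tol else 0
        if stall >= 30:
            break

    p, n_folded = _untangle(p, mesh.faces, adj)
    if n_folded > 0 and np.isfinite(best_E):
        p, n_folded = best_p, 0
        E = best_E
    elif not _fold_mask(p, mesh.faces).any():
        Ef, _ = _area_energy(p, mesh.faces, target)
        if Ef > best_E:
            p, E = best_p, best_E
    ratios = distortion_ratios(mesh, p)
    finite = ratios[np.isfinite(ratios)]
    max_ratio = float(finite.max()) if len(finite) else np.inf
    med_ratio = float(np.median(finite)) if len(finite) else np.inf
    if n_folded > 0:
        raise ParameterizationError(
            f"spherical map not bijective after {it} iterations: {n_folded} folded "
            f"triangles remain (max area ratio {max_ratio:.3g})"
        )
    theta, phi = sphere_to_angles(p)
    converged = max_ratio <= tol_ratio
    return SphericalParam(
        theta=theta,
        phi=phi,
        points=p,
        n_folded=0,
        max_area_ratio=max_ratio,
        median_area_ratio=med_ratio,
        iterations=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Icosahedral sampling grids
# ---------------------------------------------------------------------------

_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
        [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
        [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ]
)


def icosphere(n: int):
    """Frequency-``n`` geodesic subdivision of the icosahedron.

    Returns unit vertices (10 n^2 + 2, 3) and faces (20 n^2, 3).  Each
    icosahedral face is split into n^2 triangles on a barycentric grid and
    the vertices are projected to the unit sphere.
    """
    if n < 1:
        raise ValueError(f"subdivision parameter must be >= 1, got {n}")
    base = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    verts = []
    faces = []
    for (ia, ib, ic) in _ICO_FACES:
        A, B, C = base[ia], base[ib], base[ic]
        idx = {}
        for i in range(n + 1):
            for j in range(n + 1 - i):
                pt = A + (B - A) * (i / n) + (C - A) * (j / n)
                idx[(i, j)] = len(verts)
                verts.append(pt)
        for i in range(n):
            for j in range(n - i):
                faces.append([idx[(i, j)], idx[(i + 1, j)], idx[(i, j + 1)]])
                if j < n - i - 1:
                    faces.append([idx[(i + 1, j)], idx[(i + 1, j + 1)], idx[(i, j + 1)]])
    verts = np.asarray(verts)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    # merge duplicated vertices along shared icosahedral edges
    key = np.round(verts * 1e7).astype(np.int64)
    _, uniq_idx, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    verts_u = verts[uniq_idx]
    faces_u = inv[np.asarray(faces)]
    assert len(verts_u) == 10 * n * n + 2, "icosphere vertex count mismatch"
    return verts_u, faces_u
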