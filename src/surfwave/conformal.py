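"""Conformal parameterization of genus-0 surfaces onto the unit sphere.

The template surface is flattened by solving the discrete Laplace-Beltrami
equation with a complex point-dipole source at a chosen puncture vertex:
the cotangent-weight stiffness matrix discretizes the Laplace-Beltrami
operator, and the dipole is discretized through the gradients of the hat
functions on the faces incident to the puncture (a set of equal-and-
opposite loads on the puncture's 1-ring).  The planar conformal
coordinates are then carried to the unit sphere by inverse stereographic
projection.

The spherical image is unique only up to Moebius transformations; the
parameterization is normalized by (i) iteratively re-centering with sphere
inversions until the area-weighted centroid of the mapped vertices is at
the origin, and (ii) rotating the sphere so the puncture maps to the north
pole.  This makes the map reproducible across runs and vertex orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import factorized
from scipy.spatial import cKDTree

from .icosphere import IcosphereLevel
from .mesh import SurfaceField, TriangleMesh

__all__ = ["SphericalParam", "AngleDistortionReport", "conformal_to_sphere",
           "angle_distortion", "resample_to_icosphere", "build_resample_operator",
           "CoverageError"]


class CoverageError(RuntimeError):
    """Target sphere points not covered by the parameterized triangulation."""

    def __init__(self, vertices):
        self.vertices = list(vertices)
        super().__init__(
            f"{len(self.vertices)} icosphere vertices not inside any spherical "
            f"triangle (flipped triangles in the parameterization?): "
            f"{self.vertices[:10]}{'...' if len(self.vertices) > 10 else ''}")


@dataclass(frozen=True)
class SphericalParam:
    """Spherical conformal coordinates of a template mesh."""

    mesh: TriangleMesh
    sphere_coords: np.ndarray          # (V, 3), unit vectors
    puncture_vertex: int
    pole: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    n_flipped: int = 0

    def __post_init__(self):
        sc = np.ascontiguousarray(np.asarray(self.sphere_coords, dtype=float))
        object.__setattr__(self, "sphere_coords", sc)
        if sc.shape != self.mesh.vertices.shape:
            raise ValueError("sphere_coords shape must match mesh vertices")
        norms = np.linalg.norm(sc, axis=1)
        if np.abs(norms - 1.0).max() > 1e-9:
            raise ValueError("sphere_coords must be unit vectors (within 1e-9)")


def cotan_laplacian(mesh: TriangleMesh) -> sparse.csr_matrix:
    """Cotangent-weight FEM stiffness matrix (positive semidefinite)."""
    v = mesh.vertices
    f = mesh.faces
    rows, cols, vals = [], [], []
    for k in range(3):
        i = f[:, k]
        j = f[:, (k + 1) % 3]
        o = f[:, (k + 2) % 3]
        e1 = v[i] - v[o]
        e2 = v[j] - v[o]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.einsum("ij,ij->i", e1, e2) / np.maximum(cross, 1e-300)
        w = 0.5 * cot
        rows += [i, j, i, j]
        cols += [j, i, i, j]
        vals += [-w, -w, w, w]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    n = mesh.n_vertices
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def _dipole_rhs(mesh: TriangleMesh, puncture: int) -> np.ndarray:
    """Complex load vector discretizing the derivative-of-Dirac source.

    The dipole is supported on the first face incident to the puncture:
    hat-function gradients on that face yield three equal-and-opposite
    loads on the puncture and two adjacent 1-ring vertices, the discrete
    analogue of (d/dx - i d/dy) of a point delta in the face's frame.
    """
    v = mesh.vertices
    fidx = int(np.flatnonzero(np.any(mesh.faces == puncture, axis=1))[0])
    tri = mesh.faces[fidx].copy()
    while tri[0] != puncture:
        tri = np.roll(tri, 1)
    a, bb, c = v[tri[0]], v[tri[1]], v[tri[2]]
    nrm = np.cross(bb - a, c - a)
    area2 = np.linalg.norm(nrm)
    nrm = nrm / area2
    x_hat = (bb - a) / np.linalg.norm(bb - a)
    y_hat = np.cross(nrm, x_hat)
    b = np.zeros(mesh.n_vertices, dtype=complex)
    for k in range(3):
        edge = v[tri[(k + 2) % 3]] - v[tri[(k + 1) % 3]]
        grad = np.cross(nrm, edge) / area2  # gradient of corner-k hat function
        b[tri[k]] -= (grad @ x_hat) - 1j * (grad @ y_hat)
    return b


def _inverse_stereographic(z: np.ndarray) -> np.ndarray:
    """Map complex plane -> unit sphere, infinity -> north pole (0,0,1)."""
    r2 = z.real ** 2 + z.imag ** 2
    denom = 1.0 + r2
    return np.column_stack([2 * z.real / denom, 2 * z.imag / denom,
                            (r2 - 1.0) / denom])


def _sphere_vertex_areas(coords: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = coords[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    va = np.zeros(len(coords))
    for k in range(3):
        np.add.at(va, faces[:, k], areas / 3.0)
    return va


def _sphere_inversion(coords: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Moebius inversion of the unit sphere about an interior point ``a``."""
    # Moebius transformation of the unit ball restricted to its boundary:
    # T_a(s) = (1-|a|^2)(s-a)/|s-a|^2 - a, an automorphism of the sphere
    d = coords - a
    s = (1.0 - np.sum(a * a)) * d / np.maximum(
        np.einsum("ij,ij->i", d, d), 1e-300)[:, None] - a
    return s / np.linalg.norm(s, axis=1, keepdims=True)


def _mobius_center(coords: np.ndarray, faces: np.ndarray,
                   tol: float = 1e-8, max_iter: int = 100) -> np.ndarray:
    """Iteratively apply sphere inversions until the area-weighted centroid
    of the mapped vertices is at the origin (within ``tol``)."""
    out = coords.copy()
    step = 0.5
    for _ in range(max_iter):
        w = _sphere_vertex_areas(out, faces)
        c = (out * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(c) < tol:
            break
        a = step * c
        cand = _sphere_inversion(out, a)
        wc = _sphere_vertex_areas(cand, faces)
        cc = (cand * wc[:, None]).sum(axis=0) / wc.sum()
        if np.linalg.norm(cc) < np.linalg.norm(c):
            out = cand
        else:
            cand = _sphere_inversion(out, -a)
            wc = _sphere_vertex_areas(cand, faces)
            cc2 = (cand * wc[:, None]).sum(axis=0) / wc.sum()
            if np.linalg.norm(cc2) < np.linalg.norm(c):
                out = cand
            else:
                step *= 0.5
                if step < 1e-6:
                    break
    return out


def _rotate_to_pole(coords: np.ndarray, idx: int) -> np.ndarray:
    """Rotate the sphere so vertex ``idx`` lands on (0, 0, 1)."""
    s = coords[idx]
    target = np.array([0.0, 0.0, 1.0])
    vv = np.cross(s, target)
    c = float(s @ target)
    if np.linalg.norm(vv) < 1e-15:
        if c > 0:
            return coords
        return coords * np.array([1.0, -1.0, -1.0])  # 180 deg about x
    vx = np.array([[0, -vv[2], vv[1]], [vv[2], 0, -vv[0]], [-vv[1], vv[0], 0]])
    r = np.eye(3) + vx + vx @ vx / (1.0 + c)
    out = coords @ r.T
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _count_flipped(coords: np.ndarray, faces: np.ndarray) -> int:
    tri = coords[faces]
    det = np.einsum("ij,ij->i", tri[:, 0],
                    np.cross(tri[:, 1], tri[:, 2]))
    return int(np.sum(det < 0))


def _harmonic_refine(mesh: TriangleMesh, coords: np.ndarray,
                     tol: float = 1e-10, max_iter: int = 1500,
                     step: float = 0.5) -> np.ndarray:
    """Drive the spherical embedding to the discrete harmonic (= conformal,
    for genus 0) map by Jacobi-relaxed tangential Laplacian descent.

    The cotangent stiffness matrix of the *original* mesh defines the
    harmonic energy; only the tangential component of its gradient is
    followed so vertices stay on the sphere, and periodic Moebius
    re-centering removes the conformal group's degeneracy (which would
    otherwise let the flow drift toward collapsing the map to a point).
    """
    lap = cotan_laplacian(mesh)
    diag = lap.diagonal()
    s = coords.copy()
    for it in range(max_iter):
        r = (lap @ s) / diag[:, None]
        r_t = r - np.einsum("ij,ij->i", r, s)[:, None] * s
        res = np.abs(r_t).max()
        s = s - step * r_t
        s /= np.linalg.norm(s, axis=1, keepdims=True)
        if it % 50 == 49:
            s = _mobius_center(s, mesh.faces)
        if res < tol:
            break
    return _mobius_center(s, mesh.faces)


def conformal_to_sphere(mesh: TriangleMesh, puncture: int = 0) -> SphericalParam:
    """Conformally parameterize a closed genus-0 mesh onto the unit sphere.

    A planar conformal flattening (Laplace-Beltrami solve with the dipole
    source at the puncture, then inverse stereographic projection) provides
    a bijective spherical initialization, which is then relaxed to the
    discrete harmonic map of the original metric.  The result is
    Moebius-normalized: area-weighted centroid at the origin and the
    puncture vertex at the north pole.  Conformal maps ignore global scale,
    so scaling the input leaves the result unchanged.
    """
    if not 0 <= puncture < mesh.n_vertices:
        raise ValueError(f"puncture index {puncture} out of range")
    lap = cotan_laplacian(mesh)
    b = _dipole_rhs(mesh, puncture)
    # pin the vertex farthest from the puncture to fix the constant mode
    pin = int(np.argmax(np.linalg.norm(mesh.vertices - mesh.vertices[puncture],
                                       axis=1)))
    keep = np.ones(mesh.n_vertices, dtype=bool)
    keep[pin] = False
    lap_red = lap[keep][:, keep].tocsc()
    try:
        solve = factorized(lap_red)
    except RuntimeError as exc:
        raise RuntimeError(f"singular Laplacian (degenerate triangles?): {exc}")
    z = np.zeros(mesh.n_vertices, dtype=complex)
    z[keep] = solve(b[keep].real) + 1j * solve(b[keep].imag)
    if not np.all(np.isfinite(z.view(float))):
        raise RuntimeError("conformal solve did not converge to finite values")

    # robust plane normalization (a Moebius similarity) before projection
    med = complex(np.median(z.real), np.median(z.imag))
    scale = np.median(np.abs(z - med))
    z = (z - med) / max(scale, 1e-300)

    coords = _inverse_stereographic(z)
    if _count_flipped(coords, mesh.faces) > mesh.n_faces // 2:
        coords = _inverse_stereographic(np.conj(z))
    coords = _mobius_center(coords, mesh.faces)
    coords = _harmonic_refine(mesh, coords)
    coords = _rotate_to_pole(coords, puncture)
    return SphericalParam(mesh, coords, puncture,
                          n_flipped=_count_flipped(coords, mesh.faces))


# ---------------------------------------------------------------------------
# Angle distortion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AngleDistortionReport:
    """Per-triangle maximum absolute corner-angle change, radians."""

    per_triangle: np.ndarray
    mean: float
    median: float
    p95: float


def _corner_angles(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    angles = np.empty((len(faces), 3))
    for k in range(3):
        e1 = tri[:, (k + 1) % 3] - tri[:, k]
        e2 = tri[:, (k + 2) % 3] - tri[:, k]
        cosv = np.einsum("ij,ij->i", e1, e2) / np.maximum(
            np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1), 1e-300)
        angles[:, k] = np.arccos(np.clip(cosv, -1.0, 1.0))
    return angles


def angle_distortion(mesh: TriangleMesh, param: SphericalParam) -> AngleDistortionReport:
    """Compare triangle corner angles between the original embedding and the
    spherical parameterization."""
    if param.mesh is not mesh and not (
            param.mesh.same_topology(mesh)
            and param.mesh.vertices.shape == mesh.vertices.shape):
        raise ValueError("param does not belong to this mesh")
    a0 = _corner_angles(mesh.vertices, mesh.faces)
    a1 = _corner_angles(param.sphere_coords, mesh.faces)
    per_tri = np.abs(a1 - a0).max(axis=1)
    return AngleDistortionReport(per_tri, float(per_tri.mean()),
                                 float(np.median(per_tri)),
                                 float(np.percentile(per_tri, 95)))


# ---------------------------------------------------------------------------
# Resampling onto the wavelet icosphere
# ---------------------------------------------------------------------------

def _central_barycentric(q: np.ndarray, inv_m: np.ndarray) -> np.ndarray:
    """Central-projection barycentric coordinates of unit vector(s) q in the
    planar triangles given by precomputed inverses of [A B C] matrices."""
    w = inv_m @ q
    s = w.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        wn = np.where(s > 1e-12, w / s, -np.inf)
    return wn


def build_resample_operator(param: SphericalParam, target_vertices: np.ndarray,
                            method: str = "barycentric",
                            tol: float = 1e-6) -> sparse.csr_matrix:
    """Sparse interpolation operator from the parameterized template onto a
    set of unit-sphere points (usually icosphere vertices).

    ``barycentric``: each target point gets the barycentric weights of the
    spherical triangle containing it (weights sum to one); ``nearest``: the
    value of the nearest parameterized vertex.  Raises
    :class:`CoverageError` for points not inside any triangle.
    """
    coords = param.sphere_coords
    faces = param.mesh.faces
    nq = len(target_vertices)
    if method == "nearest":
        tree = cKDTree(coords)
        _, idx = tree.query(target_vertices)
        return sparse.csr_matrix(
            (np.ones(nq), (np.arange(nq), idx)), shape=(nq, len(coords)))
    if method != "barycentric":
        raise ValueError(f"unknown method {method!r}")

    tri_mats = coords[faces]                       # (F, 3, 3) rows A,B,C
    inv_m = np.linalg.inv(np.transpose(tri_mats, (0, 2, 1)))
    # faces incident to each vertex, for KD-tree candidate lookup
    incident: list[list[int]] = [[] for _ in range(len(coords))]
    for fi, tri in enumerate(faces):
        for vv in tri:
            incident[vv].append(fi)
    tree = cKDTree(coords)
    _, knn = tree.query(target_vertices, k=min(8, len(coords)))
    if knn.ndim == 1:
        knn = knn[:, None]

    rows, cols, vals = [], [], []
    missed = []
    for qi in range(nq):
        q = target_vertices[qi]
        cand = sorted({fi for vv in knn[qi] for fi in incident[vv]})
        w = _central_barycentric(q, inv_m[cand])   # (len(cand), 3)
        best = int(np.argmax(w.min(axis=1)))
        if w[best].min() < -tol:
            # fall back to exhaustive search before declaring a miss
            w_all = _central_barycentric(q, inv_m)
            best_all = int(np.argmax(w_all.min(axis=1)))
            if w_all[best_all].min() < -tol:
                missed.append(qi)
                continue
            fidx, wts = best_all, w_all[best_all]
        else:
            fidx, wts = cand[best], w[best]
        wts = np.clip(wts, 0.0, None)
        wts = wts / wts.sum()
        rows += [qi] * 3
        cols += list(faces[fidx])
        vals += list(wts)
    if missed:
        raise CoverageError(missed)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(nq, len(coords)))


def resample_to_icosphere(field: SurfaceField, param: SphericalParam,
                          target: IcosphereLevel,
                          method: str = "barycentric") -> SurfaceField:
    """Transfer a surface field from the parameterized template onto the
    vertices of a wavelet icosphere level."""
    if len(field.values) != len(param.sphere_coords):
        raise ValueError("field is not defined on the parameterized mesh")
    op = build_resample_operator(param, target.mesh.vertices, method=method)
    return SurfaceField(target.mesh, op @ field.values, kind=field.kind,
                        units=field.units)
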