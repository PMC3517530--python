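"""Subdivided-icosahedron hierarchy on the unit sphere.

Level j of the hierarchy has ``10 * 4**j + 2`` vertices; level 0 is the
regular icosahedron (12 vertices) and level 2 has 162.  Each subdivision
splits every edge at its midpoint projected back to the unit sphere, and
records for every vertex introduced at level j its two parent-edge
endpoints at level j-1.  The parent map, the prediction stencils and the
per-level vertex areas are what the lifting-scheme wavelet transform in
:mod:`surfwave.wavelet` consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import sparse

from .mesh import TriangleMesh

__all__ = ["IcosphereLevel", "IcosphereHierarchy", "icosphere", "get_hierarchy",
           "vertex_count"]


def vertex_count(level: int) -> int:
    """Number of vertices at a given subdivision level: 10 * 4**j + 2."""
    return 10 * 4 ** level + 2


@dataclass(frozen=True)
class IcosphereLevel:
    """One resolution level of the icosphere hierarchy.

    ``parent_map`` has one row per vertex introduced at this level (empty at
    level 0): row k gives the two parent-edge endpoints of vertex
    ``vertex_count(level - 1) + k``.
    """

    level: int
    mesh: TriangleMesh
    parent_map: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.mesh.n_vertices


def _icosahedron() -> TriangleMesh:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    return TriangleMesh(v, f, name="icosphere0")


def _subdivide(mesh: TriangleMesh):
    """One midpoint-projection subdivision step.

    Returns the refined mesh and the (n_new, 2) parent array; new vertex
    ``V_old + k`` is the normalized midpoint of edge ``parents[k]``.
    """
    v_old = mesh.vertices
    n_old = len(v_old)
    midpoint_index: dict[tuple[int, int], int] = {}
    parents = []
    new_vertices = [v_old]

    def mid(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        idx = midpoint_index.get(key)
        if idx is None:
            idx = n_old + len(parents)
            midpoint_index[key] = idx
            parents.append(key)
            p = v_old[a] + v_old[b]
            new_vertices.append((p / np.linalg.norm(p))[None, :])
        return idx

    faces = []
    for a, b, c in mesh.faces:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    out = TriangleMesh(np.concatenate(new_vertices), np.asarray(faces, dtype=np.int64),
                       name=f"icosphere{int(mesh.name.removeprefix('icosphere')) + 1}")
    return out, np.asarray(parents, dtype=np.int64)


def _vertex_rings(mesh: TriangleMesh):
    """Ordered 1-ring of every vertex (cyclic order from face winding)."""
    nxt: list[dict[int, int]] = [dict() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.faces:
        nxt[a][b] = c
        nxt[b][c] = a
        nxt[c][a] = b
    rings = []
    for v in range(mesh.n_vertices):
        start = next(iter(nxt[v]))
        ring = [start]
        while True:
            nb = nxt[v][ring[-1]]
            if nb == start:
                break
            ring.append(nb)
        rings.append(ring)
    return rings


def _zorin_weights(valence: int) -> np.ndarray:
    """Modified-butterfly ring weights around an extraordinary vertex.

    The ring is indexed from the odd vertex's other parent; the center
    vertex itself carries weight 3/4 and the ring weights sum to 1/4
    (Zorin's construction; only valence 5 occurs on an icosphere besides
    the regular valence 6)."""
    k = valence
    if k == 3:
        return np.array([5.0 / 12.0, -1.0 / 12.0, -1.0 / 12.0])
    if k == 4:
        return np.array([3.0 / 8.0, 0.0, -1.0 / 8.0, 0.0])
    q = np.arange(k)
    return (0.25 + np.cos(2 * np.pi * q / k) + 0.5 * np.cos(4 * np.pi * q / k)) / k


def _predict_matrices(coarse: TriangleMesh, parents: np.ndarray):
    """Linear and butterfly prediction stencils for one subdivision step.

    Rows index the vertices introduced by the step (in parent order),
    columns the coarse vertices.  Both stencils reproduce constants (row
    sums are 1); the butterfly stencil reproduces the linear part of the
    field to higher order, using the 2 parents (1/2), 2 wing vertices (1/8)
    and 4 outer vertices (-1/16) where both parents are regular, and the
    modified-butterfly ring weights around valence-5 vertices.
    """
    n_odd = len(parents)
    n_even = coarse.n_vertices
    lin = sparse.coo_matrix(
        (np.full(2 * n_odd, 0.5),
         (np.repeat(np.arange(n_odd), 2), parents.ravel())),
        shape=(n_odd, n_even)).tocsr()

    # adjacency: opposite vertex of each directed edge
    opp: dict[tuple[int, int], int] = {}
    for a, b, c in coarse.faces:
        opp[(a, b)] = c
        opp[(b, c)] = a
        opp[(c, a)] = b
    valence = np.zeros(n_even, dtype=int)
    for (a, b) in opp:
        valence[a] += 1
    rings = _vertex_rings(coarse)

    rows, cols, vals = [], [], []

    def add(r: int, stencil: dict[int, float]):
        for c, w in stencil.items():
            rows.append(r)
            cols.append(c)
            vals.append(w)

    def regular_stencil(i: int, j: int) -> dict[int, float]:
        # classic 8-point butterfly: parents 1/2, wings 1/8, outers -1/16
        w1 = opp[(i, j)]
        w2 = opp[(j, i)]
        st = {i: 0.5, j: 0.5}
        st[w1] = st.get(w1, 0.0) + 0.125
        st[w2] = st.get(w2, 0.0) + 0.125
        for p, w in ((i, w1), (j, w1), (i, w2), (j, w2)):
            third = j if p == i else i  # third vertex of the wing face {p, w, third}
            o1, o2 = opp[(p, w)], opp[(w, p)]
            o = o2 if o1 == third else o1
            st[o] = st.get(o, 0.0) - 1.0 / 16.0
        return st

    def extraordinary(v: int, other: int) -> dict[int, float]:
        ring = rings[v]
        k = len(ring)
        pos = ring.index(other)
        order = [ring[(pos + q) % k] for q in range(k)]
        wts = _zorin_weights(k)
        st = {v: 0.75}
        for vtx, w in zip(order, wts):
            st[vtx] = st.get(vtx, 0.0) + w
        return st

    for r, (i, j) in enumerate(parents):
        vi, vj = valence[i], valence[j]
        if vi == 6 and vj == 6:
            st = regular_stencil(i, j)
        elif vi != 6 and vj == 6:
            st = extraordinary(i, j)
        elif vj != 6 and vi == 6:
            st = extraordinary(j, i)
        else:
            st = {}
            for c, w in extraordinary(i, j).items():
                st[c] = st.get(c, 0.0) + 0.5 * w
            for c, w in extraordinary(j, i).items():
                st[c] = st.get(c, 0.0) + 0.5 * w
        add(r, st)

    fly = sparse.coo_matrix((vals, (rows, cols)), shape=(n_odd, n_even)).tocsr()
    return {"linear_lifted": lin, "butterfly_lifted": fly}


class IcosphereHierarchy:
    """Icosphere levels 0..max_level with subdivision metadata.

    Exposes per-level meshes, parent maps, prediction stencils for both
    lifting schemes, and barycentric vertex areas, all precomputed once.
    """

    def __init__(self, max_level: int):
        if max_level < 0:
            raise ValueError("level must be >= 0")
        if max_level > 7:
            raise ValueError("practical cap: level <= 7")
        self.max_level = max_level
        mesh = _icosahedron()
        self.levels: list[IcosphereLevel] = [
            IcosphereLevel(0, mesh, np.zeros((0, 2), dtype=np.int64))]
        self.predict: list[dict] = []       # predict[j]: level j -> j+1 stencils
        for j in range(max_level):
            fine, parents = _subdivide(mesh)
            self.predict.append(_predict_matrices(mesh, parents))
            self.levels.append(IcosphereLevel(j + 1, fine, parents))
            mesh = fine
        self.vertex_areas = [lvl.mesh.vertex_areas() for lvl in self.levels]

    def level(self, j: int) -> IcosphereLevel:
        if not 0 <= j <= self.max_level:
            raise ValueError(f"level {j} outside hierarchy 0..{self.max_level}")
        return self.levels[j]

    @lru_cache(maxsize=None)
    def scaling_integrals(self, finest: int, scheme: str):
        """Integrals of the (interpolating) scaling functions per level.

        At the finest level these are the vertex areas; coarser integrals
        follow the two-scale relation through the predict stencil.  They
        supply the lifting update weights that make the wavelets integrate
        to zero, so the area-weighted mean is preserved across levels.
        """
        integrals = [None] * (finest + 1)
        integrals[finest] = self.vertex_areas[finest].copy()
        for j in range(finest - 1, -1, -1):
            fine_i = integrals[j + 1]
            n_even = vertex_count(j)
            p = self.predict[j][scheme]
            coarse_i = fine_i[:n_even] + p.T @ fine_i[n_even:]
            integrals[j] = coarse_i
        return integrals


@lru_cache(maxsize=8)
def get_hierarchy(max_level: int) -> IcosphereHierarchy:
    return IcosphereHierarchy(max_level)


def icosphere(level: int) -> IcosphereLevel:
    """The unit icosphere at the requested subdivision level.

    Level 0 is the icosahedron (12 vertices, 20 faces); each level splits
    every edge at its sphere-projected midpoint (level 2 has 162 vertices).
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    return get_hierarchy(level).level(level)
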