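"""Triangle-mesh primitives for electrode-planning geometry.

Everything downstream of the imaging pipeline lives on triangulated
surfaces: the cortex carries one dipole source per triangle, safety
filters need fast minimum-distance queries from electrode shafts to
critical structures, and extended sources are grown as contiguous
patches of triangles.  This module provides the mesh container, a
bounding-volume-hierarchy (BVH) distance index, breadth-first patch
growth, sulci-surface derivation via mesh smoothing, and radial
projection of patches onto the inner skull.

All coordinates are in millimetres; patch areas and extents are reported
in cm^2 / cm to match clinical convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "SurfaceMesh",
    "DistanceIndex",
    "Patch",
    "triangle_metrics",
    "min_distance",
    "grow_patch",
    "patch_extent",
    "laplacian_smooth",
    "sulci_face_mask",
    "derive_sulci_surface",
    "projected_area_on_skull",
    "points_inside",
    "ray_surface_intersection",
]

_DEGENERATE_AREA = 1e-12  # mm^2; below this a triangle's normal is undefined


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """A triangulated surface in millimetre coordinates.

    Per-triangle areas, outward unit normals and centroids are computed
    on construction.  Normals of degenerate (zero-area) triangles are
    NaN-flagged rather than raising, so that smoothing-collapse checks
    can count them.
    """

    vertices: np.ndarray  # (n_v, 3) float, mm
    faces: np.ndarray     # (n_f, 3) int
    areas: np.ndarray = field(init=False)      # (n_f,) mm^2
    normals: np.ndarray = field(init=False)    # (n_f, 3) unit (NaN if degenerate)
    centroids: np.ndarray = field(init=False)  # (n_f, 3) mm

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if not np.isfinite(self.vertices).all():
            raise ValueError("vertex coordinates must be finite")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        self.areas, self.normals, self.centroids = triangle_metrics(
            self.vertices, self.faces)
        self._adjacency: list[np.ndarray] | None = None

    # -- derived quantities -------------------------------------------------

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangle_vertices(self) -> np.ndarray:
        """(n_f, 3, 3) vertex coordinates of every triangle."""
        return self.vertices[self.faces]

    def total_area(self) -> float:
        """Total surface area in mm^2."""
        return float(self.areas.sum())

    def face_adjacency(self) -> list[np.ndarray]:
        """Edge-adjacent neighbour faces of every face (cached)."""
        if self._adjacency is None:
            edges = np.sort(
                self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
            face_of_edge = np.repeat(np.arange(self.n_faces), 3)
            order = np.lexsort((edges[:, 1], edges[:, 0]))
            edges, face_of_edge = edges[order], face_of_edge[order]
            same = (edges[1:] == edges[:-1]).all(axis=1)
            pairs = np.stack([face_of_edge[:-1][same],
                              face_of_edge[1:][same]], axis=1)
            neigh: list[list[int]] = [[] for _ in range(self.n_faces)]
            for a, b in pairs:
                neigh[a].append(b)
                neigh[b].append(a)
            self._adjacency = [np.array(n, dtype=np.int64) for n in neigh]
        return self._adjacency

    # -- interop ------------------------------------------------------------

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(),
                               faces=self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(mesh.vertices, dtype=float),
                   np.asarray(mesh.faces, dtype=np.int64))

    def submesh(self, face_indices: np.ndarray) -> "SurfaceMesh":
        """Sub-mesh of the given faces, with vertices re-indexed."""
        face_indices = np.asarray(face_indices, dtype=np.int64)
        faces = self.faces[face_indices]
        used, inverse = np.unique(faces, return_inverse=True)
        return SurfaceMesh(self.vertices[used], inverse.reshape(-1, 3))


def triangle_metrics(vertices: np.ndarray,
                     faces: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact per-triangle area (mm^2), unit normal and centroid.

    Degenerate triangles get area 0 and NaN normals.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(cross, axis=1)
    areas = 0.5 * norm
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = cross / norm[:, None]
    normals[areas <= _DEGENERATE_AREA] = np.nan
    centroids = tri.mean(axis=1)
    return areas, normals, centroids


# ---------------------------------------------------------------------------
# BVH minimum-distance queries
# ---------------------------------------------------------------------------

def _point_triangle_distance(points: np.ndarray, triangles: np.ndarray,
                             paired: bool = False) -> np.ndarray:
    """Distances from points (q,3) to triangles.

    All-pairs mode (default): triangles (t,3,3) -> (q,t).  Paired mode:
    triangles (q,3,3), one per point -> (q,).  Closest point on triangle
    by barycentric region classification (the standard seven-region
    construction), fully vectorised.
    """
    if paired:
        p = points
        a, b, c = triangles[:, 0, :], triangles[:, 1, :], triangles[:, 2, :]
    else:
        p = points[:, None, :]                  # (q,1,3)
        a = triangles[None, :, 0, :]            # (1,t,3)
        b = triangles[None, :, 1, :]
        c = triangles[None, :, 2, :]
    ab, ac = b - a, c - a
    ap = p - a
    d1 = (ab * ap).sum(-1)
    d2 = (ac * ap).sum(-1)
    bp = p - b
    d3 = (ab * bp).sum(-1)
    d4 = (ac * bp).sum(-1)
    cp = p - c
    d5 = (ab * cp).sum(-1)
    d6 = (ac * cp).sum(-1)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    eps = np.finfo(float).tiny

    with np.errstate(invalid="ignore", divide="ignore"):
        v_ab = d1 / np.where(np.abs(d1 - d3) < eps, eps, d1 - d3)
        w_ac = d2 / np.where(np.abs(d2 - d6) < eps, eps, d2 - d6)
        w_bc = (d4 - d3) / np.where(
            np.abs((d4 - d3) + (d5 - d6)) < eps, eps, (d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        denom = np.where(np.abs(denom) < eps, eps, denom)
        v_in = vb / denom
        w_in = vc / denom

    # region masks, applied in priority order (vertices, edges, interior)
    in_a = (d1 <= 0) & (d2 <= 0)
    in_b = (d3 >= 0) & (d4 <= d3)
    in_c = (d6 >= 0) & (d5 <= d6)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    v_ab = np.clip(v_ab, 0.0, 1.0)[..., None]
    w_ac = np.clip(w_ac, 0.0, 1.0)[..., None]
    w_bc = np.clip(w_bc, 0.0, 1.0)[..., None]
    v_in_ = v_in[..., None]
    w_in_ = w_in[..., None]

    closest = a + ab * v_in_ + ac * w_in_
    closest = np.where(on_bc[..., None], b + (c - b) * w_bc, closest)
    closest = np.where(on_ac[..., None], a + ac * w_ac, closest)
    closest = np.where(on_ab[..., None], a + ab * v_ab, closest)
    closest = np.where(in_c[..., None], c, closest)
    closest = np.where(in_b[..., None], b, closest)
    closest = np.where(in_a[..., None], a, closest)
    return np.linalg.norm(p - closest, axis=-1)


class DistanceIndex:
    """Axis-aligned-box BVH over mesh triangles for minimum-distance queries.

    Binary tree built by median split along the widest centroid axis;
    every triangle lands in exactly one leaf and parent boxes contain
    their children.  Queries are batched: a stack of (node, active
    queries) pairs is traversed with per-query best-distance pruning.
    """

    leaf_size = 8

    def __init__(self, mesh: SurfaceMesh):
        if mesh.n_faces == 0:
            raise ValueError("cannot index an empty mesh")
        self.mesh = mesh
        tri = mesh.triangle_vertices
        lo_t = tri.min(axis=1)
        hi_t = tri.max(axis=1)
        cen = mesh.centroids

        n = mesh.n_faces
        order = np.arange(n)
        # nodes appended as (lo, hi, left, right, start, end); leaves use
        # start/end into self.tri_order, internal nodes use left/right.
        boxes_lo: list[np.ndarray] = []
        boxes_hi: list[np.ndarray] = []
        children: list[tuple[int, int]] = []
        ranges: list[tuple[int, int]] = []

        def build(idx: np.ndarray, start: int) -> int:
            node = len(boxes_lo)
            boxes_lo.append(lo_t[idx].min(axis=0))
            boxes_hi.append(hi_t[idx].max(axis=0))
            children.append((-1, -1))
            ranges.append((-1, -1))
            if len(idx) <= self.leaf_size:
                ranges[node] = (start, start + len(idx))
                order[start:start + len(idx)] = idx
                return node
            axis = int(np.argmax(boxes_hi[node] - boxes_lo[node]))
            half = len(idx) // 2
            part = idx[np.argpartition(cen[idx, axis], half)]
            left = build(part[:half], start)
            right = build(part[half:], start + half)
            children[node] = (left, right)
            return node

        import sys
        limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(limit, 10000))
        try:
            build(np.arange(n), 0)
        finally:
            sys.setrecursionlimit(limit)

        self.tri_order = order
        self.box_lo = np.array(boxes_lo)
        self.box_hi = np.array(boxes_hi)
        self.children = np.array(children, dtype=np.int64)
        self.ranges = np.array(ranges, dtype=np.int64)
        self._tri_sorted = tri[order]
        # seed structure: nearest triangle centroid gives a valid upper
        # bound (centroid distance + that triangle's circumradius)
        from scipy.spatial import cKDTree
        self._centroid_tree = cKDTree(cen)
        self._tri_radius = np.linalg.norm(
            tri - cen[:, None, :], axis=-1).max(axis=1)

    def _box_distance(self, node: int, pts: np.ndarray) -> np.ndarray:
        return np.linalg.norm(
            np.maximum(self.box_lo[node] - pts, 0.0)
            + np.maximum(pts - self.box_hi[node], 0.0), axis=1)

    def min_distance(self, points: np.ndarray) -> np.ndarray:
        """Exact minimum Euclidean distance (mm) of each point to the mesh."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        nq = len(points)
        _, i_cen = self._centroid_tree.query(points)
        best = _point_triangle_distance(
            points, self.mesh.triangle_vertices[i_cen], paired=True)
        stack: list[tuple[int, np.ndarray]] = [(0, np.arange(nq))]
        while stack:
            node, qi = stack.pop()
            qi = qi[self._box_distance(node, points[qi]) < best[qi]]
            if qi.size == 0:
                continue
            left, right = self.children[node]
            if left < 0:  # leaf
                s, e = self.ranges[node]
                d = _point_triangle_distance(points[qi], self._tri_sorted[s:e])
                best[qi] = np.minimum(best[qi], d.min(axis=1))
            else:
                # push the farther child first so the nearer one tightens
                # the bounds before the farther is examined
                d_l = self._box_distance(left, points[qi])
                d_r = self._box_distance(right, points[qi])
                near_first = d_l.mean() <= d_r.mean()
                a, da = (left, d_l) if near_first else (right, d_r)
                b, db = (right, d_r) if near_first else (left, d_l)
                qb = qi[db < best[qi]]
                if qb.size:
                    stack.append((b, qb))
                qa = qi[da < best[qi]]
                if qa.size:
                    stack.append((a, qa))
        return best


def min_distance(index: DistanceIndex, query: np.ndarray) -> np.ndarray:
    """Minimum distances (mm) from query points to the indexed mesh."""
    return index.min_distance(query)


# ---------------------------------------------------------------------------
# Patches: breadth-first growth and extent
# ---------------------------------------------------------------------------

@dataclass
class Patch:
    """A contiguous set of cortical triangles representing an extended source."""

    center_element: int
    members: np.ndarray      # triangle indices, edge-connected
    area_cm2: float
    extent_cm: float | None = None

    def to_json_dict(self) -> dict:
        d = {"center": int(self.center_element),
             "members": [int(m) for m in self.members],
             "area_cm2": float(self.area_cm2)}
        if self.extent_cm is not None:
            d["extent_cm"] = float(self.extent_cm)
        return d


def grow_patch(mesh: SurfaceMesh, center: int, target_area_cm2: float) -> Patch:
    """Grow an extended-source patch of at least ``target_area_cm2`` around
    a centre triangle.

    Accretion is ring-wise breadth-first over edge adjacency: whole rings
    of neighbours are admitted until the cumulative area first reaches
    the target, so the result is orientation-free and deterministic.
    The returned area ``A`` satisfies ``A >= target`` and
    ``A - area(last ring) < target``.
    """
    target_mm2 = float(target_area_cm2) * 100.0
    if target_mm2 > mesh.total_area() * (1 + 1e-12):
        raise ValueError("target area exceeds total mesh area")
    if target_mm2 < mesh.areas[center]:
        target_mm2 = mesh.areas[center]  # a single element always qualifies
    adjacency = mesh.face_adjacency()
    in_patch = np.zeros(mesh.n_faces, dtype=bool)
    in_patch[center] = True
    members = [center]
    area = float(mesh.areas[center])
    ring = [center]
    while area < target_mm2:
        nxt: list[int] = []
        for f in ring:
            for g in adjacency[f]:
                if not in_patch[g]:
                    in_patch[g] = True
                    nxt.append(int(g))
        if not nxt:
            break
        members.extend(nxt)
        area += float(mesh.areas[nxt].sum())
        ring = nxt
    return Patch(center_element=int(center),
                 members=np.array(members, dtype=np.int64),
                 area_cm2=area / 100.0)


def _boundary_vertices(mesh: SurfaceMesh, members: np.ndarray) -> np.ndarray:
    """Vertices on edges of member faces shared with non-members (or open)."""
    faces = mesh.faces[members]
    edges = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary_edges = uniq[counts == 1]  # interior patch edges appear twice
    return np.unique(boundary_edges)


def patch_extent(mesh: SurfaceMesh, patch: Patch) -> float:
    """Mean distance (cm) from the patch centre of mass to its boundary.

    Centre of mass is the area-weighted mean of member-triangle centroids;
    the boundary is the set of vertices on edges shared with non-member
    triangles.  Euclidean distances are used.
    """
    members = np.asarray(patch.members, dtype=np.int64)
    bverts = _boundary_vertices(mesh, members)
    if bverts.size == 0:
        raise ValueError("patch has no boundary (covers a closed surface)")
    w = mesh.areas[members]
    com = (mesh.centroids[members] * w[:, None]).sum(axis=0) / w.sum()
    dists = np.linalg.norm(mesh.vertices[bverts] - com, axis=1)
    return float(dists.mean()) / 10.0  # mm -> cm


# ---------------------------------------------------------------------------
# Inside tests and ray casting (no external spatial-index dependency)
# ---------------------------------------------------------------------------

def points_inside(mesh: SurfaceMesh, points: np.ndarray,
                  chunk: int = 256) -> np.ndarray:
    """Generalized-winding-number inside test for a closed, outward-oriented
    mesh.  Robust to points near the surface; O(queries x triangles),
    evaluated in chunks."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangle_vertices
    out = np.empty(len(points), dtype=bool)
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        a = tri[None, :, 0, :] - p[:, None, :]
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        lc = np.linalg.norm(c, axis=-1)
        det = np.einsum("qtk,qtk->qt", a, np.cross(b, c))
        denom = (la * lb * lc + np.einsum("qtk,qtk->qt", a, b) * lc
                 + np.einsum("qtk,qtk->qt", b, c) * la
                 + np.einsum("qtk,qtk->qt", c, a) * lb)
        omega = 2.0 * np.arctan2(det, denom)
        out[s:s + chunk] = omega.sum(axis=1) >= 2.0 * np.pi
    return out


def ray_surface_intersection(mesh: SurfaceMesh, origins: np.ndarray,
                             directions: np.ndarray,
                             chunk: int = 128) -> np.ndarray:
    """First intersection points of rays with the mesh (Moller-Trumbore,
    smallest positive ray parameter).  NaN rows where a ray misses."""
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    tri = mesh.triangle_vertices
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    hits = np.full_like(origins, np.nan)
    eps = 1e-12
    for s in range(0, len(origins), chunk):
        o = origins[s:s + chunk][:, None, :]
        d = directions[s:s + chunk][:, None, :]
        pvec = np.cross(d, e2[None])
        det = np.einsum("qtk,tk->qt", pvec, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / det
            tvec = o - v0[None]
            u = np.einsum("qtk,qtk->qt", tvec, pvec) * inv
            qvec = np.cross(tvec, e1[None])
            v = (qvec * d).sum(-1) * inv
            t = np.einsum("qtk,tk->qt", qvec, e2) * inv
            ok = (np.abs(det) > eps) & (u >= -1e-9) & (v >= -1e-9) \
                & (u + v <= 1 + 1e-9) & (t > eps)
        t = np.where(ok, t, np.inf)
        tmin = t.min(axis=1)
        good = np.isfinite(tmin)
        hits[s:s + chunk][good] = (origins[s:s + chunk][good]
                                   + directions[s:s + chunk][good]
                                   * tmin[good][:, None])
    return hits


# ---------------------------------------------------------------------------
# Sulci surface: intersection of cortex with its super-smoothed copy
# ---------------------------------------------------------------------------

def laplacian_smooth(mesh: SurfaceMesh, iterations: int,
                     lamb: float = 0.5) -> SurfaceMesh:
    """Uniform-weight Laplacian smoothing: v <- v + lamb*(mean(neighbours) - v)."""
    from scipy import sparse

    edges = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    edges = np.unique(edges, axis=0)
    n = len(mesh.vertices)
    adj = sparse.coo_matrix(
        (np.ones(2 * len(edges)),
         (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    avg = sparse.diags(1.0 / deg) @ adj
    v = mesh.vertices.copy()
    for _ in range(int(iterations)):
        v = v + lamb * (avg @ v - v)
    return SurfaceMesh(v, mesh.faces.copy())


def hc_laplacian_smooth(mesh: SurfaceMesh, iterations: int,
                        alpha: float = 0.0, beta: float = 0.5) -> SurfaceMesh:
    """Shrink-compensated (HC) Laplacian smoothing after Vollmer et al.

    Each uniform-Laplacian step is followed by a push-back of the
    smoothed estimate towards the original/previous positions, so that
    many iterations flatten folds without collapsing the global scale —
    the behaviour needed for a "super-smoothed" reference surface.
    """
    from scipy import sparse

    edges = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    edges = np.unique(edges, axis=0)
    n = len(mesh.vertices)
    adj = sparse.coo_matrix(
        (np.ones(2 * len(edges)),
         (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    avg = sparse.diags(1.0 / deg) @ adj
    o = mesh.vertices
    q = o.copy()
    for _ in range(int(iterations)):
        p = avg @ q
        b = p - (alpha * o + (1.0 - alpha) * q)
        q = p - (beta * b + (1.0 - beta) * (avg @ b))
    return SurfaceMesh(q, mesh.faces.copy())


def sulci_face_mask(cortex: SurfaceMesh, smooth_iters: int = 100,
                    margin_mm: float = 1.5,
                    method: str = "hc") -> np.ndarray:
    """Boolean mask of cortex triangles at the bases of sulci.

    A super-smoothed copy of the cortex is computed (shrink-compensated
    HC Laplacian by default, ``method="laplacian"`` for the plain
    filter); triangles whose centroids lie inside the smoothed surface
    by more than ``margin_mm`` (winding-number containment plus a BVH
    distance check) are sulcal.  The margin absorbs faceting offsets —
    triangle centroids sit inside any smooth surface by the chord
    sagitta — and must stay well below the sulcal depth.
    ``smooth_iters = 0`` yields an empty mask: the surface equals itself
    and there is no interior.
    """
    if smooth_iters <= 0:
        return np.zeros(cortex.n_faces, dtype=bool)
    if method == "hc":
        smoothed = hc_laplacian_smooth(cortex, smooth_iters)
    elif method == "laplacian":
        smoothed = laplacian_smooth(cortex, smooth_iters)
    else:
        raise ValueError(f"unknown smoothing method: {method}")
    degenerate = smoothed.areas <= _DEGENERATE_AREA
    if degenerate.mean() > 0.5:
        raise ValueError("smoothing collapsed the mesh "
                         f"({degenerate.mean():.0%} degenerate triangles)")
    inside = points_inside(smoothed, cortex.centroids)
    if margin_mm > 0 and inside.any():
        depth = DistanceIndex(smoothed).min_distance(cortex.centroids)
        inside &= depth > margin_mm
    return inside


def derive_sulci_surface(cortex: SurfaceMesh, smooth_iters: int = 100,
                         margin_mm: float = 1.5,
                         method: str = "hc") -> SurfaceMesh:
    """Sub-mesh of cortex triangles forming the bases of sulci.

    Convex meshes (e.g. a spherical cortex) give an empty surface: no
    centroid lies inside its smoothed copy by more than the faceting
    margin.
    """
    mask = sulci_face_mask(cortex, smooth_iters, margin_mm=margin_mm,
                           method=method)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
    return cortex.submesh(idx)


# ---------------------------------------------------------------------------
# Radial projection onto the inner skull
# ---------------------------------------------------------------------------

def projected_area_on_skull(patch: Patch, cortex: SurfaceMesh,
                            skull: SurfaceMesh,
                            head_center: np.ndarray) -> float:
    """Area (cm^2) of the patch projected radially onto the inner skull.

    Every vertex of every member triangle is pushed along the ray from
    ``head_center`` through the vertex until it meets the skull mesh;
    the areas of the projected triangles are summed.
    """
    head_center = np.asarray(head_center, dtype=float)
    members = np.asarray(patch.members, dtype=np.int64)
    if members.size == 0 or patch.area_cm2 == 0:
        return 0.0
    verts_idx = np.unique(cortex.faces[members])
    pts = cortex.vertices[verts_idx]
    dirs = pts - head_center
    if np.any(np.linalg.norm(dirs, axis=1) < 1e-9):
        raise ValueError("patch vertex coincides with head centre")
    hits = ray_surface_intersection(skull, np.broadcast_to(
        head_center, pts.shape).copy(), dirs)
    if np.isnan(hits).any():
        raise ValueError("projection ray missed the skull mesh")
    remap = np.full(len(cortex.vertices), -1, dtype=np.int64)
    remap[verts_idx] = np.arange(len(verts_idx))
    proj_faces = remap[cortex.faces[members]]
    areas, _, _ = triangle_metrics(hits, proj_faces)
    return float(areas.sum()) / 100.0
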