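"""Low-level mesh geometry kernels.

Vectorized ray–triangle intersection (Möller–Trumbore), parity-based
point-in-mesh queries, and point-to-triangle distances, all operating on
plain ``(m, 3, 3)`` triangle arrays so they work with any triangulated
surface regardless of how it was loaded.

Computations are chunked over rays/points to bound peak memory at roughly
``CHUNK_FLOATS`` float64 values per intermediate array.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError

# ~4M float64 entries (~32 MB) per broadcast intermediate
CHUNK_FLOATS = 4_000_000

# Fixed, deliberately "irrational-looking" direction for parity tests so
# axis-aligned meshes are never probed exactly along an edge or face plane.
_PARITY_DIRECTION = np.array([0.2781624871, 0.5964217315, 0.7529841372])
_PARITY_DIRECTION = _PARITY_DIRECTION / np.linalg.norm(_PARITY_DIRECTION)


def triangles_of(mesh) -> np.ndarray:
    """Return the ``(m, 3, 3)`` triangle vertex array of a trimesh mesh."""
    return np.asarray(mesh.triangles, dtype=np.float64)


def _chunk_size(n_tri: int) -> int:
    return max(1, CHUNK_FLOATS // max(n_tri, 1))


def intersect_rays(
    origins: np.ndarray,
    directions: np.ndarray,
    triangles: np.ndarray,
    *,
    t_min: float = 1e-9,
    bary_tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intersect rays with a triangle soup.

    Parameters
    ----------
    origins, directions
        ``(n, 3)`` ray origins and (not necessarily unit) directions.
    triangles
        ``(m, 3, 3)`` triangle vertices.
    t_min
        Minimum accepted ray parameter; hits closer than this are treated
        as grazing the origin and discarded.
    bary_tol
        Barycentric slack so rays hitting exactly on shared edges are
        counted by at least one of the adjacent triangles.

    Returns
    -------
    ray_index, tri_index, t
        Flat arrays, one entry per (ray, triangle) hit. ``t`` is in units
        of ``|direction|`` (mm when directions are unit vectors).
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=np.float64))
    directions = np.atleast_2d(np.asarray(directions, dtype=np.float64))
    triangles = np.asarray(triangles, dtype=np.float64)
    if triangles.ndim != 3 or triangles.shape[1:] != (3, 3):
        raise GeometryError("triangles must have shape (m, 3, 3)")

    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0

    ray_idx_out: list[np.ndarray] = []
    tri_idx_out: list[np.ndarray] = []
    t_out: list[np.ndarray] = []

    step = _chunk_size(len(triangles))
    for start in range(0, len(origins), step):
        o = origins[start : start + step, None, :]   # (r, 1, 3)
        d = directions[start : start + step, None, :]
        pvec = np.cross(d, e2[None, :, :])           # (r, m, 3)
        det = np.einsum("ij,rij->ri", e1, pvec)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_det = np.where(np.abs(det) > 1e-14, 1.0 / det, 0.0)
            tvec = o - v0[None, :, :]
            u = np.einsum("rij,rij->ri", tvec, pvec) * inv_det
            qvec = np.cross(tvec, e1[None, :, :])
            v = np.einsum("rij,rij->ri", np.broadcast_to(d, qvec.shape), qvec) * inv_det
            t = np.einsum("ij,rij->ri", e2, qvec) * inv_det
        hit = (
            (np.abs(det) > 1e-14)
            & (u >= -bary_tol)
            & (v >= -bary_tol)
            & (u + v <= 1.0 + bary_tol)
            & (t > t_min)
        )
        r_loc, m_loc = np.nonzero(hit)
        ray_idx_out.append(r_loc + start)
        tri_idx_out.append(m_loc)
        t_out.append(t[r_loc, m_loc])

    if not ray_idx_out:
        empty = np.empty(0)
        return empty.astype(np.intp), empty.astype(np.intp), empty
    return (
        np.concatenate(ray_idx_out),
        np.concatenate(tri_idx_out),
        np.concatenate(t_out),
    )


def first_and_last_hits(
    origin: np.ndarray, direction: np.ndarray, triangles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted (t, tri_index) of all forward hits of a single ray."""
    _, tri, t = intersect_rays(origin[None, :], direction[None, :], triangles)
    order = np.argsort(t)
    return t[order], tri[order]


def points_inside(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Boolean inside/outside test by ray-crossing parity.

    Assumes a closed (watertight) surface; a point is inside when a ray in
    the fixed probe direction crosses the surface an odd number of times.
    Duplicate hits from the edge-slack tolerance are deduplicated by ray
    parameter before the parity count.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    dirs = np.broadcast_to(_PARITY_DIRECTION, points.shape)
    ray_idx, _, t = intersect_rays(points, dirs, triangles)
    inside = np.zeros(len(points), dtype=bool)
    if len(ray_idx) == 0:
        return inside
    for r in np.unique(ray_idx):
        tr = np.sort(t[ray_idx == r])
        # collapse shared-edge double counts
        keep = np.ones(len(tr), dtype=bool)
        if len(tr) > 1:
            keep[1:] = np.diff(tr) > 1e-9
        inside[r] = (keep.sum() % 2) == 1
    return inside


def _segment_distance_sq(p, a, ab):
    """Squared distance from points ``p (r, 1, 3)`` to segments
    ``a + u*ab`` (broadcast ``(1, m, 3)``), u clamped to [0, 1]."""
    ap = p - a
    denom = np.einsum("...i,...i->...", ab, ab)
    u = np.einsum("...i,...i->...", ap, np.broadcast_to(ab, ap.shape))
    u = np.clip(u / np.where(denom > 0, denom, 1.0), 0.0, 1.0)
    closest = a + u[..., None] * ab
    d = p - closest
    return np.einsum("...i,...i->...", d, d)


def _pt_tri_distance_sq(p, v0, v1, v2):
    """Squared point-triangle distance on broadcastable ``(..., 3)``
    operands.

    The closest point on a triangle is either the orthogonal projection
    onto its plane (when the projection's barycentric coordinates are
    all non-negative) or lies on one of the three boundary segments;
    both candidates are evaluated and the valid minimum taken.
    """
    e0 = v1 - v0
    e1 = v2 - v0
    a = np.einsum("...i,...i->...", e0, e0)
    b = np.einsum("...i,...i->...", e0, e1)
    c = np.einsum("...i,...i->...", e1, e1)
    det = a * c - b * b
    det_safe = np.where(det > 0, det, 1.0)

    w = p - v0
    d0 = np.einsum("...i,...i->...", np.broadcast_to(e0, w.shape), w)
    d1 = np.einsum("...i,...i->...", np.broadcast_to(e1, w.shape), w)
    s = (c * d0 - b * d1) / det_safe
    t = (a * d1 - b * d0) / det_safe
    interior = (s >= 0) & (t >= 0) & (s + t <= 1) & (det > 0)
    proj = v0 + s[..., None] * e0 + t[..., None] * e1
    dp = p - proj
    d2_int = np.einsum("...i,...i->...", dp, dp)

    d2_edges = np.minimum(
        _segment_distance_sq(p, v0, e0),
        np.minimum(
            _segment_distance_sq(p, v0, e1),
            _segment_distance_sq(p, v1, v2 - v1),
        ),
    )
    return np.where(interior, d2_int, d2_edges)


def point_triangle_distances(
    points: np.ndarray, triangles: np.ndarray, *, prune_above: int = 8192, k_candidates: int = 64
) -> np.ndarray:
    """Minimum Euclidean distance from each point to a triangle soup.

    For small soups every (point, triangle) pair is evaluated, chunked
    over points to bound memory. For large soups (``> prune_above``
    triangles, e.g. dense marching-cubes output) candidate triangles are
    pre-selected per point as the ``k_candidates`` nearest by centroid,
    which is exact in practice for near-uniform meshes whose triangle
    diameter is far below the pruning radius.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    triangles = np.asarray(triangles, dtype=np.float64)
    m = len(triangles)

    if m > prune_above:
        from scipy.spatial import cKDTree

        centroids = triangles.mean(axis=1)
        k = min(k_candidates, m)
        _, idx = cKDTree(centroids).query(points, k=k)
        cand = triangles[idx]                       # (n, k, 3, 3)
        d2 = _pt_tri_distance_sq(
            points[:, None, :], cand[:, :, 0], cand[:, :, 1], cand[:, :, 2]
        )
        return np.sqrt(d2.min(axis=1))

    v0 = triangles[None, :, 0]
    v1 = triangles[None, :, 1]
    v2 = triangles[None, :, 2]
    out = np.empty(len(points))
    step = _chunk_size(m)
    for start in range(0, len(points), step):
        p = points[start : start + step, None, :]   # (r, 1, 3)
        d2 = _pt_tri_distance_sq(p, v0, v1, v2)
        out[start : start + step] = np.sqrt(d2.min(axis=1))
    return out


def hausdorff_vertices(mesh_a, mesh_b, *, max_points: int = 4000, seed: int = 0) -> float:
    """Symmetric Hausdorff distance between two meshes, estimated on
    (sub-sampled) vertex sets against the full opposing triangle soup."""
    rng = np.random.default_rng(seed)

    def sample(verts):
        if len(verts) > max_points:
            idx = rng.choice(len(verts), size=max_points, replace=False)
            return verts[idx]
        return verts

    da = point_triangle_distances(sample(np.asarray(mesh_a.vertices)), triangles_of(mesh_b))
    db = point_triangle_distances(sample(np.asarray(mesh_b.vertices)), triangles_of(mesh_a))
    return float(max(da.max(), db.max()))


def distance_point_to_line(p: np.ndarray, a: np.ndarray, d_unit: np.ndarray) -> float:
    """Distance from point ``p`` to the infinite line through ``a`` with
    unit direction ``d_unit``."""
    return float(np.linalg.norm(np.cross(np.asarray(p) - np.asarray(a), d_unit)))
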