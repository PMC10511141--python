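"""Vectorized geometric primitives shared by labeling, inflation and quality.

Point-to-triangle distances use the standard region classification (Ericson);
segment/surface intersection is Moller-Trumbore.  Candidate faces come from a
KD-tree over face centroids with an exact radius re-query, so reported
distances are true minima, not approximations.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["closest_point_on_triangles", "SurfaceDistance",
           "segment_surface_hits"]


def closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on triangle tri[i] to point p[i], elementwise.

    p: (n, 3); tri: (n, 3, 3).  Returns (n, 3) closest points.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def fill(mask, val):
        m = mask & ~done
        out[m] = val[m] if val.ndim == 2 else val
        done[m] = True

    fill((d1 <= 0) & (d2 <= 0), a)                       # vertex A
    fill((d3 >= 0) & (d4 <= d3), b)                      # vertex B
    fill((d6 >= 0) & (d5 <= d6), c)                      # vertex C
    vc = d1 * d4 - d3 * d2
    v_ab = np.divide(d1, d1 - d3, out=np.zeros_like(d1),
                     where=np.abs(d1 - d3) > 0)
    fill((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge AB
    vb = d5 * d2 - d1 * d6
    w_ac = np.divide(d2, d2 - d6, out=np.zeros_like(d2),
                     where=np.abs(d2 - d6) > 0)
    fill((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge AC
    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    w_bc = np.divide(d4 - d3, denom_bc, out=np.zeros_like(d4),
                     where=np.abs(denom_bc) > 0)
    fill((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
         b + w_bc[:, None] * (c - b))                    # edge BC
    denom = va + vb + vc
    v = np.divide(vb, denom, out=np.zeros_like(vb), where=np.abs(denom) > 0)
    w = np.divide(vc, denom, out=np.zeros_like(vc), where=np.abs(denom) > 0)
    fill(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


class SurfaceDistance:
    """Exact unsigned point-to-surface distance queries against one surface."""

    def __init__(self, surface):
        self.surface = surface
        self.tri = surface.vertices[surface.faces]          # (m, 3, 3)
        self.centroids = self.tri.mean(axis=1)
        # circumradius bound: max distance centroid -> own vertices
        self.rmax = float(np.linalg.norm(
            self.tri - self.centroids[:, None, :], axis=2).max())
        self.tree = cKDTree(self.centroids)

    def query(self, points: np.ndarray, k: int = 8
              ) -> tuple[np.ndarray, np.ndarray]:
        """Distances and closest surface points for each query point.

        Two-stage: k nearest centroids give an upper bound d0, then every face
        whose centroid lies within d0 + rmax is checked exactly.
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        k = min(k, len(self.centroids))
        _, idx = self.tree.query(points, k=k)
        idx = np.atleast_2d(idx)
        n = len(points)
        rep = np.repeat(np.arange(n), idx.shape[1])
        cp = closest_point_on_triangles(points[rep], self.tri[idx.ravel()])
        d = np.linalg.norm(cp - points[rep], axis=1).reshape(n, -1)
        best = d.argmin(axis=1)
        d0 = d[np.arange(n), best]
        closest = cp.reshape(n, -1, 3)[np.arange(n), best]

        # exact re-query within the guaranteed radius
        radii = d0 + self.rmax + 1e-9
        groups = self.tree.query_ball_point(points, radii)
        counts = np.fromiter((len(g) for g in groups), dtype=np.int64, count=n)
        need = counts > k
        if need.any():
            flat_pts = np.repeat(np.nonzero(need)[0],
                                 counts[need])
            flat_faces = np.concatenate([groups[i] for i in
                                         np.nonzero(need)[0]])
            cp2 = closest_point_on_triangles(points[flat_pts],
                                             self.tri[flat_faces])
            d2 = np.linalg.norm(cp2 - points[flat_pts], axis=1)
            # segmented argmin
            order = np.argsort(flat_pts, kind="stable")
            fp, dd, cc = flat_pts[order], d2[order], cp2[order]
            starts = np.searchsorted(fp, np.nonzero(need)[0])
            ends = np.append(starts[1:], len(fp))
            for s, e, i in zip(starts, ends, np.nonzero(need)[0]):
                j = s + np.argmin(dd[s:e])
                if dd[j] < d0[i]:
                    d0[i] = dd[j]
                    closest[i] = cc[j]
        return d0, closest


def segment_surface_hits(starts: np.ndarray, ends: np.ndarray,
                         dist: SurfaceDistance,
                         eps: float = 1e-12) -> np.ndarray:
    """First intersection parameter t in (0, 1] of segments with a surface.

    Returns (n,) array of t values; np.inf where a segment does not cross.
    Candidate faces are gathered from the centroid KD-tree around each segment
    midpoint with a covering radius, then tested with Moller-Trumbore in one
    vectorized pass.
    """
    starts = np.asarray(starts, dtype=np.float64)
    ends = np.asarray(ends, dtype=np.float64)
    n = len(starts)
    mids = 0.5 * (starts + ends)
    half = 0.5 * np.linalg.norm(ends - starts, axis=1)
    groups = dist.tree.query_ball_point(mids, half + dist.rmax + 1e-9)
    counts = np.fromiter((len(g) for g in groups), dtype=np.int64, count=n)
    t_out = np.full(n, np.inf)
    if counts.sum() == 0:
        return t_out
    seg_idx = np.repeat(np.arange(n), counts)
    face_idx = np.concatenate([g for g in groups if g]) if counts.any() \
        else np.empty(0, dtype=np.int64)
    face_idx = np.asarray(face_idx, dtype=np.int64)

    tri = dist.tri[face_idx]
    orig = starts[seg_idx]
    d = ends[seg_idx] - starts[seg_idx]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > eps
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = orig - tri[:, 0]
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.einsum("ij,ij->i", d, qvec) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & \
        (t > 1e-12) & (t <= 1 + 1e-12)
    if hit.any():
        np.minimum.at(t_out, seg_idx[hit], t[hit])
    return t_out
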