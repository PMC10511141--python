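"""Boundary-fitting post-processing: smoothing, inflation, optimization.

After labeling, each FE compartment boundary is a staircase strictly enclosed
by its segmentation boundary (every claimed tet has all four nodes inside).
Post-processing deforms node positions -- labels are never changed here -- in
three stages:

* Taubin smoothing: alternating Laplacian steps, a forward step with factor
  lambda and a backward (inflating) step with factor mu, which smooths without
  the systematic shrinkage of plain Laplacian averaging.
* Inflation: boundary nodes move along mesh edges toward their intersection
  with the segmentation boundary, a fraction zeta of the remaining distance
  per pass, so the FE boundary approaches the segmentation from inside
  without ever crossing it.
* Optimization: inverted elements are repaired by retracting offending nodes
  into the hull of their edge neighbours ("supernode"), then 2-3 face flips
  (Delaunay turns) are applied to pairs of same-label tets whose condition
  kappa = volume / longest-edge falls below a threshold tau, whenever the
  flip strictly raises the pairwise minimum kappa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._geom import SurfaceDistance, segment_surface_hits
from .meshing import TetMesh, _all_faces, _face_order, tet_volumes
from .surfaces import SegmentationSpec

log = logging.getLogger(__name__)

__all__ = ["SmoothingParams", "InflationParams", "OptimizationParams",
           "taubin_smooth", "inflate_to_boundary", "tet_condition",
           "repair_inverted", "delaunay_optimize"]


@dataclass
class SmoothingParams:
    lam: float = 0.4        # forward (smoothing) factor, < 1
    mu: float = 0.4         # backward (inflating) factor, < 1
    xi: float = 0.9         # stopping tolerance on relative displacement
    max_iters: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.lam < 1 and 0 < self.mu < 1 and self.xi > 0):
            raise ValueError("require 0 < lam, mu < 1 and xi > 0")


@dataclass
class InflationParams:
    zeta: float = 0.05      # fraction of node-to-boundary distance per pass
    max_passes: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.zeta < 1:
            raise ValueError("require 0 < zeta < 1")


@dataclass
class OptimizationParams:
    tau: float = 0.01       # condition threshold, mm^2
    max_sweeps: int = 3

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


# ---------------------------------------------------------------------------
# connectivity helpers
# ---------------------------------------------------------------------------

def _edge_arrays(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique undirected edges of the tet mesh as two index arrays."""
    local = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])
    e = tets[:, local].reshape(-1, 2)
    e = np.sort(e, axis=1)
    e = np.unique(e, axis=0)
    return e[:, 0], e[:, 1]


def _interface_faces(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Faces between differently labeled tets; returns (faces, (t1, t2))."""
    faces, face_tets = _all_faces(mesh.tets)
    order = _face_order(faces)
    f, t = faces[order], face_tets[order]
    same = (f[1:] == f[:-1]).all(axis=1)
    i = np.nonzero(same)[0]
    cross = mesh.labels[t[i]] != mesh.labels[t[i + 1]]
    return f[i][cross], np.column_stack([t[i][cross], t[i + 1][cross]])


def hull_node_mask(mesh: TetMesh) -> np.ndarray:
    """Nodes on the outer hull of the lattice (kept fixed by smoothing)."""
    faces, _ = _all_faces(mesh.tets)
    order = _face_order(faces)
    f = faces[order]
    same = np.zeros(len(f), dtype=bool)
    eq = (f[1:] == f[:-1]).all(axis=1)
    same[1:] |= eq
    same[:-1] |= eq
    hull_nodes = np.unique(f[~same])
    mask = np.zeros(mesh.n_nodes, dtype=bool)
    mask[hull_nodes] = True
    return mask


# ---------------------------------------------------------------------------
# Taubin smoothing
# ---------------------------------------------------------------------------

def taubin_smooth(mesh: TetMesh, node_set: str = "volume",
                  params: SmoothingParams | None = None) -> TetMesh:
    """Alternating forward/backward Laplacian smoothing of node positions.

    node_set "volume": all interior nodes move, with all edge-connected
    neighbours in the averaging stencil.  node_set "surface": only nodes on
    compartment interfaces move, averaging over interface-edge neighbours
    only, so each boundary sheet is smoothed within itself.  Hull (bounding
    box) nodes are always fixed.  Stops when the relative displacement
    ||x_half - x|| / ||x_initial|| drops to xi or below.
    """
    params = params or SmoothingParams()
    if node_set == "volume":
        a, b = _edge_arrays(mesh.tets)
        movable = ~hull_node_mask(mesh)
    elif node_set == "surface":
        faces, _ = _interface_faces(mesh)
        if len(faces) == 0:
            return mesh
        fe = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]])
        fe = np.unique(np.sort(fe, axis=1), axis=0)
        a, b = fe[:, 0], fe[:, 1]
        movable = np.zeros(mesh.n_nodes, dtype=bool)
        movable[np.unique(faces)] = True
        movable &= ~hull_node_mask(mesh)
    else:
        raise ValueError("node_set must be 'volume' or 'surface'")

    from scipy import sparse
    x = mesh.nodes
    n = mesh.n_nodes
    ones = np.ones(len(a))
    adj = sparse.coo_matrix((np.concatenate([ones, ones]),
                             (np.concatenate([a, b]),
                              np.concatenate([b, a]))), shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    x0_norm = np.linalg.norm(x)

    def laplacian(pos: np.ndarray) -> np.ndarray:
        return (adj @ pos) / deg[:, None] - pos

    for _ in range(params.max_iters):
        lap = laplacian(x)
        step = params.lam * lap
        step[~movable] = 0.0
        x_half = x + step
        lap2 = laplacian(x_half)
        back = params.mu * lap2
        back[~movable] = 0.0
        x = x_half - back
        ratio = np.linalg.norm(step) / x0_norm
        if ratio <= params.xi:
            break
    mesh.nodes = x
    mesh.node_inside = {}
    return mesh


# ---------------------------------------------------------------------------
# inflation
# ---------------------------------------------------------------------------

def _region_boundary(mesh: TetMesh, region_labels: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Boundary nodes of the union of the region and their outward edges."""
    in_region = np.isin(mesh.labels, region_labels)
    faces, face_tets = _all_faces(mesh.tets)
    order = _face_order(faces)
    f, t = faces[order], face_tets[order]
    same = (f[1:] == f[:-1]).all(axis=1)
    i = np.nonzero(same)[0]
    cross = in_region[t[i]] != in_region[t[i + 1]]
    bnodes = np.unique(f[i][cross])
    return bnodes, in_region


def inflate_to_boundary(mesh: TetMesh, spec: SegmentationSpec,
                        params: InflationParams | None = None) -> TetMesh:
    """Lift FE boundary nodes toward their segmentation boundaries (Eq-style
    x <- x + zeta * d * e with d the distance to the intersection along the
    edge direction e).

    For each compartment (innermost first) the FE realization of its surface
    is the boundary of the union of all compartments with priority >= its
    own.  Each boundary node moves along the incident edge whose intersection
    with the segmentation surface is nearest; a fraction zeta < 1 of that
    distance per pass guarantees the node never crosses the surface.  Nodes
    with no intersecting incident edge are skipped (counted in the log).
    """
    params = params or InflationParams()
    prio = {cid: comp.priority for cid, comp in spec.by_priority()}
    ea, eb = _edge_arrays(mesh.tets)

    # labels and hence boundary topology are fixed during inflation: build the
    # per-compartment boundary node / incident edge sets and the candidate
    # face lists once, then re-test intersections each pass as nodes move.
    per_comp = []
    for cid, comp in spec.by_priority():
        region = np.array([c for c in prio if prio[c] >= prio[cid]])
        bnodes, in_region = _region_boundary(mesh, region)
        if len(bnodes) == 0:
            continue
        is_b = np.zeros(mesh.n_nodes, dtype=bool)
        is_b[bnodes] = True
        # nodes interior to the region (region nodes that are not boundary)
        region_nodes = np.zeros(mesh.n_nodes, dtype=bool)
        region_nodes[np.unique(mesh.tets[in_region])] = True
        inward = region_nodes & ~is_b
        # outward edges: from a boundary node to a node outside the region
        # interior -- these are the edges that can cross the segmentation
        sel_ab = is_b[ea] & ~inward[eb]
        sel_ba = is_b[eb] & ~inward[ea]
        src = np.concatenate([ea[sel_ab], eb[sel_ba]])
        dst = np.concatenate([eb[sel_ab], ea[sel_ba]])
        dist = SurfaceDistance(comp.surface)
        # candidate faces per segment with slack covering all later motion
        # (nodes only ever move along their edges by < the edge length)
        mids = 0.5 * (mesh.nodes[src] + mesh.nodes[dst])
        seg_len = np.linalg.norm(mesh.nodes[dst] - mesh.nodes[src], axis=1)
        groups = dist.tree.query_ball_point(mids, 1.5 * seg_len + dist.rmax
                                            + 1e-9)
        counts = np.fromiter((len(g) for g in groups), dtype=np.int64,
                             count=len(src))
        seg_idx = np.repeat(np.arange(len(src)), counts)
        face_idx = (np.concatenate([g for g in groups if g]).astype(np.int64)
                    if counts.any() else np.empty(0, dtype=np.int64))
        # static per-pair triangle data (the surface never moves)
        tri = dist.tri[face_idx]
        tri_data = (tri[:, 0].copy(), tri[:, 1] - tri[:, 0],
                    tri[:, 2] - tri[:, 0])
        per_comp.append((comp, bnodes, src, dst, seg_idx, tri_data))

    for _pass in range(params.max_passes):
        for comp, bnodes, src, dst, seg_idx, tri_data in per_comp:
            t_hit = _segment_hits_cached(mesh.nodes[src], mesh.nodes[dst],
                                         tri_data, seg_idx)
            seg = mesh.nodes[dst] - mesh.nodes[src]
            seg_len = np.linalg.norm(seg, axis=1)
            d_hit = np.where(np.isfinite(t_hit), t_hit * seg_len, np.inf)
            # nearest intersecting edge per node
            best_d = np.full(mesh.n_nodes, np.inf)
            np.minimum.at(best_d, src, d_hit)
            take = np.isfinite(d_hit) & (d_hit <= best_d[src] + 1e-12)
            winner = np.full(mesh.n_nodes, -1, dtype=np.int64)
            cand = np.nonzero(take)[0]
            winner[src[cand[::-1]]] = cand[::-1]
            chosen = winner[bnodes]
            ok = chosen >= 0
            moved = bnodes[ok]
            ce = chosen[ok]
            unit = seg[ce] / seg_len[ce][:, None]
            mesh.nodes[moved] = (mesh.nodes[moved]
                                 + params.zeta * d_hit[ce][:, None] * unit)
            skipped = int((~ok).sum())
            if skipped:
                log.debug("inflation %s pass %d: %d boundary nodes without "
                          "an intersecting edge", comp.name, _pass + 1,
                          skipped)
    mesh.node_inside = {}
    return mesh


def _segment_hits_cached(starts: np.ndarray, ends: np.ndarray,
                         tri_data: tuple, seg_idx: np.ndarray,
                         eps: float = 1e-12) -> np.ndarray:
    """Moller-Trumbore over precomputed (segment, candidate face) pairs."""
    n = len(starts)
    t_out = np.full(n, np.inf)
    if len(seg_idx) == 0:
        return t_out
    tri0, e1, e2 = tri_data
    orig = starts[seg_idx]
    d = ends[seg_idx] - starts[seg_idx]
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > eps
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = orig - tri0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.einsum("ij,ij->i", d, qvec) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & \
        (t > 1e-12) & (t <= 1 + 1e-12)
    if hit.any():
        np.minimum.at(t_out, seg_idx[hit], t[hit])
    return t_out


# ---------------------------------------------------------------------------
# element condition and optimization
# ---------------------------------------------------------------------------

def tet_condition(nodes_or_mesh, tets: np.ndarray | None = None) -> np.ndarray:
    """Condition kappa = volume / longest edge (mm^2); 0 iff degenerate.

    Accepts either (nodes, tets) arrays or a single (4, 3) tet, or a TetMesh.
    """
    if isinstance(nodes_or_mesh, TetMesh):
        nodes, tets = nodes_or_mesh.nodes, nodes_or_mesh.tets
    elif tets is None:
        tet = np.asarray(nodes_or_mesh, dtype=np.float64).reshape(1, 4, 3)
        vol = abs(np.linalg.det(tet[:, 1:] - tet[:, :1])) / 6.0
        local = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])
        el = np.linalg.norm(tet[:, local[:, 0]] - tet[:, local[:, 1]],
                            axis=2).max(axis=1)
        return float(vol[0] / el[0])
    else:
        nodes = nodes_or_mesh
    p = nodes[tets]
    vol = np.abs(np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                           np.cross(p[:, 2] - p[:, 0],
                                    p[:, 3] - p[:, 0]))) / 6.0
    local = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])
    el = np.linalg.norm(p[:, local[:, 0]] - p[:, local[:, 1]], axis=2)
    return vol / el.max(axis=1)


def repair_inverted(mesh: TetMesh, max_passes: int = 10) -> TetMesh:
    """Restore positive orientation by retracting offending nodes.

    A node of an inverted tet is moved toward the centroid of its
    edge-connected neighbour set (its supernode), which is a convex combination
    and therefore lies inside the supernode hull.  Iterates until no negative
    signed volume remains; raises if the cap is hit.
    """
    ea, eb = None, None
    for _ in range(max_passes):
        vols = tet_volumes(mesh.nodes, mesh.tets)
        bad = vols <= 0
        if not bad.any():
            return mesh
        if ea is None:
            ea, eb = _edge_arrays(mesh.tets)
        nodes_bad = np.unique(mesh.tets[bad])
        acc = np.zeros_like(mesh.nodes)
        deg = np.zeros(mesh.n_nodes)
        np.add.at(acc, ea, mesh.nodes[eb])
        np.add.at(acc, eb, mesh.nodes[ea])
        np.add.at(deg, ea, 1.0)
        np.add.at(deg, eb, 1.0)
        centroid = acc[nodes_bad] / deg[nodes_bad][:, None]
        # move halfway toward the supernode centroid (repeated per pass)
        mesh.nodes[nodes_bad] = 0.5 * (mesh.nodes[nodes_bad] + centroid)
    vols = tet_volumes(mesh.nodes, mesh.tets)
    bad = np.nonzero(vols <= 0)[0]
    if len(bad):
        raise RuntimeError(f"irreparable inverted elements: {bad[:20].tolist()}")
    return mesh


def delaunay_optimize(mesh: TetMesh, params: OptimizationParams | None = None
                      ) -> TetMesh:
    """2-3 face flips on low-condition same-label tet pairs.

    For each interior face whose two incident tets share a label and whose
    smaller condition is below tau, the pair is replaced by three tets around
    the apex-apex edge when (a) that edge actually pierces the shared face
    (the union is convex across it) and (b) the minimum condition strictly
    improves.  Faces between differently labeled tets are never flipped, so
    compartment boundaries are preserved.
    """
    params = params or OptimizationParams()
    for _sweep in range(params.max_sweeps):
        kappa = tet_condition(mesh)
        faces, pairs = _face_pairs_same_label(mesh)
        if len(faces) == 0:
            break
        kmin = np.minimum(kappa[pairs[:, 0]], kappa[pairs[:, 1]])
        cand = np.nonzero(kmin < params.tau)[0]
        if len(cand) == 0:
            break
        # process worst first
        cand = cand[np.argsort(kmin[cand])]
        dead = np.zeros(mesh.n_tets, dtype=bool)
        new_tets, new_labels = [], []
        n_flips = 0
        for ci in cand:
            t1, t2 = pairs[ci]
            if dead[t1] or dead[t2]:
                continue
            f = faces[ci]
            tet1, tet2 = mesh.tets[t1], mesh.tets[t2]
            p = int(np.setdiff1d(tet1, f)[0])
            q = int(np.setdiff1d(tet2, f)[0])
            flip = _try_flip(mesh.nodes, f, p, q,
                             min(float(kappa[t1]), float(kappa[t2])))
            if flip is None:
                continue
            dead[t1] = dead[t2] = True
            for tt in flip:
                new_tets.append(tt)
                new_labels.append(mesh.labels[t1])
            n_flips += 1
        if n_flips == 0:
            break
        keep = ~dead
        mesh.tets = np.vstack([mesh.tets[keep],
                               np.array(new_tets, dtype=np.int64)])
        mesh.labels = np.concatenate([mesh.labels[keep],
                                      np.array(new_labels, dtype=np.int64)])
        mesh.orient_positive()
        log.info("delaunay sweep %d: %d flips", _sweep + 1, n_flips)
    return mesh


def _face_pairs_same_label(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    faces, face_tets = _all_faces(mesh.tets)
    order = _face_order(faces)
    f, t = faces[order], face_tets[order]
    same = (f[1:] == f[:-1]).all(axis=1)
    i = np.nonzero(same)[0]
    ok = mesh.labels[t[i]] == mesh.labels[t[i + 1]]
    return f[i][ok], np.column_stack([t[i][ok], t[i + 1][ok]])


def _try_flip(nodes: np.ndarray, face: np.ndarray, p: int, q: int,
              old_kmin: float) -> list[np.ndarray] | None:
    """Evaluate the 2-3 flip; return the three new tets or None."""
    f1, f2, f3 = (int(v) for v in face)
    # the new edge p-q must pierce the shared face interior
    a, b, c = nodes[f1], nodes[f2], nodes[f3]
    n = np.cross(b - a, c - a)
    denom = np.dot(n, nodes[q] - nodes[p])
    if abs(denom) < 1e-300:
        return None
    t = np.dot(n, a - nodes[p]) / denom
    if not 1e-9 < t < 1 - 1e-9:
        return None
    x = nodes[p] + t * (nodes[q] - nodes[p])
    # normalized barycentric coordinates of the piercing point
    nn = np.dot(n, n)
    if nn < 1e-300:
        return None
    w1 = np.dot(np.cross(c - b, x - b), n) / nn
    w2 = np.dot(np.cross(a - c, x - c), n) / nn
    w3 = np.dot(np.cross(b - a, x - a), n) / nn
    if min(w1, w2, w3) <= 1e-9:
        return None
    cand = [np.array([p, q, f1, f2]), np.array([p, q, f2, f3]),
            np.array([p, q, f3, f1])]
    kappas = []
    out = []
    for tt in cand:
        pts = nodes[tt]
        v = np.dot(pts[1] - pts[0],
                   np.cross(pts[2] - pts[0], pts[3] - pts[0])) / 6.0
        if abs(v) < 1e-12:
            return None
        if v < 0:
            tt = tt[[0, 1, 3, 2]]
        out.append(tt)
        kappas.append(tet_condition(nodes[tt]))
    if min(kappas) <= old_kmin:
        return None
    return out
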