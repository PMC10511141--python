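"""Solid-angle point classification and hierarchical compartment labeling.

A mesh node at position r is inside a closed segmentation boundary when the
normalized solid angle subtended by the boundary,

    s = (1 / 4 pi) * sum_faces Omega_face(r),

reaches a threshold T (default 0.5).  Omega is evaluated per triangle with
the van Oosterom-Strackee arctangent formula, which stays well-conditioned
where the surface integral is nearly singular (points close to the surface).
A tetrahedron belongs to a compartment when all four of its nodes are inside
that compartment's boundary; with intersecting boundaries the compartment
that comes first in the innermost-to-outermost hierarchy takes priority.
Unclaimed tets keep label 0, the temporary bounding box that acts as the
outermost compartment.

Far-field acceleration: nodes provably farther from the surface than a
Hausdorff bound between the surface and a decimated proxy are classified
against the proxy (same solid-angle method, identical result inside the
guarantee); only the near band is evaluated against the full surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._geom import SurfaceDistance
from .meshing import TetMesh, _all_faces, _face_order
from .surfaces import SegmentationSpec, TriSurface, decimate_surface

log = logging.getLogger(__name__)

__all__ = ["SolidAngleParams", "solid_angle_fraction", "classify_points",
           "SolidAngleClassifier", "label_mesh", "relabel_recursive"]


@dataclass
class SolidAngleParams:
    threshold: float = 0.5        # T in (0, 1]; s >= T counts as inside
    batch_size: int = 1 << 15     # node chunk per kernel call
    use_proxy: bool = True        # far-field proxy acceleration

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def _solid_angle_numpy(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Sum of signed triangle solid angles for each point; (n,) in steradians."""
    a = tri[None, :, 0, :] - points[:, None, :]
    b = tri[None, :, 1, :] - points[:, None, :]
    c = tri[None, :, 2, :] - points[:, None, :]
    la = np.linalg.norm(a, axis=2)
    lb = np.linalg.norm(b, axis=2)
    lc = np.linalg.norm(c, axis=2)
    num = np.einsum("nmi,nmi->nm", a, np.cross(b, c))
    den = (la * lb * lc + np.einsum("nmi,nmi->nm", a, b) * lc
           + np.einsum("nmi,nmi->nm", a, c) * lb
           + np.einsum("nmi,nmi->nm", b, c) * la)
    # points coincident with a vertex: exclude that face (limit value)
    bad = (la < 1e-12) | (lb < 1e-12) | (lc < 1e-12)
    omega = 2.0 * np.arctan2(num, den)
    omega[bad] = 0.0
    return omega.sum(axis=1)


try:  # optional numba acceleration; numpy chunked fallback is equivalent
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _solid_angle_numba(points, tri):  # pragma: no cover - jitted
        n = points.shape[0]
        m = tri.shape[0]
        out = np.zeros(n)
        for i in range(n):
            px, py, pz = points[i, 0], points[i, 1], points[i, 2]
            acc = 0.0
            for f in range(m):
                ax = tri[f, 0, 0] - px
                ay = tri[f, 0, 1] - py
                az = tri[f, 0, 2] - pz
                bx = tri[f, 1, 0] - px
                by = tri[f, 1, 1] - py
                bz = tri[f, 1, 2] - pz
                cx = tri[f, 2, 0] - px
                cy = tri[f, 2, 1] - py
                cz = tri[f, 2, 2] - pz
                la = (ax * ax + ay * ay + az * az) ** 0.5
                lb = (bx * bx + by * by + bz * bz) ** 0.5
                lc = (cx * cx + cy * cy + cz * cz) ** 0.5
                if la < 1e-12 or lb < 1e-12 or lc < 1e-12:
                    continue
                # a . (b x c)
                num = (ax * (by * cz - bz * cy) + ay * (bz * cx - bx * cz)
                       + az * (bx * cy - by * cx))
                den = (la * lb * lc
                       + (ax * bx + ay * by + az * bz) * lc
                       + (ax * cx + ay * cy + az * cz) * lb
                       + (bx * cx + by * cy + bz * cz) * la)
                acc += 2.0 * np.arctan2(num, den)
            out[i] = acc
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def solid_angle_fraction(points: np.ndarray, surface: TriSurface,
                         batch_size: int = 1 << 15) -> np.ndarray:
    """Normalized solid angle s in [~0, ~1] of a closed surface at each point.

    s ~ 1 deep inside, ~ 0 far outside, 0.5 on a smooth part of the surface.
    Evaluated in batches so that many points amount to one flat pass (the
    batched-evaluation contract of the accelerated labeling stage).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tri = np.ascontiguousarray(surface.vertices[surface.faces])
    out = np.empty(len(pts))
    kernel = _solid_angle_numba if _HAVE_NUMBA else _solid_angle_numpy
    # keep numpy fallback chunks small enough to bound the (n x m) temporaries
    if not _HAVE_NUMBA:
        batch_size = max(1, min(batch_size, 40_000_000 // max(1, len(tri))))
    for i in range(0, len(pts), batch_size):
        out[i:i + batch_size] = kernel(
            np.ascontiguousarray(pts[i:i + batch_size]), tri)
    res = out / (4.0 * np.pi)
    return res if np.ndim(points) == 2 else res  # always (n,)


class SolidAngleClassifier:
    """Inside/outside classification for one closed surface with far-field
    proxy acceleration."""

    def __init__(self, surface: TriSurface, params: SolidAngleParams
                 | None = None):
        self.surface = surface
        self.params = params or SolidAngleParams()
        self.dist = SurfaceDistance(surface)
        self._max_edge = float(surface.edge_lengths().max())
        self.proxy = None
        self.margin = np.inf
        if self.params.use_proxy and surface.n_faces > 400:
            try:
                proxy = decimate_surface(
                    surface, target_faces=max(100, surface.n_faces // 12),
                    volume_tol=0.5)
                pd = SurfaceDistance(proxy)
                d_fine, _ = pd.query(surface.vertices)
                d_coarse, _ = self.dist.query(proxy.vertices)
                haus = max(d_fine.max(), d_coarse.max())
                self.margin = (haus + self._max_edge
                               + float(proxy.edge_lengths().max()))
                self.proxy = proxy
            except Exception as exc:  # decimation is best-effort
                log.warning("proxy construction failed (%s); using full "
                            "surface everywhere", exc)

    def fraction(self, points: np.ndarray) -> np.ndarray:
        return solid_angle_fraction(points, self.surface,
                                    self.params.batch_size)

    def inside(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: s >= T (points at exactly T count as inside)."""
        points = np.atleast_2d(points)
        T = self.params.threshold
        if self.proxy is None:
            return self.fraction(points) >= T
        # guaranteed lower bound on distance-to-surface via the vertex tree
        from scipy.spatial import cKDTree
        vt = getattr(self, "_vtree", None)
        if vt is None:
            vt = self._vtree = cKDTree(self.surface.vertices)
        dv, _ = vt.query(points)
        far = (dv - self._max_edge) > self.margin
        out = np.empty(len(points), dtype=bool)
        if far.any():
            out[far] = solid_angle_fraction(points[far], self.proxy,
                                            self.params.batch_size) >= T
        if (~far).any():
            out[~far] = solid_angle_fraction(points[~far], self.surface,
                                             self.params.batch_size) >= T
        return out


def classify_points(points: np.ndarray, surface: TriSurface,
                    params: SolidAngleParams | None = None) -> np.ndarray:
    """Convenience wrapper: boolean inside-mask for one surface."""
    return SolidAngleClassifier(surface, params).inside(points)


def _get_classifier(comp, params: SolidAngleParams) -> SolidAngleClassifier:
    cached = getattr(comp, "_classifier", None)
    if cached is None or cached.params.threshold != params.threshold \
            or cached.params.use_proxy != params.use_proxy:
        cached = SolidAngleClassifier(comp.surface, params)
        comp._classifier = cached
    return cached


# ---------------------------------------------------------------------------
# mesh labeling
# ---------------------------------------------------------------------------

def _ensure_masks(mesh: TetMesh, spec: SegmentationSpec,
                  params: SolidAngleParams,
                  node_ids: np.ndarray | None = None) -> None:
    """Fill mesh.node_inside caches (-1 unknown / 0 outside / 1 inside)."""
    if node_ids is None:
        node_ids = np.arange(mesh.n_nodes)
    for cid, comp in spec.by_priority():
        cache = mesh.node_inside.get(cid)
        if cache is None or len(cache) != mesh.n_nodes:
            cache = np.full(mesh.n_nodes, -1, dtype=np.int8)
            mesh.node_inside[cid] = cache
        todo = node_ids[cache[node_ids] < 0]
        if len(todo):
            clf = _get_classifier(comp, params)
            cache[todo] = clf.inside(mesh.nodes[todo]).astype(np.int8)


def _assign_labels(mesh: TetMesh, spec: SegmentationSpec,
                   tet_ids: np.ndarray) -> int:
    """Re-derive labels of the given tets from node masks; returns #changes."""
    new = np.zeros(len(tet_ids), dtype=np.int64)
    undecided = np.ones(len(tet_ids), dtype=bool)
    tn = mesh.tets[tet_ids]
    for cid, _comp in spec.by_priority():
        mask = mesh.node_inside[cid]
        all_in = (mask[tn] == 1).all(axis=1)
        take = undecided & all_in
        new[take] = cid
        undecided &= ~take
    changed = int((mesh.labels[tet_ids] != new).sum())
    mesh.labels[tet_ids] = new
    return changed


def label_mesh(mesh: TetMesh, spec: SegmentationSpec,
               params: SolidAngleParams | None = None) -> TetMesh:
    """Label every tet: innermost-to-outermost solid-angle classification.

    A tet gets a compartment's label iff all four nodes are inside the
    compartment surface and no higher-priority compartment has claimed it;
    everything else keeps the bounding-box label 0.
    """
    params = params or SolidAngleParams()
    mesh.node_inside = {k: v for k, v in mesh.node_inside.items()
                        if isinstance(v, np.ndarray) and len(v) == mesh.n_nodes}
    _ensure_masks(mesh, spec, params)
    _assign_labels(mesh, spec, np.arange(mesh.n_tets))
    return mesh


def _boundary_adjacent_tets(mesh: TetMesh) -> np.ndarray:
    """Tets sharing at least one node with any inter-label face (incl. hull)."""
    faces, face_tets = _all_faces(mesh.tets)
    order = _face_order(faces)
    f = faces[order]
    t = face_tets[order]
    same = (f[1:] == f[:-1]).all(axis=1)
    i = np.nonzero(same)[0]
    lab = mesh.labels
    cross = lab[t[i]] != lab[t[i + 1]]
    bnodes = np.unique(f[i][cross])
    if len(bnodes) == 0:
        return np.empty(0, dtype=np.int64)
    mask = np.isin(mesh.tets, bnodes).any(axis=1)
    return np.nonzero(mask)[0]


def relabel_recursive(mesh: TetMesh, spec: SegmentationSpec,
                      params: SolidAngleParams | None = None,
                      max_iter: int = 20) -> TetMesh:
    """Sharpen FE compartment boundaries after refinement.

    Each sweep re-derives the labels of tets adjacent to any current boundary
    from the (cached) solid-angle node classifications; the node masks are
    evaluated lazily for nodes not seen before (refinement midpoints).  Stops
    when a sweep changes no label; warns at the iteration cap.
    """
    params = params or SolidAngleParams()
    mesh.node_inside = {k: v for k, v in mesh.node_inside.items()
                        if isinstance(v, np.ndarray) and len(v) == mesh.n_nodes}
    for sweep in range(max_iter):
        tids = _boundary_adjacent_tets(mesh)
        if len(tids) == 0:
            break
        nodes = np.unique(mesh.tets[tids])
        _ensure_masks(mesh, spec, params, nodes)
        changed = _assign_labels(mesh, spec, tids)
        log.info("relabel sweep %d: %d tets checked, %d changed",
                 sweep + 1, len(tids), changed)
        if changed == 0:
            break
    else:
        log.warning("relabeling reached the iteration cap (%d) without "
                    "convergence", max_iter)
    return mesh
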