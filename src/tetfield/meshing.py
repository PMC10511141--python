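"""Tetrahedral mesh generation from a regular hexahedral lattice.

The initial (unfitted) mesh tiles an axis-aligned bounding box of the
segmentation with cubes of the requested spacing and splits each cube into
five tetrahedra -- the minimal cube subdivision.  The split is mirrored
between cubes of opposite parity so that the face diagonals of adjacent cubes
coincide, which keeps the mesh conforming and avoids the directional bias a
six-tet (all-same-diagonal) subdivision would imprint on smoothing and
inflation.

Refinement is red/green: tetrahedra selected for refinement are split into
eight children through their edge midpoints (red); neighbours that received
one, two or three split edges on a face are closed with 2-, 3- or 4-child
templates (green) so that no hanging nodes remain.  Neighbours whose split
edges cannot be covered by a single face are promoted to red and the closure
is iterated to a fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .surfaces import SegmentationSpec, TriSurface

log = logging.getLogger(__name__)

__all__ = [
    "HexLattice",
    "TetMesh",
    "build_lattice",
    "subdivide_hex_to_tets",
    "refine_volume",
    "refine_transition",
    "refine_mesh",
    "boundary_tet_mask",
    "extract_compartment_surface",
    "tet_volumes",
    "conformity_report",
]


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass
class HexLattice:
    """Regular hexahedral lattice: origin + isotropic spacing + cell counts."""

    origin: np.ndarray        # (3,) mm, lattice corner
    spacing: float            # mm
    counts: np.ndarray        # (3,) number of cells per axis

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if (self.counts < 1).any():
            raise ValueError("counts must be >= 1")

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.counts))

    def node_grid_shape(self) -> tuple[int, int, int]:
        return tuple(int(c) + 1 for c in self.counts)

    def upper(self) -> np.ndarray:
        return self.origin + self.spacing * self.counts


@dataclass
class TetMesh:
    """Node coordinates, 4-index tetrahedra and per-element compartment labels.

    Label 0 is the temporary bounding box ("outside"); labels >= 1 index
    compartments of the SegmentationSpec (1-based storage order).  All tets
    keep positive signed volume under the (v0, v1, v2, v3) convention
    det[v1-v0, v2-v0, v3-v0] > 0.
    """

    nodes: np.ndarray                       # (n, 3) float64, mm
    tets: np.ndarray                        # (m, 4) int64
    labels: np.ndarray                      # (m,) int64
    resolution: float = 0.0                 # initial lattice spacing, mm
    node_inside: dict = field(default_factory=dict, repr=False)
    # node_inside caches per-compartment solid-angle classifications
    # (compartment id -> bool array over nodes); maintained by labeling.

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets)

    def orient_positive(self) -> None:
        """Swap two vertices of negatively oriented tets in place."""
        v = self.volumes()
        bad = v < 0
        if bad.any():
            self.tets[bad] = self.tets[bad][:, [0, 1, 3, 2]]

    def copy(self) -> "TetMesh":
        return TetMesh(self.nodes.copy(), self.tets.copy(), self.labels.copy(),
                       self.resolution, dict(self.node_inside))

    # -- I/O (legacy ASCII VTK unstructured grid) --------------------------

    def save_vtk(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 2.0\ntetfield tetrahedral mesh\n"
                     "ASCII\nDATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {self.n_nodes} double\n")
            np.savetxt(fh, self.nodes, fmt="%.10g")
            fh.write(f"CELLS {self.n_tets} {self.n_tets * 5}\n")
            cells = np.column_stack([np.full(self.n_tets, 4), self.tets])
            np.savetxt(fh, cells, fmt="%d")
            fh.write(f"CELL_TYPES {self.n_tets}\n")
            np.savetxt(fh, np.full(self.n_tets, 10), fmt="%d")
            fh.write(f"CELL_DATA {self.n_tets}\nSCALARS label int 1\n"
                     "LOOKUP_TABLE default\n")
            np.savetxt(fh, self.labels, fmt="%d")

    @classmethod
    def load_vtk(cls, path: str | Path) -> "TetMesh":
        tokens = Path(path).read_text().split()
        i = tokens.index("POINTS")
        n = int(tokens[i + 1])
        nodes = np.array(tokens[i + 3:i + 3 + 3 * n],
                         dtype=np.float64).reshape(n, 3)
        i = tokens.index("CELLS")
        m = int(tokens[i + 1])
        raw = np.array(tokens[i + 3:i + 3 + 5 * m], dtype=np.int64).reshape(m, 5)
        tets = raw[:, 1:]
        labels = np.zeros(m, dtype=np.int64)
        if "CELL_DATA" in tokens:
            j = tokens.index("LOOKUP_TABLE")
            labels = np.array(tokens[j + 2:j + 2 + m], dtype=np.int64)
        return cls(nodes, tets, labels)


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes det[v1-v0, v2-v0, v3-v0] / 6."""
    p = nodes[tets]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


# ---------------------------------------------------------------------------
# lattice construction and 5-tet subdivision
# ---------------------------------------------------------------------------

def build_lattice(spec: SegmentationSpec, spacing: float) -> HexLattice:
    """Axis-aligned lattice enclosing the segmentation plus padding.

    The origin is snapped so that the model centroid sits at a cell center,
    which makes lattices reproducible regardless of the surfaces' absolute
    bounding box.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if not spec.compartments:
        raise ValueError("empty segmentation")
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    allv = []
    for c in spec.compartments:
        l, h = c.surface.bounds()
        lo = np.minimum(lo, l)
        hi = np.maximum(hi, h)
        allv.append(c.surface.vertices)
    pad = spec.bounding_box_padding
    lo -= pad
    hi += pad
    centroid = np.concatenate(allv).mean(axis=0)
    # snap: centroid at the center of some cell => origin = centroid - (k+1/2)h
    k = np.ceil((centroid - lo) / spacing - 0.5)
    origin = centroid - (k + 0.5) * spacing
    counts = np.ceil((hi - origin) / spacing).astype(np.int64)
    return HexLattice(origin=origin, spacing=spacing, counts=counts)


# local cube corner offsets, index = bit pattern (x + 2y + 4z)
_CUBE_OFFSETS = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
                          [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]],
                         dtype=np.int64)

# five-tet split for even-parity cubes: central tet on the even-bit corners
# {000, 110, 101, 011}, plus one corner tet per odd-bit corner
_FIVE_EVEN = np.array([[0, 3, 5, 6],
                       [1, 0, 3, 5],
                       [2, 0, 3, 6],
                       [4, 0, 5, 6],
                       [7, 3, 5, 6]], dtype=np.int64)
# mirrored split for odd-parity cubes (central tet on the odd-bit corners)
_FIVE_ODD = np.array([[1, 2, 4, 7],
                      [0, 1, 2, 4],
                      [3, 1, 2, 7],
                      [5, 1, 4, 7],
                      [6, 2, 4, 7]], dtype=np.int64)


def subdivide_hex_to_tets(lattice: HexLattice) -> TetMesh:
    """Split every cube into five tets with parity-alternating diagonals."""
    nx, ny, nz = (int(c) for c in lattice.counts)
    gx, gy, gz = nx + 1, ny + 1, nz + 1
    # node index = ix + gx*(iy + gy*iz)
    idx = np.arange(gx * gy * gz)
    cx = idx % gx
    cy = (idx // gx) % gy
    cz = idx // (gx * gy)
    nodes = lattice.origin[None, :] + lattice.spacing * np.column_stack(
        [cx, cy, cz]).astype(np.float64)

    ci, cj, ck = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    corner = np.empty((len(ci), 8), dtype=np.int64)
    for b, (dx, dy, dz) in enumerate(_CUBE_OFFSETS):
        corner[:, b] = (ci + dx) + gx * ((cj + dy) + gy * (ck + dz))
    parity = (ci + cj + ck) % 2
    tets = np.empty((len(ci) * 5, 4), dtype=np.int64)
    even = parity == 0
    for t in range(5):
        tets[np.nonzero(even)[0] * 5 + t] = corner[even][:, _FIVE_EVEN[t]]
        tets[np.nonzero(~even)[0] * 5 + t] = corner[~even][:, _FIVE_ODD[t]]
    mesh = TetMesh(nodes, tets, np.zeros(len(tets), dtype=np.int64),
                   resolution=lattice.spacing)
    mesh.orient_positive()
    return mesh


# ---------------------------------------------------------------------------
# red/green refinement
# ---------------------------------------------------------------------------

_LOCAL_EDGES = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]],
                        dtype=np.int64)
# faces as (vertex triple) with the local ids of their three edges
_LOCAL_FACES = {
    frozenset({0, 1, 3}): (0, 1, 2),   # edges 01, 02, 12 -> face (0,1,2)
    frozenset({0, 2, 4}): (0, 1, 3),   # edges 01, 03, 13 -> face (0,1,3)
    frozenset({1, 2, 5}): (0, 2, 3),   # edges 02, 03, 23 -> face (0,2,3)
    frozenset({3, 4, 5}): (1, 2, 3),   # edges 12, 13, 23 -> face (1,2,3)
}


def _edge_keys(tets: np.ndarray, n_nodes: int) -> np.ndarray:
    """(m, 6) int64 keys min*n + max for the six edges of each tet."""
    e = tets[:, _LOCAL_EDGES]                       # (m, 6, 2)
    lo = e.min(axis=2).astype(np.int64)
    hi = e.max(axis=2).astype(np.int64)
    return lo * np.int64(n_nodes) + hi


def _face_of_pattern(pattern: int) -> tuple[int, int, int] | None:
    """Face (local vertex triple) covering all split edges, or None."""
    ids = frozenset(i for i in range(6) if pattern >> i & 1)
    for face_ids, verts in _LOCAL_FACES.items():
        if ids <= face_ids:
            return verts
    return None


def refine_mesh(mesh: TetMesh, red_mask: np.ndarray,
                max_closure_passes: int = 30) -> TetMesh:
    """Red/green refinement: red tets -> 8 children, conforming green closure.

    Children inherit their parent's label.  The result contains no hanging
    nodes: every split-edge midpoint is a vertex of all tets incident to that
    edge (audited by tests, not here).
    """
    red = np.asarray(red_mask, dtype=bool).copy()
    if not red.any():
        return mesh
    n = mesh.n_nodes
    keys = _edge_keys(mesh.tets, n)

    # closure: promote tets whose split edges do not fit a single face
    for _ in range(max_closure_passes):
        split = np.unique(keys[red])
        hit = np.isin(keys, split)                   # (m, 6)
        pattern = (hit * (1 << np.arange(6))).sum(axis=1)
        promote = np.zeros(mesh.n_tets, dtype=bool)
        for pat in np.unique(pattern[~red]):
            if pat == 0:
                continue
            if _face_of_pattern(int(pat)) is None:
                promote |= (~red) & (pattern == pat)
        if not promote.any():
            break
        red |= promote
    else:
        raise RuntimeError("refinement closure did not stabilize")

    split = np.unique(keys[red])
    hit = np.isin(keys, split)
    pattern = (hit * (1 << np.arange(6))).sum(axis=1)

    # midpoint nodes for every split edge
    lo = (split // n).astype(np.int64)
    hi = (split % n).astype(np.int64)
    mids = 0.5 * (mesh.nodes[lo] + mesh.nodes[hi])
    mid_index = {int(k): n + i for i, k in enumerate(split)}
    nodes = np.vstack([mesh.nodes, mids])

    def midpoint(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        k = np.minimum(a, b).astype(np.int64) * np.int64(n) + np.maximum(a, b)
        return np.array([mid_index[int(x)] for x in k], dtype=np.int64)

    out_tets: list[np.ndarray] = []
    out_labels: list[np.ndarray] = []

    # untouched tets
    keep = (~red) & (pattern == 0)
    out_tets.append(mesh.tets[keep])
    out_labels.append(mesh.labels[keep])

    # ---- red: 8 children ---------------------------------------------------
    rt = mesh.tets[red]
    rl = mesh.labels[red]
    if len(rt):
        v = [rt[:, i] for i in range(4)]
        m = {}
        for (i, j) in [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]:
            m[(i, j)] = midpoint(v[i], v[j])
        for corner in [
            np.column_stack([v[0], m[(0, 1)], m[(0, 2)], m[(0, 3)]]),
            np.column_stack([v[1], m[(0, 1)], m[(1, 2)], m[(1, 3)]]),
            np.column_stack([v[2], m[(0, 2)], m[(1, 2)], m[(2, 3)]]),
            np.column_stack([v[3], m[(0, 3)], m[(1, 3)], m[(2, 3)]]),
        ]:
            out_tets.append(corner)
            out_labels.append(rl)
        # octahedron: split along the shortest of the three diagonals
        # (ties broken by the smallest sorted node-index pair -> deterministic)
        diags = [(m[(0, 1)], m[(2, 3)]), (m[(0, 2)], m[(1, 3)]),
                 (m[(0, 3)], m[(1, 2)])]
        dlen = np.column_stack([
            np.linalg.norm(nodes[a] - nodes[b], axis=1) for a, b in diags])
        dkey = np.column_stack([
            np.minimum(a, b) * np.int64(len(nodes)) + np.maximum(a, b)
            for a, b in diags])
        near = np.abs(dlen - dlen.min(axis=1)[:, None]) < 1e-9
        masked_key = np.where(near, dkey, np.iinfo(np.int64).max)
        best = np.argmin(masked_key, axis=1)
        # ring of the remaining 4 midpoints around each diagonal, in edge order
        cycles = {0: [(0, 2), (1, 2), (1, 3), (0, 3)],
                  1: [(0, 1), (1, 2), (2, 3), (0, 3)],
                  2: [(0, 1), (1, 3), (2, 3), (0, 2)]}
        for c in range(3):
            sel = best == c
            if not sel.any():
                continue
            a, b = diags[c][0][sel], diags[c][1][sel]
            ring = [m[e][sel] for e in cycles[c]]
            for q in range(4):
                out_tets.append(np.column_stack(
                    [a, b, ring[q], ring[(q + 1) % 4]]))
                out_labels.append(rl[sel])

    # ---- green templates ---------------------------------------------------
    green = (~red) & (pattern > 0)
    gt_idx = np.nonzero(green)[0]
    for pat in np.unique(pattern[gt_idx]):
        sel = gt_idx[pattern[gt_idx] == pat]
        t = mesh.tets[sel]
        lab = mesh.labels[sel]
        edge_ids = [i for i in range(6) if int(pat) >> i & 1]
        if len(edge_ids) == 1:
            p_, q_ = _LOCAL_EDGES[edge_ids[0]]
            rest = [i for i in range(4) if i not in (p_, q_)]
            m_ = midpoint(t[:, p_], t[:, q_])
            out_tets.append(np.column_stack(
                [t[:, p_], m_, t[:, rest[0]], t[:, rest[1]]]))
            out_tets.append(np.column_stack(
                [m_, t[:, q_], t[:, rest[0]], t[:, rest[1]]]))
            out_labels.extend([lab, lab])
        elif len(edge_ids) == 2:
            e1, e2 = _LOCAL_EDGES[edge_ids[0]], _LOCAL_EDGES[edge_ids[1]]
            shared = (set(e1) & set(e2)).pop()
            b_ = (set(e1) - {shared}).pop()
            c_ = (set(e2) - {shared}).pop()
            d_ = (set(range(4)) - {shared, b_, c_}).pop()
            a = t[:, shared]
            b = t[:, b_]
            c = t[:, c_]
            d = t[:, d_]
            mab = midpoint(a, b)
            mac = midpoint(a, c)
            out_tets.append(np.column_stack([a, mab, mac, d]))
            out_labels.append(lab)
            # canonical quad diagonal on face (a, b, c): (mab, c) vs (b, mac)
            d1 = np.linalg.norm(nodes[mab] - nodes[c], axis=1)
            d2 = np.linalg.norm(nodes[b] - nodes[mac], axis=1)
            k1 = (np.minimum(mab, c) * np.int64(len(nodes)) +
                  np.maximum(mab, c))
            k2 = (np.minimum(b, mac) * np.int64(len(nodes)) +
                  np.maximum(b, mac))
            use1 = np.where(np.abs(d1 - d2) < 1e-9, k1 < k2, d1 < d2)
            for mask, tet_a, tet_b in [
                (use1,
                 np.column_stack([mab, b, c, d]),
                 np.column_stack([mab, c, mac, d])),
                (~use1,
                 np.column_stack([mab, b, mac, d]),
                 np.column_stack([b, c, mac, d])),
            ]:
                if mask.any():
                    out_tets.append(tet_a[mask])
                    out_tets.append(tet_b[mask])
                    out_labels.extend([lab[mask], lab[mask]])
        else:  # 3 split edges forming one face
            fa, fb, fc = _face_of_pattern(int(pat))
            d_ = (set(range(4)) - {fa, fb, fc}).pop()
            a, b, c, d = t[:, fa], t[:, fb], t[:, fc], t[:, d_]
            mab = midpoint(a, b)
            mbc = midpoint(b, c)
            mca = midpoint(c, a)
            out_tets.append(np.column_stack([a, mab, mca, d]))
            out_tets.append(np.column_stack([b, mbc, mab, d]))
            out_tets.append(np.column_stack([c, mca, mbc, d]))
            out_tets.append(np.column_stack([mab, mbc, mca, d]))
            out_labels.extend([lab] * 4)

    new = TetMesh(nodes, np.vstack(out_tets), np.concatenate(out_labels),
                  resolution=mesh.resolution)
    new.orient_positive()
    # original node indices are preserved: carry classification caches over,
    # marking the appended midpoints as not-yet-evaluated (-1)
    pad = np.full(len(mids), -1, dtype=np.int8)
    new.node_inside = {k: np.concatenate([v, pad])
                       for k, v in mesh.node_inside.items()
                       if isinstance(v, np.ndarray) and len(v) == n}
    return new


def refine_volume(mesh: TetMesh, region: set[int] | list[int],
                  closure: bool = True) -> TetMesh:
    """Uniformly refine all tets whose label is in ``region`` (red split).

    With ``closure`` (default) the surrounding transition tets are refined by
    the green templates so the output is conforming.
    """
    region = set(int(r) for r in region)
    red = np.isin(mesh.labels, list(region)) if region else \
        np.zeros(mesh.n_tets, dtype=bool)
    if not red.any():
        return mesh
    if not closure:
        raise NotImplementedError("refinement without closure would leave "
                                  "hanging nodes; use refine_mesh directly")
    return refine_mesh(mesh, red)


def boundary_tet_mask(mesh: TetMesh, label_a: int,
                      label_b: int | None = None) -> np.ndarray:
    """Tets touching (by node) the interface between label_a and label_b.

    With label_b None: the interface between label_a and everything else.
    Both sides of the boundary are included, giving the "two similar
    refinements on both sides" semantics.
    """
    in_a = mesh.labels == label_a
    faces, face_tets = _all_faces(mesh.tets)
    # boundary faces: shared by one tet in A and one not in A (or hull)
    order = _face_order(faces)
    f = faces[order]
    t = face_tets[order]
    samef = (f[1:] == f[:-1]).all(axis=1)
    i = np.nonzero(samef)[0]
    t1, t2 = t[i], t[i + 1]
    if label_b is None:
        cross = in_a[t1] != in_a[t2]
    else:
        cross = ((mesh.labels[t1] == label_a) & (mesh.labels[t2] == label_b)) | \
                ((mesh.labels[t1] == label_b) & (mesh.labels[t2] == label_a))
    bnodes = np.unique(f[i][cross])
    mask = np.isin(mesh.tets, bnodes).any(axis=1)
    return mask


def refine_transition(mesh: TetMesh, already_red: np.ndarray) -> TetMesh:
    """Green-close a mesh around a red-refined region.

    Provided for API symmetry; :func:`refine_mesh` performs red subdivision
    and green closure in one conforming pass, which is what the pipeline uses.
    """
    return refine_mesh(mesh, already_red)


# ---------------------------------------------------------------------------
# surface extraction and audits
# ---------------------------------------------------------------------------

# outward faces of a positively oriented tet (v0, v1, v2, v3)
_OUTWARD_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]],
                          dtype=np.int64)


def _all_faces(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All 4m faces (sorted vertex triples) and their tet of origin."""
    m = len(tets)
    faces = tets[:, _OUTWARD_FACES].reshape(4 * m, 3)
    faces = np.sort(faces, axis=1)
    face_tets = np.repeat(np.arange(m), 4)
    return faces, face_tets


def _face_order(faces: np.ndarray) -> np.ndarray:
    """Sorting order grouping identical (row-sorted) faces.

    Packs each triple into one int64 key when the node-id range allows it
    (single argsort, ~3x faster than a three-column lexsort); falls back to
    lexsort otherwise.
    """
    n = int(faces.max()) + 1 if len(faces) else 1
    if n < 2_000_000:
        key = (faces[:, 0].astype(np.int64) * n
               + faces[:, 1]) * n + faces[:, 2]
        return np.argsort(key, kind="stable")
    return np.lexsort(faces.T[::-1])


def extract_compartment_surface(mesh: TetMesh, compartment: int) -> TriSurface:
    """Closed outward-oriented boundary of the union of tets with a label.

    The face audit is a flat vectorized pass over all element faces (the
    batched-evaluation contract): faces occurring exactly once among the
    compartment's tets form the boundary.
    """
    sel = mesh.labels == compartment
    if not sel.any():
        raise ValueError(f"label {compartment} absent from mesh")
    tets = mesh.tets[sel]
    oriented = tets[:, _OUTWARD_FACES].reshape(-1, 3)
    key = np.sort(oriented, axis=1)
    order = np.lexsort(key.T[::-1])
    k = key[order]
    dup = np.zeros(len(k), dtype=bool)
    same = (k[1:] == k[:-1]).all(axis=1)
    dup[1:] |= same
    dup[:-1] |= same
    boundary = oriented[order][~dup]
    used, inv = np.unique(boundary, return_inverse=True)
    surf = TriSurface(mesh.nodes[used], inv.reshape(-1, 3))
    return surf


def conformity_report(mesh: TetMesh) -> dict:
    """Global face audit: interior faces shared by exactly 2 tets.

    Returns counts; a conforming mesh has ``bad_faces == 0``.
    """
    faces, _ = _all_faces(mesh.tets)
    order = _face_order(faces)
    f = faces[order]
    same_prev = np.concatenate([[False], (f[1:] == f[:-1]).all(axis=1)])
    # run lengths
    group_start = np.nonzero(~same_prev)[0]
    counts = np.diff(np.append(group_start, len(f)))
    n_interior = int((counts == 2).sum())
    n_hull = int((counts == 1).sum())
    n_bad = int((counts > 2).sum())
    vols = mesh.volumes()
    return dict(interior_faces=n_interior, hull_faces=n_hull,
                bad_faces=n_bad, inverted=int((vols <= 0).sum()),
                total_volume=float(vols.sum()))
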