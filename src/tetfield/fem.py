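"""EEG forward modeling: P1 finite elements, dipolar sources, lead fields.

The electric potential u solves the conductivity Poisson equation
div(sigma grad u) = div J_p in the head with the insulating Neumann condition
(sigma grad u) . n = 0 on the scalp.  Discretized with linear tetrahedral
elements this is A z = G x; point measurements are y = R z, giving the lead
field L = R A^-1 G, computed column-by-electrode with the transfer-matrix
trick: solve A^T t_e = R^T delta_e per electrode, then L = T^T G.

Dipoles are realized either as divergence-conforming (RT0 face-based)
interpolants of the host tet with minimum-norm moment-matching coefficients
("hdiv", default) or as classical partial-integration point dipoles
("partial_integration", cross-check fallback).

Internally everything is converted to SI (meters); inputs are the package's
millimeter geometry, conductivities in S/m, moments in A*m, potentials in V.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as sla

from ._geom import SurfaceDistance
from .meshing import TetMesh, _all_faces, _face_order, tet_volumes
from .surfaces import ElectrodeSet, SegmentationSpec

log = logging.getLogger(__name__)

__all__ = ["ConductivityField", "StiffnessSystem", "SourceSpace", "LeadField",
           "conductivity_from_spec", "assemble_stiffness",
           "build_source_space", "compute_lead_field", "forward_potentials",
           "rdm_mag"]


# ---------------------------------------------------------------------------
# conductivity and stiffness
# ---------------------------------------------------------------------------

@dataclass
class ConductivityField:
    """Per-tet scalar conductivity (S/m)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values[np.isfinite(self.values)] < 0).any():
            raise ValueError("conductivities must be > 0")


def conductivity_from_spec(mesh: TetMesh, spec: SegmentationSpec
                           ) -> ConductivityField:
    """Map labels to conductivities; label 0 (bounding box) gets 0 and is
    excluded from the FE domain."""
    sigma = np.zeros(mesh.n_tets)
    for cid, comp in spec.by_priority():
        sigma[mesh.labels == cid] = comp.conductivity
    return ConductivityField(sigma)


@dataclass
class StiffnessSystem:
    """Assembled Neumann stiffness matrix over the conducting domain.

    ``A`` is restricted to nodes of tets with sigma > 0 ("active" nodes,
    indexed by ``active_nodes`` into the mesh).  A is symmetric positive
    semi-definite with the constant vector in its null space (pure Neumann);
    the gauge is fixed during solves and results are average-referenced.
    """

    A: sparse.csr_matrix
    active_nodes: np.ndarray            # global node ids, len = A.shape[0]
    node_map: np.ndarray                # global -> active index (-1 outside)
    tets: np.ndarray                    # (m, 4) active-node indices
    tet_ids: np.ndarray                 # original tet ids in the mesh
    grads: np.ndarray                   # (m, 4, 3) P1 gradients, 1/m
    volumes: np.ndarray                 # (m,) m^3
    mesh: TetMesh = field(repr=False, default=None)
    _solve = None                       # cached solver closure

    def solver(self, rtol: float = 1e-8):
        """Return a solve(rhs) closure for the grounded SPD system.

        Conjugate gradients preconditioned with zero-fill incomplete
        Cholesky; the factorization is built once and reused across the many
        per-electrode transfer solves.
        """
        if self._solve is not None:
            return self._solve
        from ._solvers import IChol0, pcg
        n = self.A.shape[0]
        keep = np.arange(n - 1)             # ground the last active node
        Ared = self.A[keep][:, keep].tocsr()
        M = IChol0(Ared)

        def solve(rhs: np.ndarray) -> np.ndarray:
            x, _ = pcg(Ared, rhs[keep], M, rtol=rtol)
            out = np.zeros(n)
            out[:-1] = x
            return out

        self._solve = solve
        return solve


def assemble_stiffness(mesh: TetMesh, conductivity: ConductivityField
                       ) -> StiffnessSystem:
    """P1 stiffness: A_ij = sum_K sigma_K V_K grad(phi_i) . grad(phi_j)."""
    sigma = conductivity.values
    act = sigma > 0
    if not act.any():
        raise ValueError("no conducting elements")
    tet_ids = np.nonzero(act)[0]
    tets_g = mesh.tets[act]
    nodes_m = mesh.nodes * 1e-3                       # mm -> m
    p = nodes_m[tets_g]
    e = p[:, 1:] - p[:, :1]                           # (m, 3, 3) edge matrix
    vol = np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2])) / 6.0
    if (np.abs(vol) < 1e-300).any():
        bad = tet_ids[np.abs(vol) < 1e-300]
        raise ValueError(f"singular element geometry in tets {bad[:10]}")
    inv = np.linalg.inv(e.transpose(0, 2, 1))         # rows: grads of l1..l3
    grads = np.empty((len(tets_g), 4, 3))
    grads[:, 1:] = inv
    grads[:, 0] = -grads[:, 1:].sum(axis=1)

    w = (sigma[act] * np.abs(vol))[:, None, None]
    Ke = w * np.einsum("mid,mjd->mij", grads, grads)  # (m, 4, 4)

    active_nodes = np.unique(tets_g)
    node_map = np.full(mesh.n_nodes, -1, dtype=np.int64)
    node_map[active_nodes] = np.arange(len(active_nodes))
    t = node_map[tets_g]
    rows = np.repeat(t, 4, axis=1).ravel()
    cols = np.tile(t, (1, 4)).ravel()
    A = sparse.coo_matrix((Ke.ravel(), (rows, cols)),
                          shape=(len(active_nodes),) * 2).tocsr()
    return StiffnessSystem(A=A, active_nodes=active_nodes, node_map=node_map,
                           tets=t, tet_ids=tet_ids, grads=grads,
                           volumes=np.abs(vol), mesh=mesh)


# ---------------------------------------------------------------------------
# source space
# ---------------------------------------------------------------------------

@dataclass
class SourceSpace:
    """Dipole positions/orientations with their host tets.

    orientations has shape (k, dof, 3) with dof = 3 (cartesian) or 1
    (normal-constrained); lead-field columns follow this layout flattened.
    """

    positions: np.ndarray               # (k, 3) mm
    orientations: np.ndarray            # (k, dof, 3) unit vectors
    host_tets: np.ndarray               # (k,) tet ids in the mesh
    compartments: np.ndarray            # (k,) labels
    mode: str = "cartesian"

    @property
    def n_sources(self) -> int:
        return len(self.positions)

    @property
    def dof(self) -> int:
        return self.orientations.shape[1]

    def eccentricities(self, reference_radius: float,
                       center: np.ndarray | None = None) -> np.ndarray:
        c = np.zeros(3) if center is None else np.asarray(center)
        return np.linalg.norm(self.positions - c, axis=1) / reference_radius


def admissible_tet_mask(mesh: TetMesh, active_labels: np.ndarray) -> np.ndarray:
    """Active-compartment tets not inside or next to a boundary-touching tet."""
    faces, face_tets = _all_faces(mesh.tets)
    order = _face_order(faces)
    f, t = faces[order], face_tets[order]
    same = (f[1:] == f[:-1]).all(axis=1)
    i = np.nonzero(same)[0]
    cross = mesh.labels[t[i]] != mesh.labels[t[i + 1]]
    bnodes = np.unique(f[i][cross])
    node_flag = np.zeros(mesh.n_nodes, dtype=bool)
    node_flag[bnodes] = True
    touching = node_flag[mesh.tets].any(axis=1)       # tets touching a boundary
    excl_nodes = np.zeros(mesh.n_nodes, dtype=bool)
    excl_nodes[np.unique(mesh.tets[touching])] = True
    next_to = excl_nodes[mesh.tets].any(axis=1)       # touching or adjacent
    return np.isin(mesh.labels, active_labels) & ~next_to


def build_source_space(mesh: TetMesh, spec: SegmentationSpec,
                       n_sources: int = 1000,
                       orientation_mode: str = "cartesian",
                       seed: int = 0) -> SourceSpace:
    """Uniform-in-volume dipole sampling over admissible active-compartment
    tets; deterministic under seed.

    normal_constrained orientations point along the outward normal of the
    compartment's segmentation boundary (direction from the source to its
    closest boundary point), emulating cortical sources oriented along the
    local surface normal.
    """
    active = np.array([cid for cid, c in spec.by_priority() if c.active])
    if len(active) == 0:
        raise ValueError("no active compartments")
    ok = admissible_tet_mask(mesh, active)
    tids = np.nonzero(ok)[0]
    if len(tids) == 0:
        raise ValueError("no admissible tets for source placement")
    vols = np.abs(tet_volumes(mesh.nodes, mesh.tets[tids]))
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(tids), size=n_sources, p=vols / vols.sum())
    # uniform barycentric coordinates via sorted uniforms
    u = np.sort(rng.random((n_sources, 3)), axis=1)
    bary = np.column_stack([u[:, 0], u[:, 1] - u[:, 0], u[:, 2] - u[:, 1],
                            1.0 - u[:, 2]])
    host = tids[pick]
    pos = np.einsum("kij,ki->kj", mesh.nodes[mesh.tets[host]], bary)

    if orientation_mode == "cartesian":
        orient = np.broadcast_to(np.eye(3), (n_sources, 3, 3)).copy()
    elif orientation_mode == "normal_constrained":
        orient = np.empty((n_sources, 1, 3))
        labels = mesh.labels[host]
        for cid, comp in spec.by_priority():
            sel = labels == cid
            if not sel.any():
                continue
            sd = SurfaceDistance(comp.surface)
            d, cp = sd.query(pos[sel])
            vec = cp - pos[sel]
            nrm = np.linalg.norm(vec, axis=1)
            orient[sel, 0] = vec / np.maximum(nrm, 1e-12)[:, None]
    else:
        raise ValueError("orientation_mode must be 'cartesian' or "
                         "'normal_constrained'")
    return SourceSpace(positions=pos, orientations=orient, host_tets=host,
                       compartments=mesh.labels[host], mode=orientation_mode)


# ---------------------------------------------------------------------------
# dipolar right-hand sides
# ---------------------------------------------------------------------------

def _tet_neighbors_by_face(system: StiffnessSystem) -> dict:
    """face (sorted triple of active ids) -> list of local tet indices."""
    m = len(system.tets)
    local = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])
    faces = np.sort(system.tets[:, local].reshape(-1, 3), axis=1)
    owner = np.repeat(np.arange(m), 4)
    opp = np.tile(np.arange(4), m)
    order = _face_order(faces)
    return faces[order], owner[order], opp[order]


def build_rhs(system: StiffnessSystem, sources: SourceSpace,
              mode: str = "hdiv") -> sparse.csr_matrix:
    """Sparse G: active nodes x source coefficients (one column per dof).

    partial_integration: g_i = q . grad(phi_i)(x0) over the host tet nodes
    (integrating both sides of the PDE by parts cancels the minus signs).
    hdiv: minimum-norm RT0 face coefficients of the host tet matched to the
    dipole moment, assembled over the full (two-tet) support of each face
    function; reduces to a divergence-conforming dipole-like source.
    """
    mesh = system.mesh
    global_to_local = np.full(mesh.n_tets, -1, dtype=np.int64)
    global_to_local[system.tet_ids] = np.arange(len(system.tet_ids))
    host = global_to_local[sources.host_tets]
    if (host < 0).any():
        raise ValueError("source hosted in a non-conducting tet")
    dof = sources.dof
    rows, cols, vals = [], [], []

    if mode == "partial_integration":
        for k in range(sources.n_sources):
            t = host[k]
            g = system.grads[t]                       # (4, 3)
            for d in range(dof):
                q = sources.orientations[k, d]        # A*m, unit here
                rhs = g @ q
                rows.append(system.tets[t])
                cols.append(np.full(4, k * dof + d))
                vals.append(rhs)
    elif mode == "hdiv":
        faces, owner, opp = _tet_neighbors_by_face(system)
        # neighbor lookup: for each (tet, face) its partner tet/opposite node
        partner = np.full(len(faces), -1, dtype=np.int64)
        same = (faces[1:] == faces[:-1]).all(axis=1)
        i = np.nonzero(same)[0]
        partner[i] = i + 1
        partner[i + 1] = i
        # index by (owner, opp): build (m, 4) tables
        m = len(system.tets)
        nb_tet = np.full((m, 4), -1, dtype=np.int64)
        nb_opp = np.full((m, 4), -1, dtype=np.int64)
        for j in range(len(faces)):
            pj = partner[j]
            if pj >= 0:
                nb_tet[owner[j], opp[j]] = owner[pj]
                nb_opp[owner[j], opp[j]] = opp[pj]
        nodes_m = mesh.nodes * 1e-3
        for k in range(sources.n_sources):
            t = host[k]
            tn = system.tets[t]
            pts = nodes_m[system.active_nodes[tn]]
            cK = pts.mean(axis=0)
            # RT0 moments over full support, per host face (opposite node i)
            moments = np.empty((4, 3))
            contribs = []                             # per face: (nodes, per-node vecs)
            for i_loc in range(4):
                V = system.volumes[t]
                fidx = [j for j in range(4) if j != i_loc]
                tri = pts[fidx]
                area = 0.5 * np.linalg.norm(
                    np.cross(tri[1] - tri[0], tri[2] - tri[0]))
                mvec = area * (cK - pts[i_loc]) / 3.0
                ent_nodes = [tn]
                ent_vecs = [(area / 3.0) * (system.grads[t]
                                            @ (cK - pts[i_loc]))]
                t2 = nb_tet[t, i_loc]
                if t2 >= 0:
                    tn2 = system.tets[t2]
                    pts2 = nodes_m[system.active_nodes[tn2]]
                    c2 = pts2.mean(axis=0)
                    p_opp2 = pts2[nb_opp[t, i_loc]]
                    mvec = mvec - area * (c2 - p_opp2) / 3.0
                    ent_nodes.append(tn2)
                    ent_vecs.append(-(area / 3.0) * (system.grads[t2]
                                                     @ (c2 - p_opp2)))
                moments[i_loc] = mvec
                contribs.append((ent_nodes, ent_vecs))
            coeff_basis = np.linalg.pinv(moments.T)   # (4, 3): c = pinv @ q
            for d in range(dof):
                q = sources.orientations[k, d]
                cvec = coeff_basis @ q
                for i_loc in range(4):
                    for nset, vset in zip(*contribs[i_loc]):
                        rows.append(nset)
                        cols.append(np.full(4, k * dof + d))
                        vals.append(cvec[i_loc] * vset)
    else:
        raise ValueError("mode must be 'hdiv' or 'partial_integration'")

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    G = sparse.coo_matrix((vals, (rows, cols)),
                          shape=(system.A.shape[0],
                                 sources.n_sources * dof)).tocsr()
    return G


# ---------------------------------------------------------------------------
# lead field
# ---------------------------------------------------------------------------

@dataclass
class LeadField:
    """Electrode x source-coefficient matrix, V per unit dipole moment (A*m).

    Columns are average-referenced (zero mean over electrodes)."""

    matrix: np.ndarray
    electrodes: ElectrodeSet
    sources: SourceSpace
    electrode_nodes: np.ndarray          # mesh node each electrode snapped to

    def column(self, source: int, dof: int = 0) -> np.ndarray:
        return self.matrix[:, source * self.sources.dof + dof]

    def source_block(self, source: int) -> np.ndarray:
        d = self.sources.dof
        return self.matrix[:, source * d:(source + 1) * d]

    def save(self, path) -> None:
        from pathlib import Path
        import json
        path = Path(path)
        np.savetxt(path, self.matrix)
        meta = dict(
            units="V per A*m, average-referenced",
            electrode_labels=self.electrodes.labels,
            electrode_positions=self.electrodes.positions.tolist(),
            source_positions=self.sources.positions.tolist(),
            orientation_mode=self.sources.mode)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def snap_electrodes(mesh: TetMesh, electrodes: ElectrodeSet,
                    tol: float = np.inf) -> np.ndarray:
    """Snap electrodes to their nearest node on the conducting-domain hull."""
    act = mesh.labels > 0
    faces, _ = _all_faces(mesh.tets[act])
    order = _face_order(faces)
    f = faces[order]
    dup = np.zeros(len(f), dtype=bool)
    same = (f[1:] == f[:-1]).all(axis=1)
    dup[1:] |= same
    dup[:-1] |= same
    hull_nodes = np.unique(f[~dup])
    from scipy.spatial import cKDTree
    tree = cKDTree(mesh.nodes[hull_nodes])
    d, idx = tree.query(electrodes.positions)
    if (d > tol).any():
        raise ValueError("electrodes farther than snap tolerance from scalp")
    return hull_nodes[idx]


def compute_lead_field(system: StiffnessSystem, sources: SourceSpace,
                       electrodes: ElectrodeSet, mode: str = "hdiv",
                       rtol: float = 1e-8) -> LeadField:
    """Transfer-matrix lead field: one grounded CG solve per electrode."""
    mesh = system.mesh
    enodes = snap_electrodes(mesh, electrodes)
    eact = system.node_map[enodes]
    if (eact < 0).any():
        raise ValueError("electrode snapped outside the conducting domain")
    G = build_rhs(system, sources, mode=mode)
    solve = system.solver(rtol=rtol)
    n = system.A.shape[0]
    T = np.empty((len(enodes), n))
    for e, ia in enumerate(eact):
        rhs = np.zeros(n)
        rhs[ia] = 1.0
        rhs -= rhs.mean()                    # consistent (zero-sum) load
        T[e] = solve(rhs)
    L = np.asarray((G.T @ T.T).T)        # sparse @ dense, no densified G
    L -= L.mean(axis=0, keepdims=True)
    return LeadField(matrix=L, electrodes=electrodes, sources=sources,
                     electrode_nodes=enodes)


def forward_potentials(system: StiffnessSystem, sources: SourceSpace,
                       electrodes: ElectrodeSet, source_index: int,
                       moment: np.ndarray, mode: str = "hdiv",
                       rtol: float = 1e-8) -> np.ndarray:
    """Direct forward solve for one dipole (oracle path for the transfer
    matrix): assemble the rhs, solve A z = g, restrict, average-reference."""
    single = SourceSpace(
        positions=sources.positions[[source_index]],
        orientations=np.asarray(moment, dtype=float).reshape(1, 1, 3),
        host_tets=sources.host_tets[[source_index]],
        compartments=sources.compartments[[source_index]],
        mode="fixed")
    G = build_rhs(system, single, mode=mode)
    solve = system.solver(rtol=rtol)
    z = solve(G.toarray().ravel())
    enodes = snap_electrodes(system.mesh, electrodes)
    y = z[system.node_map[enodes]]
    return y - y.mean()


# ---------------------------------------------------------------------------
# error measures
# ---------------------------------------------------------------------------

def rdm_mag(J1: np.ndarray, J2: np.ndarray) -> tuple[float, float]:
    """Topography and magnitude discrepancy between two potential vectors.

    RDM = || J1/||J1|| - J2/||J2|| || in [0, 2];  MAG = 1 - ||J1|| / ||J2||.
    """
    J1 = np.asarray(J1, dtype=float)
    J2 = np.asarray(J2, dtype=float)
    n1 = np.linalg.norm(J1)
    n2 = np.linalg.norm(J2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-norm potential vector")
    rdm = float(np.linalg.norm(J1 / n1 - J2 / n2))
    mag = float(1.0 - n1 / n2)
    return rdm, mag
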