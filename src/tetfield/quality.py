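"""Mesh-quality metrics: boundary fitting distance and condition statistics.

The fitting distance of a compartment is measured from every node of its
extracted FE boundary surface to the closest point (point-to-triangle, not
point-to-vertex) of the reference segmentation surface.  Condition
statistics summarize kappa = volume / longest-edge over all elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geom import SurfaceDistance
from .meshing import TetMesh, conformity_report, extract_compartment_surface
from .postprocess import tet_condition
from .surfaces import TriSurface

__all__ = ["boundary_distance", "QualityReport", "quality_report",
           "EccentricitySweep", "eccentricity_sweep"]


def boundary_distance(mesh: TetMesh, compartment: int,
                      reference: TriSurface) -> np.ndarray:
    """Distances (mm) from extracted-boundary nodes to a reference surface."""
    surf = extract_compartment_surface(mesh, compartment)
    d, _ = SurfaceDistance(reference).query(surf.vertices)
    return d


@dataclass
class QualityReport:
    """Per-stage mesh quality summary (machine-readable)."""

    stage: str
    n_nodes: int
    n_tets: int
    condition_min: float
    condition_median: float
    frac_condition_below: float          # fraction with kappa < 0.01 mm^2
    inverted: int
    bad_faces: int
    distance_quantiles: dict = field(default_factory=dict)
    # per-compartment {name: (q25, median, q75)} in mm

    def as_dict(self) -> dict:
        return {
            "stage": self.stage, "n_nodes": self.n_nodes,
            "n_tets": self.n_tets, "condition_min": self.condition_min,
            "condition_median": self.condition_median,
            "frac_condition_below_0p01": self.frac_condition_below,
            "inverted": self.inverted, "bad_faces": self.bad_faces,
            "distance_quantiles_mm": {
                k: list(v) for k, v in self.distance_quantiles.items()},
        }


def quality_report(mesh: TetMesh, stage: str = "",
                   references: dict[str, tuple[int, TriSurface]] | None = None,
                   kappa_cut: float = 0.01) -> QualityReport:
    """Compute the stage report; ``references`` maps name -> (label, surface)."""
    kappa = tet_condition(mesh)
    conf = conformity_report(mesh)
    dq = {}
    for name, (label, ref) in (references or {}).items():
        d = boundary_distance(mesh, label, ref)
        # linear-interpolation (type 7) quantiles
        dq[name] = tuple(float(q) for q in
                         np.quantile(d, [0.25, 0.5, 0.75]))
    return QualityReport(
        stage=stage, n_nodes=mesh.n_nodes, n_tets=mesh.n_tets,
        condition_min=float(kappa.min()),
        condition_median=float(np.median(kappa)),
        frac_condition_below=float((kappa < kappa_cut).mean()),
        inverted=conf["inverted"], bad_faces=conf["bad_faces"],
        distance_quantiles=dq)


@dataclass
class EccentricitySweep:
    """Per-eccentricity-bin forward-error quantiles (RDM/MAG, fractions)."""

    bin_edges: np.ndarray
    rdm_quantiles: list       # per bin: (q25, median, q75) or None if empty
    mag_quantiles: list
    n_samples: list
    rdm_all: np.ndarray = None
    mag_all: np.ndarray = None
    ecc_all: np.ndarray = None

    def median_rdm_upto(self, ecc_max: float) -> float:
        sel = self.ecc_all <= ecc_max
        return float(np.median(self.rdm_all[sel]))

    def median_mag_upto(self, ecc_max: float) -> float:
        sel = self.ecc_all <= ecc_max
        return float(np.median(np.abs(self.mag_all[sel])))


def eccentricity_sweep(leadfield, model, bin_edges=None,
                       center: np.ndarray | None = None) -> EccentricitySweep:
    """Lead-field accuracy vs the analytic sphere across eccentricity bins.

    Every source coefficient column (unit moment along each orientation) is
    compared against the analytic oracle evaluated at the matching position
    and orientation; RDM/MAG samples are pooled per eccentricity bin of the
    innermost (brain) radius.
    """
    from .fem import rdm_mag
    from .sphere import sphere_potential
    if bin_edges is None:
        bin_edges = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 0.9, 0.95, 1.0])
    bin_edges = np.asarray(bin_edges, dtype=float)
    src = leadfield.sources
    elec = leadfield.electrodes.positions
    ecc = src.eccentricities(model.inner_radius, center)
    rdms, mags, eccs = [], [], []
    for k in range(src.n_sources):
        for d in range(src.dof):
            moment = src.orientations[k, d] * 1e-8      # 10 nAm test dipole
            ana = sphere_potential(model, src.positions[k], moment, elec)
            fem = leadfield.column(k, d) * 1e-8
            r, m = rdm_mag(fem, ana)
            rdms.append(r)
            mags.append(m)
            eccs.append(ecc[k])
    rdms = np.array(rdms)
    mags = np.array(mags)
    eccs = np.array(eccs)
    rq, mq, ns = [], [], []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        sel = (eccs >= lo) & (eccs < hi)
        ns.append(int(sel.sum()))
        if sel.any():
            rq.append(tuple(np.quantile(rdms[sel], [0.25, 0.5, 0.75])))
            mq.append(tuple(np.quantile(mags[sel], [0.25, 0.5, 0.75])))
        else:
            rq.append(None)
            mq.append(None)
    return EccentricitySweep(bin_edges=bin_edges, rdm_quantiles=rq,
                             mag_quantiles=mq, n_samples=ns,
                             rdm_all=rdms, mag_all=mags, ecc_all=eccs)
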