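"""End-to-end boundary-fitted mesh generation.

Stage order: surface downsampling -> lattice -> five-tet subdivision ->
solid-angle labeling -> boundary refinement -> recursive re-labeling ->
volumetric + surface Taubin smoothing -> inflation -> inverted-element
repair -> condition-driven flips.  Each stage appends a QualityReport.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .labeling import SolidAngleParams, label_mesh, relabel_recursive
from .meshing import (TetMesh, boundary_tet_mask, build_lattice, refine_mesh,
                      subdivide_hex_to_tets)
from .postprocess import (InflationParams, OptimizationParams, SmoothingParams,
                          delaunay_optimize, inflate_to_boundary,
                          repair_inverted, taubin_smooth)
from .quality import QualityReport, quality_report
from .surfaces import Compartment, SegmentationSpec, downsample_surface

log = logging.getLogger(__name__)

__all__ = ["MeshingConfig", "load_meshing_config", "build_fitted_mesh",
           "build_unfitted_mesh"]


@dataclass
class MeshingConfig:
    resolution: float = 3.0                     # initial lattice spacing, mm
    solid_angle: SolidAngleParams = field(default_factory=SolidAngleParams)
    smoothing_volume: SmoothingParams = field(
        default_factory=lambda: SmoothingParams(xi=0.9))
    smoothing_surface: SmoothingParams = field(
        default_factory=lambda: SmoothingParams(xi=0.1))
    inflation: InflationParams = field(default_factory=InflationParams)
    optimization: OptimizationParams = field(default_factory=OptimizationParams)
    downsample: bool = True
    refine: bool = True
    postprocess: bool = True
    track_quality: bool = True


def load_meshing_config(path) -> MeshingConfig:
    """Build a MeshingConfig from a YAML file mirroring the defaults.

    Top-level keys match MeshingConfig fields; the nested parameter groups
    (solid_angle, smoothing_volume, smoothing_surface, inflation,
    optimization) take their dataclass field names, e.g.::

        resolution: 3.0
        solid_angle: {threshold: 0.5}
        smoothing_volume: {lam: 0.4, mu: 0.4, xi: 0.9}
        inflation: {zeta: 0.05, max_passes: 10}
        optimization: {tau: 0.01}
    """
    import yaml
    from pathlib import Path
    raw = yaml.safe_load(Path(path).read_text()) or {}
    groups = dict(solid_angle=SolidAngleParams,
                  smoothing_volume=SmoothingParams,
                  smoothing_surface=SmoothingParams,
                  inflation=InflationParams,
                  optimization=OptimizationParams)
    kwargs = {}
    for key, val in raw.items():
        if key in groups:
            kwargs[key] = groups[key](**val)
        else:
            kwargs[key] = val
    return MeshingConfig(**kwargs)


def _downsampled_spec(spec: SegmentationSpec, resolution: float
                      ) -> SegmentationSpec:
    comps = []
    for c in spec.compartments:
        surf = downsample_surface(c.surface, resolution)
        comps.append(Compartment(c.name, surf, c.conductivity, c.priority,
                                 c.refine_boundary, c.active))
    return SegmentationSpec(comps, spec.bounding_box_padding)


def build_unfitted_mesh(spec: SegmentationSpec, config: MeshingConfig
                        ) -> tuple[TetMesh, SegmentationSpec]:
    """Lattice subdivision + labeling only (no refinement/fitting)."""
    work = _downsampled_spec(spec, config.resolution) if config.downsample \
        else spec
    lattice = build_lattice(work, config.resolution)
    mesh = subdivide_hex_to_tets(lattice)
    log.info("unfitted mesh: %d nodes, %d tets", mesh.n_nodes, mesh.n_tets)
    label_mesh(mesh, work, config.solid_angle)
    return mesh, work


def build_fitted_mesh(spec: SegmentationSpec,
                      config: MeshingConfig | None = None
                      ) -> tuple[TetMesh, SegmentationSpec, list[QualityReport]]:
    """Full boundary-fitted pipeline; returns (mesh, working spec, reports).

    The working spec holds the (possibly downsampled) surfaces actually used;
    quality distances are measured against them.
    """
    config = config or MeshingConfig()
    reports: list[QualityReport] = []
    mesh, work = build_unfitted_mesh(spec, config)

    refs = {c.name: (cid, c.surface)
            for cid, c in work.by_priority()} if config.track_quality else None

    def report(stage: str) -> None:
        if config.track_quality:
            reports.append(quality_report(mesh, stage, refs))
            log.info("stage %-12s tets=%d inverted=%d", stage, mesh.n_tets,
                     reports[-1].inverted)

    report("labeled")

    if config.refine:
        red = np.zeros(mesh.n_tets, dtype=bool)
        for cid, comp in work.by_priority():
            if comp.refine_boundary:
                red |= boundary_tet_mask(mesh, cid)
        if red.any():
            mesh = refine_mesh(mesh, red)
            log.info("refined mesh: %d nodes, %d tets", mesh.n_nodes,
                     mesh.n_tets)
        mesh = relabel_recursive(mesh, work, config.solid_angle)
        report("relabeled")

    if config.postprocess:
        mesh = taubin_smooth(mesh, "volume", config.smoothing_volume)
        mesh = taubin_smooth(mesh, "surface", config.smoothing_surface)
        report("smoothed")
        mesh = inflate_to_boundary(mesh, work, config.inflation)
        report("inflated")
        mesh = repair_inverted(mesh)
        mesh = delaunay_optimize(mesh, config.optimization)
        report("optimized")

    return mesh, work, reports
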