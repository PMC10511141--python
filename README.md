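# tetfield

Boundary-fitted multi-compartment tetrahedral meshing and EEG
forward/inverse modeling for human-head volume conductors.

EEG source localization needs a finite-element mesh of the head in which
every tissue compartment — scalp, skull, CSF, grey matter, subcortical
nuclei — is a closed region with its own conductivity, and in which element
faces follow the tissue boundaries to sub-millimeter accuracy.  Standard
heuristic mesh generators struggle with the thin, folded, and sometimes
mutually intersecting surfaces that anatomical segmentations produce.
`tetfield` implements a labeling-based alternative:

1. a regular hexahedral lattice is split into five tetrahedra per cube with
   parity-mirrored diagonals;
2. elements are assigned to compartments by the **solid-angle rule** — a node
   is inside a closed boundary ∂S when s = (1/4π) Σ_faces Ω ≥ T, and a tet
   belongs to the innermost compartment containing all four nodes;
3. boundary layers are refined red/green, re-labeled recursively to a fixed
   point, then **Taubin-smoothed** (forward λ, backward μ), **inflated**
   toward the segmentation (x ← x + ζ·d·ê along intersecting edges), and
   optimized by inverted-element repair plus 2-3 **Delaunay turns** on
   low-condition pairs (κ = V/ℓ_max).

On the fitted mesh the package assembles the P1 stiffness system for
∇·(σ∇u) = ∇·J_p with insulating Neumann boundary, realizes dipoles as
divergence-conforming RT0 interpolants, and computes the lead field
L = R A⁻¹ G via transfer solves (CG with incomplete-Cholesky
preconditioning).  Source reconstruction ships MNE, sLORETA, and the
dipole (deviation) scan, with earth-mover's-distance evaluation against
known dipoles and weighted Gaussian-mixture summaries with BIC model
selection.  A semi-analytic concentric multilayer-sphere solution (exact
Legendre-series transfer coefficients) is the validation oracle, with the
classical three-shell model (radii 87/92/100 mm, conductivities
0.33/0.0042/0.33 S/m) built in.

Audience: EEG/MEG methods researchers and forward-modeling developers who
need a scriptable, dependency-light meshing and lead-field pipeline that
accepts any stack of closed triangulated surfaces (STL/OFF/PLY).

## Worked example

```python
import numpy as np
from tetfield import (MeshingConfig, ary_model, assemble_stiffness,
                      boundary_distance, build_fitted_mesh,
                      build_source_space, compute_lead_field,
                      conductivity_from_spec, eccentricity_sweep,
                      make_ary_segmentation, make_electrodes)

spec = make_ary_segmentation(3)            # brain/skull/scalp icospheres
mesh, work, reports = build_fitted_mesh(spec, MeshingConfig(resolution=6.0))
d = boundary_distance(mesh, 1, work.compartments[0].surface)
print(f"{mesh.n_tets} tets, median grey-matter boundary distance "
      f"{np.median(d):.2f} mm")

system = assemble_stiffness(mesh, conductivity_from_spec(mesh, work))
sources = build_source_space(mesh, work, n_sources=60, seed=1)
lf = compute_lead_field(system, sources, make_electrodes(180, 100.0))
sweep = eccentricity_sweep(lf, ary_model())
print(f"median RDM {100 * sweep.median_rdm_upto(0.95):.2f} %, "
      f"median |MAG| {100 * sweep.median_mag_upto(0.95):.2f} %")
```

Output on one CPU (about four minutes):

```
718239 tets, median grey-matter boundary distance 1.07 mm
median RDM 6.96 %, median |MAG| 13.38 %
```

The fitting distance is about a quarter of the 6 mm lattice spacing — the
refined boundary layer halves the local cell size and the
smoothing/inflation stages pull the staircase onto the sphere.  The RDM
(topography) and MAG (amplitude) medians compare the FEM lead field against
the analytic three-shell series for the same positions and orientations;
both shrink quickly with resolution (at 5 mm the RDM median is ≈3.4 %, and
at 3 mm the fitting distance drops to ≈0.5 mm).

A thin CLI wraps the same pipeline: `tetfield mesh`, `postprocess`,
`leadfield`, `localize`, and `tetfield validate-sphere --resolution 6`.

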