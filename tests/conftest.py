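"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from tetfield import (MeshingConfig, assemble_stiffness, build_fitted_mesh,
                      build_source_space, compute_lead_field,
                      conductivity_from_spec, make_ary_segmentation,
                      make_electrodes)


@pytest.fixture(scope="session")
def ary_spec_small():
    """Three-shell sphere segmentation at coarse surface resolution."""
    return make_ary_segmentation(2)


@pytest.fixture(scope="session")
def fitted_small(ary_spec_small):
    """Boundary-fitted 10 mm sphere mesh (desk-scale structural fixture)."""
    mesh, work, reports = build_fitted_mesh(
        ary_spec_small, MeshingConfig(resolution=10.0))
    return mesh, work, reports


@pytest.fixture(scope="session")
def leadfield_small(fitted_small):
    """Lead field on the coarse sphere: 48 electrodes, 50 free sources."""
    mesh, work, _ = fitted_small
    system = assemble_stiffness(mesh, conductivity_from_spec(mesh, work))
    src = build_source_space(mesh, work, n_sources=50, seed=7)
    lf = compute_lead_field(system, src, make_electrodes(48, 100.0))
    return lf, system


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def ray_cast_inside(points: np.ndarray, surface, seed: int = 0) -> np.ndarray:
    """Crossing-parity point-in-surface test (independent of solid angles).

    Casts a ray per point along a random direction and counts triangle
    crossings; re-casts with a fresh direction on numerically marginal hits.
    """
    rng = np.random.default_rng(seed)
    tri = surface.vertices[surface.faces]
    out = np.zeros(len(points), dtype=bool)
    todo = np.arange(len(points))
    for _attempt in range(25):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        retry = []
        for i in todo:
            n_hits, marginal = _count_crossings(points[i], d, tri)
            if marginal:
                retry.append(i)
            else:
                out[i] = n_hits % 2 == 1
        if not retry:
            return out
        todo = np.array(retry)
    raise RuntimeError("ray casting failed to resolve marginal hits")


def _count_crossings(origin, direction, tri, eps=1e-9):
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    p = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > 1e-14
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    t0 = origin - tri[:, 0]
    u = np.einsum("ij,ij->i", t0, p) * inv
    q = np.cross(t0, e1)
    v = direction @ q.T * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    hit = ok & (u > eps) & (v > eps) & (u + v < 1 - eps) & (t > eps)
    # marginal if any crossing parameter is too close to a face edge/origin
    near = ok & ((np.abs(u) < eps) | (np.abs(v) < eps)
                 | (np.abs(u + v - 1) < eps) | (np.abs(t) < eps))
    return int(hit.sum()), bool(near.any())
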