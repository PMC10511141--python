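"""Lattice subdivision, red/green refinement, surface extraction."""

import numpy as np
import pytest

from tetfield import (Compartment, HexLattice, SegmentationSpec, TetMesh,
                      build_lattice, conformity_report,
                      extract_compartment_surface, icosphere_surface,
                      refine_mesh, refine_volume, subdivide_hex_to_tets,
                      tet_volumes)
from tetfield.meshing import _all_faces


def _single_sphere_spec(radius=50.0, sub=2):
    return SegmentationSpec([Compartment("ball", icosphere_surface(sub, radius),
                                         0.33, 1)], bounding_box_padding=3.0)


# ---------------------------------------------------------------------------
# lattice
# ---------------------------------------------------------------------------

def test_lattice_covers_padded_bounding_box():
    spec = _single_sphere_spec(radius=100.0)
    lat = build_lattice(spec, spacing=3.0)
    assert (lat.counts >= np.ceil(206 / 3.0)).all()
    lo = lat.origin
    hi = lat.upper()
    for c in spec.compartments:
        v = c.surface.vertices
        assert (v > lo + 1e-9).all() and (v < hi - 1e-9).all()


def test_lattice_halving_spacing_grows_counts():
    spec = _single_sphere_spec()
    c3 = build_lattice(spec, 3.0).counts
    c2 = build_lattice(spec, 2.0).counts
    assert (c2 / c3 > 1.3).all()


# ---------------------------------------------------------------------------
# five-tet subdivision
# ---------------------------------------------------------------------------

def test_single_hexahedron_five_tet_volumes():
    h = 2.0
    lat = HexLattice(origin=np.zeros(3), spacing=h, counts=np.ones(3, int))
    mesh = subdivide_hex_to_tets(lat)
    v = np.sort(mesh.volumes())
    assert len(v) == 5
    # four corner tets of h^3/6 and one central of h^3/3
    assert v[:4] == pytest.approx(np.full(4, h ** 3 / 6))
    assert v[4] == pytest.approx(h ** 3 / 3)
    assert v.sum() == pytest.approx(h ** 3)


def test_lattice_tiling_volume_and_count():
    lat = HexLattice(origin=np.zeros(3), spacing=1.0,
                     counts=np.array([10, 10, 10]))
    mesh = subdivide_hex_to_tets(lat)
    assert mesh.n_tets == 5000
    assert mesh.volumes().sum() == pytest.approx(1000.0)


def test_adjacent_cubes_conform_and_alternate():
    lat = HexLattice(origin=np.zeros(3), spacing=1.0,
                     counts=np.array([2, 2, 2]))
    mesh = subdivide_hex_to_tets(lat)
    rep = conformity_report(mesh)
    assert rep["bad_faces"] == 0
    # interior faces shared by exactly two tets everywhere; with 8 cubes the
    # parity-mirrored splits must agree on every inter-cube face, i.e. no
    # face occurs an odd number of times in the interior
    faces, _ = _all_faces(mesh.tets)
    _, counts = np.unique(faces, axis=0, return_counts=True)
    assert set(counts.tolist()) <= {1, 2}
    assert rep["inverted"] == 0


def test_mirrored_parity_produces_matching_diagonals():
    # the diagonal on the shared face between cube (0,0,0) and (1,0,0) must
    # be used by both cubes (conformity already implies it; check explicitly)
    lat = HexLattice(origin=np.zeros(3), spacing=1.0,
                     counts=np.array([2, 1, 1]))
    mesh = subdivide_hex_to_tets(lat)
    plane = np.isclose(mesh.nodes[:, 0], 1.0)
    faces, _ = _all_faces(mesh.tets)
    on_plane = plane[faces].all(axis=1)
    f = faces[on_plane]
    uniq, counts = np.unique(f, axis=0, return_counts=True)
    # each triangle of the shared face appears once from each side
    assert (counts == 2).all()
    assert len(uniq) == 2


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def test_red_refinement_of_single_tet():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([5]))
    out = refine_mesh(mesh, np.array([True]))
    v = out.volumes()
    assert out.n_tets == 8
    assert v.sum() == pytest.approx(1 / 6)
    assert (out.labels == 5).all()
    # the four corner children have exactly 1/8 the parent volume
    assert np.sort(v)[:4] == pytest.approx(np.full(4, 1 / 48), rel=1e-12)


def test_refine_volume_empty_region_is_identity():
    lat = HexLattice(origin=np.zeros(3), spacing=1.0,
                     counts=np.array([2, 2, 2]))
    mesh = subdivide_hex_to_tets(lat)
    out = refine_volume(mesh, region=set())
    assert out is mesh


def test_green_closure_counts_and_conformity():
    # refine one tet of a 2-cube lattice; neighbours must be closed with
    # 2-, 3- or 4-child templates and the mesh stays conforming
    lat = HexLattice(origin=np.zeros(3), spacing=1.0,
                     counts=np.array([2, 1, 1]))
    mesh = subdivide_hex_to_tets(lat)
    red = np.zeros(mesh.n_tets, bool)
    red[0] = True
    out = refine_mesh(mesh, red)
    assert conformity_report(out)["bad_faces"] == 0
    assert out.volumes().sum() == pytest.approx(2.0)
    _assert_no_hanging_nodes(out)


def test_transition_tet_with_three_split_edges_gets_four_children():
    # two tets sharing a face; red-refining one splits exactly the three
    # edges of the shared face in the other -> 4 green children
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                      [1, 1, 1]], float)
    tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
    mesh = TetMesh(nodes, tets, np.array([1, 2]))
    out = refine_mesh(mesh, np.array([True, False]))
    assert out.n_tets == 8 + 4
    assert (np.sort(out.labels) == np.r_[np.ones(8), np.full(4, 2)]).all()
    assert out.volumes().sum() == pytest.approx(
        tet_volumes(mesh.nodes, mesh.tets).sum())
    _assert_no_hanging_nodes(out)


def test_refinement_conserves_compartment_volume(fitted_small):
    # labels inherit and per-label volume is conserved by pure refinement
    mesh, _, _ = fitted_small
    sub = TetMesh(mesh.nodes.copy(), mesh.tets.copy(), mesh.labels.copy())
    vol_before = {l: tet_volumes(sub.nodes, sub.tets[sub.labels == l]).sum()
                  for l in np.unique(sub.labels)}
    red = np.zeros(sub.n_tets, bool)
    red[sub.labels == 1] = True
    out = refine_mesh(sub, red)
    for l, v in vol_before.items():
        v2 = tet_volumes(out.nodes, out.tets[out.labels == l]).sum()
        assert v2 == pytest.approx(v, rel=1e-12)
    _assert_no_hanging_nodes(out)


def _assert_no_hanging_nodes(mesh: TetMesh) -> None:
    """Every face occurring once must lie on the hull (no interior orphans).

    A hanging node would leave a split face single-counted in the interior.
    """
    faces, _ = _all_faces(mesh.tets)
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    assert (counts <= 2).all()
    singles = uniq[counts == 1]
    # single faces must sit on the hull: all their nodes on the bounding box
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    pts = mesh.nodes[singles]
    on_box = (np.isclose(pts, lo[None, None, :]) |
              np.isclose(pts, hi[None, None, :])).any(axis=2)
    assert on_box.all(axis=1).all()


# ---------------------------------------------------------------------------
# surface extraction
# ---------------------------------------------------------------------------

def test_extract_single_tet_surface():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([1]))
    surf = extract_compartment_surface(mesh, 1)
    assert surf.n_faces == 4
    assert surf.signed_volume() == pytest.approx(1 / 6)


def test_extract_two_tets_shared_face_removed():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                      [1, 1, 1]], float)
    mesh = TetMesh(nodes, np.array([[0, 1, 2, 3], [1, 2, 3, 4]]),
                   np.array([1, 1]))
    surf = extract_compartment_surface(mesh, 1)
    assert surf.n_faces == 6


def test_extract_missing_label_raises():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([1]))
    with pytest.raises(ValueError):
        extract_compartment_surface(mesh, 9)


def test_extracted_ball_volume_matches_summed_tets(fitted_small):
    mesh, _, _ = fitted_small
    surf = extract_compartment_surface(mesh, 1)
    # closed (every edge bounds an even number of faces; pinched edges where
    # two labeled tets meet diagonally are allowed) and outward-oriented:
    # the divergence-theorem volume equals the summed tet volumes
    e = np.vstack([surf.faces[:, [0, 1]], surf.faces[:, [1, 2]],
                   surf.faces[:, [2, 0]]])
    e.sort(axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    assert (counts % 2 == 0).all()
    vol_tets = tet_volumes(mesh.nodes, mesh.tets[mesh.labels == 1]).sum()
    assert surf.signed_volume() == pytest.approx(vol_tets, rel=1e-10)


# ---------------------------------------------------------------------------
# I/O round trip
# ---------------------------------------------------------------------------

def test_vtk_roundtrip(tmp_path):
    lat = HexLattice(origin=np.zeros(3), spacing=1.0,
                     counts=np.array([2, 2, 2]))
    mesh = subdivide_hex_to_tets(lat)
    mesh.labels[:5] = 3
    path = tmp_path / "m.vtk"
    mesh.save_vtk(path)
    back = TetMesh.load_vtk(path)
    assert np.allclose(back.nodes, mesh.nodes)
    assert (back.tets == mesh.tets).all()
    assert (back.labels == mesh.labels).all()
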