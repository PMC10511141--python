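"""Triangulated segmentation surfaces and the segmentation specification.

A head segmentation is an ordered stack of closed, oriented triangle surfaces
(scalp outermost, then skull, CSF, grey matter, ... innermost structures), each
carrying an isotropic conductivity.  All geometry is in millimeters.  Surfaces
must be closed 2-manifolds with outward-facing normals: both the solid-angle
point classification and the inflation stage depend on that orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "TriSurface",
    "Compartment",
    "SegmentationSpec",
    "ElectrodeSet",
    "SurfaceValidationError",
    "read_surface",
    "write_surface",
    "surface_point_density",
    "downsample_surface",
    "decimate_surface",
]


class SurfaceValidationError(ValueError):
    """Raised when a surface fails the closed-manifold / orientation checks."""

    def __init__(self, message: str, bad_edges: np.ndarray | None = None):
        super().__init__(message)
        self.bad_edges = bad_edges


@dataclass
class TriSurface:
    """A closed, consistently wound triangle surface.

    vertices : (n, 3) float array, mm
    faces    : (m, 3) int array of vertex indices; outward winding convention
               (counter-clockwise seen from outside, signed volume > 0)
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")

    # -- basic queries -----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges_unique(self) -> np.ndarray:
        """Unique undirected edges as a sorted (e, 2) index array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges_unique()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]],
                              axis=1)

    def median_edge_length(self) -> float:
        return float(np.median(self.edge_lengths()))

    def signed_volume(self) -> float:
        """Enclosed volume by the divergence theorem; > 0 for outward winding."""
        v = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", v[:, 0],
                               np.cross(v[:, 1], v[:, 2])).sum() / 6.0)

    def face_areas(self) -> np.ndarray:
        v = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges_unique()) + self.n_faces

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    def copy(self) -> "TriSurface":
        return TriSurface(self.vertices.copy(), self.faces.copy())

    # -- validation --------------------------------------------------------

    def boundary_edges(self) -> np.ndarray:
        """Edges not shared by exactly two faces (empty for a closed manifold)."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts != 2]

    def validate(self, area_tol: float = 1e-12, reorient: bool = True
                 ) -> "TriSurface":
        """Check closed-manifold invariants; reorient inward-wound input.

        Returns self (possibly with flipped winding).  Raises
        SurfaceValidationError on open/non-manifold surfaces or degenerate
        faces.
        """
        bad = self.boundary_edges()
        if len(bad):
            raise SurfaceValidationError(
                f"surface is not a closed 2-manifold: {len(bad)} edges with "
                f"face count != 2 (first few: {bad[:8].tolist()})",
                bad_edges=bad)
        areas = self.face_areas()
        if (areas <= area_tol).any():
            idx = np.nonzero(areas <= area_tol)[0]
            raise SurfaceValidationError(
                f"{len(idx)} degenerate (zero-area) faces, e.g. {idx[:8].tolist()}")
        # winding consistency: every directed edge appears exactly once
        de = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                        self.faces[:, [2, 0]]])
        _, counts = np.unique(de, axis=0, return_counts=True)
        if (counts != 1).any():
            raise SurfaceValidationError(
                "inconsistent face winding (repeated directed edge)")
        if self.signed_volume() < 0:
            if not reorient:
                raise SurfaceValidationError("surface is wound inward")
            log.info("reorienting inward-wound surface to outward convention")
            self.faces = self.faces[:, [0, 2, 1]].copy()
        return self


@dataclass
class Compartment:
    """One tissue compartment: a closed boundary surface plus physics flags."""

    name: str
    surface: TriSurface
    conductivity: float          # S/m
    priority: int                # innermost = highest (labeled first)
    refine_boundary: bool = False
    active: bool = False         # may contain sources


@dataclass
class SegmentationSpec:
    """Ordered (innermost -> outermost) compartment stack driving meshing."""

    compartments: list[Compartment]
    bounding_box_padding: float = 3.0  # mm

    def __post_init__(self) -> None:
        prios = [c.priority for c in self.compartments]
        if len(set(prios)) != len(prios):
            raise ValueError("compartment priorities must be unique")
        if any(c.conductivity <= 0 for c in self.compartments):
            raise ValueError("conductivities must be > 0")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compartments]

    def by_priority(self) -> list[tuple[int, Compartment]]:
        """(compartment id, compartment) pairs, highest priority first.

        Compartment ids are 1-based positions in the stored order; label 0 is
        reserved for the temporary bounding box acting as the outermost
        compartment.
        """
        order = sorted(range(len(self.compartments)),
                       key=lambda i: -self.compartments[i].priority)
        return [(i + 1, self.compartments[i]) for i in order]

    def outermost(self) -> Compartment:
        return min(self.compartments, key=lambda c: c.priority)

    def conductivity_of(self, label: int) -> float:
        return self.compartments[label - 1].conductivity

    # -- (de)serialization --------------------------------------------------

    def save(self, path: str | Path, surface_format: str = "ply") -> None:
        """Write a YAML config plus one surface file per compartment."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        entries = []
        for c in self.compartments:
            fname = f"{path.stem}_{c.name}.{surface_format}"
            write_surface(c.surface, path.parent / fname)
            entries.append(dict(name=c.name, surface=fname,
                                conductivity=float(c.conductivity),
                                priority=int(c.priority),
                                refine_boundary=bool(c.refine_boundary),
                                active=bool(c.active)))
        cfg = dict(bounding_box_padding=float(self.bounding_box_padding),
                   compartments=entries)
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationSpec":
        path = Path(path)
        cfg = yaml.safe_load(path.read_text())
        comps = [Compartment(name=e["name"],
                             surface=read_surface(path.parent / e["surface"]),
                             conductivity=float(e["conductivity"]),
                             priority=int(e["priority"]),
                             refine_boundary=bool(e.get("refine_boundary", False)),
                             active=bool(e.get("active", False)))
                 for e in cfg["compartments"]]
        return cls(comps, bounding_box_padding=float(
            cfg.get("bounding_box_padding", 3.0)))


@dataclass
class ElectrodeSet:
    """Point electrodes on (or near) the outermost surface."""

    positions: np.ndarray            # (k, 3) mm
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if not self.labels:
            self.labels = [f"E{i + 1}" for i in range(len(self.positions))]

    def __len__(self) -> int:
        return len(self.positions)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p, lab in zip(self.positions, self.labels):
                fh.write(f"{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},{lab}\n")

    @classmethod
    def load(cls, path: str | Path) -> "ElectrodeSet":
        pos, labels = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            pos.append([float(parts[0]), float(parts[1]), float(parts[2])])
            labels.append(parts[3] if len(parts) > 3 else f"E{len(pos)}")
        return cls(np.array(pos), labels)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_KNOWN_FORMATS = {"stl", "off", "ply"}


def read_surface(path: str | Path, fmt: str | None = None) -> TriSurface:
    """Load and validate a triangle surface (STL, OFF or PLY).

    Inward-wound inputs are reoriented to the outward convention (logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _KNOWN_FORMATS:
        raise ValueError(f"unknown surface format {fmt!r}; expected one of "
                         f"{sorted(_KNOWN_FORMATS)}")
    mesh = trimesh.load(str(path), file_type=fmt, process=False)
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if len(geoms) != 1:
            raise SurfaceValidationError("file contains multiple geometries")
        mesh = geoms[0]
    verts = np.asarray(mesh.vertices, dtype=np.float64)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if fmt == "stl":
        # STL stores duplicated per-facet vertices; weld exact duplicates.
        verts, inv = np.unique(verts.round(12), axis=0, return_inverse=True)
        faces = inv[faces]
    return TriSurface(verts, faces).validate()


def write_surface(surface: TriSurface, path: str | Path,
                  fmt: str | None = None) -> None:
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _KNOWN_FORMATS:
        raise ValueError(f"unknown surface format {fmt!r}")
    surface.as_trimesh().export(str(path), file_type=fmt)


# ---------------------------------------------------------------------------
# resolution and downsampling
# ---------------------------------------------------------------------------

def surface_point_density(surface: TriSurface) -> float:
    """Surface resolution estimate: inverse median edge length (points / mm)."""
    return 1.0 / surface.median_edge_length()


def downsample_surface(surface: TriSurface, target_resolution: float,
                       volume_tol: float = 0.02) -> TriSurface:
    """Coarsen a surface so its median edge approaches the FE mesh resolution.

    If the surface is already at or below the requested point density
    (median edge >= target), the input is returned unchanged.  Decimation is
    shortest-edge collapse with manifoldness and normal-flip guards; if the
    enclosed volume drifts by more than ``volume_tol`` (relative) the last safe
    state is returned.
    """
    if target_resolution <= 0:
        raise ValueError("target_resolution must be > 0")
    if surface.median_edge_length() >= target_resolution:
        return surface
    out = decimate_surface(surface, target_edge=target_resolution,
                           volume_tol=volume_tol)
    out.validate()
    med = out.median_edge_length()
    if not (0.5 * target_resolution <= med <= 1.5 * target_resolution):
        log.warning("downsampled median edge %.3f mm outside [0.5, 1.5] x "
                    "target %.3f mm", med, target_resolution)
    return out


def decimate_surface(surface: TriSurface, target_edge: float | None = None,
                     target_faces: int | None = None,
                     volume_tol: float = 0.05) -> TriSurface:
    """Greedy shortest-edge-collapse decimation preserving closedness.

    Stops when the median edge length reaches ``target_edge`` (or the face
    count falls to ``target_faces``), when no legal collapse remains, or when
    the enclosed volume would drift beyond ``volume_tol`` relative to input.
    """
    if target_edge is None and target_faces is None:
        raise ValueError("need target_edge or target_faces")
    verts = surface.vertices.copy()
    vol0 = abs(surface.signed_volume())

    # adjacency as python sets; surface sizes here are modest (< ~100k faces)
    faces = {i: tuple(f) for i, f in enumerate(surface.faces)}
    v_faces: dict[int, set[int]] = {}
    for fi, f in faces.items():
        for v in f:
            v_faces.setdefault(int(v), set()).add(fi)

    def neighbors(v: int) -> set[int]:
        out = set()
        for fi in v_faces[v]:
            out.update(faces[fi])
        out.discard(v)
        return out

    def face_normal(f: tuple) -> np.ndarray:
        a, b, c = verts[f[0]], verts[f[1]], verts[f[2]]
        return np.cross(b - a, c - a)

    import heapq
    heap: list[tuple[float, int, int]] = []
    for a, b in surface.edges_unique():
        d = float(np.linalg.norm(verts[a] - verts[b]))
        heapq.heappush(heap, (d, int(a), int(b)))

    alive = set(range(len(verts)))
    removed_volume = 0.0
    next_face_id = len(faces)

    def median_edge() -> float:
        es = set()
        for f in faces.values():
            es.add((min(f[0], f[1]), max(f[0], f[1])))
            es.add((min(f[1], f[2]), max(f[1], f[2])))
            es.add((min(f[2], f[0]), max(f[2], f[0])))
        arr = np.array(list(es))
        return float(np.median(np.linalg.norm(verts[arr[:, 0]] -
                                              verts[arr[:, 1]], axis=1)))

    check_every = max(64, len(faces) // 50)
    ops = 0
    while heap:
        if target_faces is not None and len(faces) <= target_faces:
            break
        if target_edge is not None and ops and ops % check_every == 0:
            if median_edge() >= target_edge:
                break
        d, a, b = heapq.heappop(heap)
        if a not in alive or b not in alive:
            continue
        if b not in neighbors(a):
            continue
        if np.linalg.norm(verts[a] - verts[b]) > d * 1.0 + 1e-12:
            # stale entry: re-push with the current length
            heapq.heappush(heap, (float(np.linalg.norm(verts[a] - verts[b])),
                                  a, b))
            continue
        shared = v_faces[a] & v_faces[b]
        if len(shared) != 2:
            continue
        # link condition: vertex links of a and b intersect in exactly the two
        # opposite vertices of the shared faces
        opp = set()
        for fi in shared:
            opp.update(v for v in faces[fi] if v not in (a, b))
        if neighbors(a) & neighbors(b) != opp:
            continue
        mid = 0.5 * (verts[a] + verts[b])
        # normal-flip guard on the surviving faces around a and b
        affected = (v_faces[a] | v_faces[b]) - shared
        old_a, old_b = verts[a].copy(), verts[b].copy()
        flipped = False
        pre_normals = {fi: face_normal(faces[fi]) for fi in affected}
        verts[a] = mid
        verts[b] = mid
        for fi in affected:
            n_new = face_normal(tuple(a if v == b else v for v in faces[fi]))
            if np.dot(pre_normals[fi], n_new) <= 1e-14:
                flipped = True
                break
        if flipped:
            verts[a], verts[b] = old_a, old_b
            continue
        # volume drift bookkeeping (local signed volume change)
        dv = 0.0
        for fi in v_faces[a] | v_faces[b]:
            f = faces[fi]
            dv -= np.dot(verts[f[0]], np.cross(verts[f[1]], verts[f[2]])) / 6.0
        verts[a], verts[b] = old_a, old_b
        for fi in v_faces[a] | v_faces[b]:
            f = faces[fi]
            dv += np.dot(verts[f[0]], np.cross(verts[f[1]], verts[f[2]])) / 6.0
        if abs(removed_volume - dv) > volume_tol * vol0:
            continue
        removed_volume -= dv

        # commit: collapse b into a at the midpoint
        verts[a] = mid
        alive.discard(b)
        for fi in shared:
            for v in faces[fi]:
                v_faces[v].discard(fi)
            del faces[fi]
        for fi in list(v_faces[b]):
            f = faces[fi]
            faces[fi] = tuple(a if v == b else v for v in f)
            v_faces[a].add(fi)
            v_faces[b].discard(fi)
        for nb in neighbors(a):
            heapq.heappush(heap, (float(np.linalg.norm(verts[a] - verts[nb])),
                                  a, int(nb)))
        ops += 1

    # compact
    used = sorted({v for f in faces.values() for v in f})
    remap = {v: i for i, v in enumerate(used)}
    new_faces = np.array([[remap[v] for v in f] for f in faces.values()],
                         dtype=np.int64)
    out = TriSurface(verts[used], new_faces)
    if out.signed_volume() < 0:
        out.faces = out.faces[:, [0, 2, 1]].copy()
    return out
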