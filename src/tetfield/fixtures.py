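"""Deterministic synthetic inputs: sphere segmentations, electrodes, data.

Everything the pipeline needs can be generated here with no downloads: the
classical three-shell sphere head model (brain / skull / scalp at radii
87 / 92 / 100 mm with conductivities 0.33 / 0.0042 / 0.33 S/m -- note the
~1:79 skull contrast that makes the forward problem hard), evenly spread
scalp electrodes, noisy synthetic measurement vectors, and a folded-blob
stress surface emulating thin invaginated tissue layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .surfaces import Compartment, ElectrodeSet, SegmentationSpec, TriSurface

__all__ = ["ARY_RADII", "ARY_CONDUCTIVITIES", "FixtureConfig",
           "make_ary_segmentation", "make_electrodes",
           "simulate_measurements", "make_folded_blob", "icosphere_surface"]

ARY_RADII = (87.0, 92.0, 100.0)                 # mm, innermost -> outermost
ARY_CONDUCTIVITIES = (0.33, 0.0042, 0.33)       # S/m


@dataclass
class FixtureConfig:
    """Bundle of the knobs the synthetic study conditions depend on."""

    sphere_subdivisions: int = 3
    n_electrodes: int = 180
    noise_db: float = -30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_electrodes < 4:
            raise ValueError("need at least 4 electrodes")


def icosphere_surface(subdivisions: int, radius: float) -> TriSurface:
    """Icosphere as a validated TriSurface (avoids UV-pole clustering)."""
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriSurface(np.array(m.vertices), np.array(m.faces)).validate()


def make_ary_segmentation(subdivisions: int = 3,
                          refine: bool = True) -> SegmentationSpec:
    """Three nested icosphere shells: brain (active), skull, scalp.

    Priorities are innermost-first; all three boundaries are flagged for
    refinement (the active-compartment boundary for source admissibility,
    skull and scalp against conductivity-leakage through thin shells).
    """
    if subdivisions < 2:
        raise ValueError("subdivisions must be >= 2")
    names = ("brain", "skull", "scalp")
    comps = []
    for i, (name, r, sigma) in enumerate(
            zip(names, ARY_RADII, ARY_CONDUCTIVITIES)):
        comps.append(Compartment(
            name=name,
            surface=icosphere_surface(subdivisions, r),
            conductivity=sigma,
            priority=3 - i,                     # innermost = highest
            refine_boundary=refine,
            active=(name == "brain")))
    return SegmentationSpec(comps, bounding_box_padding=3.0)


def make_electrodes(n: int = 180, radius: float = 100.0) -> ElectrodeSet:
    """Fibonacci-lattice electrodes: n points evenly spread on a sphere."""
    if n < 4:
        raise ValueError("need at least 4 electrodes")
    i = np.arange(n)
    golden = (1 + 5 ** 0.5) / 2
    z = 1 - (2 * i + 1) / n
    phi = 2 * np.pi * i / golden
    s = np.sqrt(np.maximum(0.0, 1 - z * z))
    pos = radius * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    return ElectrodeSet(pos)


def simulate_measurements(forward, dipole_position: np.ndarray,
                          dipole_moment: np.ndarray,
                          noise_db: float = -30.0,
                          seed: int = 0) -> np.ndarray:
    """Clean potentials plus i.i.d. Gaussian noise.

    ``forward`` is any callable (position, moment) -> electrode potentials,
    e.g. an analytic sphere oracle or a lead-field interpolator.  The noise
    standard deviation is 10^(noise_db/20) of the maximum absolute clean
    amplitude: -30 dB corresponds to the 3% level used throughout;
    noise_db = -inf returns the clean potentials.
    """
    clean = np.asarray(forward(np.asarray(dipole_position, dtype=float),
                               np.asarray(dipole_moment, dtype=float)))
    if np.isneginf(noise_db):
        return clean
    sigma = 10.0 ** (noise_db / 20.0) * np.abs(clean).max()
    rng = np.random.default_rng(seed)
    return clean + rng.normal(0.0, sigma, size=clean.shape)


def make_folded_blob(seed: int = 0, base_radius: float = 60.0,
                     subdivisions: int = 4) -> TriSurface:
    """Star-convex surface with spherical-harmonic folds (stress fixture).

    Radial perturbations with random low-order spherical-harmonic content
    create thin invaginations while keeping the surface a closed 2-manifold
    (radius stays strictly positive).
    """
    rng = np.random.default_rng(seed)
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.array(base.vertices)
    theta = np.arccos(np.clip(v[:, 2], -1, 1))
    phi = np.arctan2(v[:, 1], v[:, 0])
    from scipy.special import sph_harm_y
    r = np.ones(len(v))
    for ell in range(2, 7):
        for m in range(-ell, ell + 1):
            amp = rng.normal(0, 0.12 / ell)
            r += amp * np.real(sph_harm_y(ell, abs(m), theta, m * phi))
    r = np.clip(r, 0.3, None)
    surf = TriSurface(base_radius * r[:, None] * v, np.array(base.faces))
    return surf.validate()
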