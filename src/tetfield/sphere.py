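"""Semi-analytic EEG potentials for concentric multilayer spheres.

For a current dipole inside the innermost layer of M concentric spherical
shells (isotropic conductivities, insulating exterior), the potential is a
Legendre series.  Working in a frame with the dipole on the +z axis at
radius b and the moment split into a radial component q_r and a tangential
component q_t (along +x), the free-space dipole field expands as

    u_inf(r, theta, phi) = (1 / 4 pi sigma_1) * sum_n  b^(n-1) r^-(n+1)
                           [ n q_r P_n(cos theta) + q_t P_n^1(cos theta) cos phi ]

and each shell adds homogeneous solutions A_j r^n + B_j r^-(n+1).  Per
degree n the radial coefficients solve a small linear system from potential
and current continuity at the interfaces and the outer Neumann condition.
This direct transfer-coefficient solution is exact to series truncation; the
classical three-dipole (Berg) approximation is not needed as an oracle.

The homogeneous special case collapses to a generating-function closed form
used as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SphereModel", "ary_model", "sphere_potential",
           "homogeneous_sphere_potential"]


@dataclass
class SphereModel:
    """Concentric shells: radii strictly increasing (mm), conductivities S/m."""

    radii: tuple[float, ...]
    conductivities: tuple[float, ...]
    n_terms: int = 200

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        s = np.asarray(self.conductivities, dtype=float)
        if len(r) != len(s):
            raise ValueError("radii and conductivities must pair up")
        if (np.diff(r) <= 0).any() or (r <= 0).any():
            raise ValueError("radii must be positive and strictly increasing")
        if (s <= 0).any():
            raise ValueError("conductivities must be > 0")
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")

    @property
    def outer_radius(self) -> float:
        return float(self.radii[-1])

    @property
    def inner_radius(self) -> float:
        return float(self.radii[0])


def ary_model(n_terms: int = 200) -> SphereModel:
    """Three-shell sphere: 87/92/100 mm, 0.33/0.0042/0.33 S/m."""
    return SphereModel(radii=(87.0, 92.0, 100.0),
                       conductivities=(0.33, 0.0042, 0.33), n_terms=n_terms)


def _radial_transfer(model: SphereModel, n_max: int) -> np.ndarray:
    """Per-degree coefficients (A_M, B_M) of the outermost shell response to a
    unit source coefficient (the dipole's r^-(n+1) term in layer 1).

    Unknowns per degree n: alpha_1 (layer-1 homogeneous r^n term) and
    (A_j, B_j) for layers j = 2..M.  Equations: continuity of u and of
    sigma du/dr at the M-1 interfaces, plus du/dr = 0 at the outer radius.
    Returns (n_max, 2) array of (A_M, B_M); the source coefficient is
    normalized to 1 so the caller scales by beta_n.
    """
    radii = np.asarray(model.radii, dtype=float)
    sig = np.asarray(model.conductivities, dtype=float)
    M = len(radii)
    # scale radii to O(1) for conditioning
    R = radii / radii[-1]
    out = np.empty((n_max, 2))
    for n in range(1, n_max + 1):
        m = 2 * M - 1
        A = np.zeros((m, m))
        rhs = np.zeros(m)
        # unknown order: [alpha_1, A_2, B_2, ..., A_M, B_M]
        def col_A(j):  # layer j >= 2
            return 1 + 2 * (j - 2)

        def col_B(j):
            return 2 + 2 * (j - 2)

        row = 0
        for j in range(1, M):          # interface between layer j and j+1
            r = R[j - 1]
            rn = r ** n
            rmn = r ** (-(n + 1))
            # potential continuity: u_j(r) = u_{j+1}(r)
            if j == 1:
                A[row, 0] = rn
                rhs[row] = -rmn       # source term beta * r^-(n+1), beta = 1
            else:
                A[row, col_A(j)] = rn
                A[row, col_B(j)] = rmn
            A[row, col_A(j + 1)] -= rn
            A[row, col_B(j + 1)] -= rmn
            row += 1
            # current continuity: sigma_j u_j'(r) = sigma_{j+1} u_{j+1}'(r)
            dn = n * r ** (n - 1)
            dmn = -(n + 1) * r ** (-(n + 2))
            if j == 1:
                A[row, 0] = sig[0] * dn
                rhs[row] = -sig[0] * dmn
            else:
                A[row, col_A(j)] = sig[j - 1] * dn
                A[row, col_B(j)] = sig[j - 1] * dmn
            A[row, col_A(j + 1)] -= sig[j] * dn
            A[row, col_B(j + 1)] -= sig[j] * dmn
            row += 1
        # outer Neumann at R[-1] = 1
        if M == 1:
            A[row, 0] = n
            rhs[row] = n + 1
        else:
            A[row, col_A(M)] = n
            A[row, col_B(M)] = -(n + 1)
            row += 1
        x = np.linalg.solve(A, rhs)
        if M == 1:
            out[n - 1] = (x[0], 1.0)
        else:
            out[n - 1] = (x[col_A(M)], x[col_B(M)])
    # coefficients are in outer-radius-scaled coordinates (rho = r / R_out);
    # callers must evaluate the series in the same scaled space
    return out


def _legendre_pair(n_max: int, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and P_n^1(x) for n = 1..n_max via upward recurrences.

    P_n^1 uses the convention without the Condon-Shortley phase:
    P_n^1 = sin(theta) * dP_n/dx.
    """
    x = np.asarray(x, dtype=float)
    s = np.sqrt(np.maximum(0.0, 1.0 - x * x))
    P = np.empty((n_max + 1,) + x.shape)
    dP = np.empty_like(P)
    P[0] = 1.0
    dP[0] = 0.0
    if n_max >= 1:
        P[1] = x
        dP[1] = 1.0
    for n in range(2, n_max + 1):
        P[n] = ((2 * n - 1) * x * P[n - 1] - (n - 1) * P[n - 2]) / n
        dP[n] = dP[n - 2] + (2 * n - 1) * P[n - 1]
    return P[1:], (s[None, :] * dP[1:])


def sphere_potential(model: SphereModel, dipole_position: np.ndarray,
                     dipole_moment: np.ndarray,
                     electrode_positions: np.ndarray,
                     tail_tol: float = 1e-10) -> np.ndarray:
    """Average-referenced potentials (V) at electrodes on the outer surface.

    dipole_position (mm) must lie strictly inside the innermost radius;
    dipole_moment is in A*m (geometry in mm, conductivity in S/m: a
    consistent scaling with potentials in volts requires moment in
    A*mm and lengths in mm, so the moment is converted internally).
    Raises if the Legendre series has not converged at the configured order.
    """
    pos = np.asarray(dipole_position, dtype=float)
    mom = np.asarray(dipole_moment, dtype=float) * 1e3   # A*m -> A*mm
    elec = np.atleast_2d(np.asarray(electrode_positions, dtype=float))
    b = float(np.linalg.norm(pos))
    r0 = model.inner_radius
    if b >= r0:
        raise ValueError(f"dipole eccentricity {b / r0:.3f} >= 1")
    R = model.outer_radius

    # frame: z along the dipole position (or moment if central)
    if b > 1e-12:
        ez = pos / b
    else:
        nm = np.linalg.norm(mom)
        ez = mom / nm if nm > 0 else np.array([0.0, 0.0, 1.0])
    # tangential direction: moment component orthogonal to ez
    q_r = float(np.dot(mom, ez))
    t_vec = mom - q_r * ez
    q_t = float(np.linalg.norm(t_vec))
    ex = t_vec / q_t if q_t > 1e-15 else _any_orthogonal(ez)
    ey = np.cross(ez, ex)

    # electrode angles in this frame
    er = np.linalg.norm(elec, axis=1)
    cos_t = np.clip(elec @ ez / er, -1.0, 1.0)
    cos_p = np.zeros(len(elec))
    xs = elec @ ex
    ys = elec @ ey
    rho = np.hypot(xs, ys)
    nz = rho > 1e-12
    cos_p[nz] = xs[nz] / rho[nz]

    n_max = model.n_terms
    ecc = b / r0
    if ecc > 0.9:
        # adaptive extension: high-eccentricity dipoles converge slowly
        n_max = max(n_max, int(np.ceil(np.log(tail_tol) /
                                       np.log(max(ecc, 1e-9)))) + 50)
    coeff = _radial_transfer(model, n_max)
    n = np.arange(1, n_max + 1, dtype=float)
    sigma1 = model.conductivities[0] * 1e-3     # S/m -> S/mm (mm geometry)
    # evaluate the series in outer-radius-scaled coordinates: lengths shrink
    # by R, so the resulting potential is R^2 times too large
    b_s = b / R
    b_pow = np.where(n == 1, 1.0, b_s ** (n - 1))
    beta = b_pow / (4.0 * np.pi * sigma1)
    # outer-shell radial factor evaluated at the (scaled) outer radius 1
    rad = coeff[:, 0] + coeff[:, 1]
    w = beta * rad / R ** 2

    Pn, Pn1 = _legendre_pair(n_max, cos_t)
    term_r = (w * n) @ Pn * q_r
    term_t = (w @ Pn1) * cos_p * q_t
    u = term_r + term_t

    # tail-convergence check on the last decade of terms
    tail = (np.abs(w[-10:, None] * n[-10:, None] * Pn[-10:]).sum(axis=0)
            * max(abs(q_r), 1e-300)
            + np.abs(w[-10:, None] * Pn1[-10:]).sum(axis=0) * abs(q_t))
    scale = np.abs(u).max() + 1e-300
    if np.max(tail) > tail_tol * 10 * scale and np.max(tail) > 1e-15:
        raise RuntimeError(
            f"Legendre series not converged at N={n_max} "
            f"(tail {np.max(tail) / scale:.2e}); increase n_terms")
    return u - u.mean()


def _any_orthogonal(v: np.ndarray) -> np.ndarray:
    a = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else \
        np.array([0.0, 1.0, 0.0])
    out = np.cross(v, a)
    return out / np.linalg.norm(out)


def homogeneous_sphere_potential(radius: float, sigma: float,
                                 dipole_position: np.ndarray,
                                 dipole_moment: np.ndarray,
                                 electrode_positions: np.ndarray
                                 ) -> np.ndarray:
    """Closed-form surface potential for a homogeneous sphere (oracle).

    Independent of the per-degree linear-system path: the series
    sum (2n+1)/n * x^n * [n q_r P_n + q_t P_n^1 cos(phi)] is summed with
    generating-function identities.  Average-referenced.
    """
    pos = np.asarray(dipole_position, dtype=float)
    mom = np.asarray(dipole_moment, dtype=float) * 1e3   # A*m -> A*mm
    elec = np.atleast_2d(np.asarray(electrode_positions, dtype=float))
    R = float(radius)
    b = float(np.linalg.norm(pos))
    if b >= R:
        raise ValueError("dipole outside sphere")
    if b < 1e-12:
        ez = mom / (np.linalg.norm(mom) + 1e-300)
        q_r, q_t = float(np.linalg.norm(mom)), 0.0
        ex = _any_orthogonal(ez)
    else:
        ez = pos / b
        q_r = float(np.dot(mom, ez))
        tv = mom - q_r * ez
        q_t = float(np.linalg.norm(tv))
        ex = tv / q_t if q_t > 1e-15 else _any_orthogonal(ez)
    ey = np.cross(ez, ex)
    c = np.clip(elec @ ez / np.linalg.norm(elec, axis=1), -1.0, 1.0)
    xs, ys = elec @ ex, elec @ ey
    rho = np.hypot(xs, ys)
    cos_p = np.where(rho > 1e-12, xs / np.maximum(rho, 1e-300), 0.0)
    s = np.sqrt(np.maximum(0.0, 1.0 - c * c))

    x = b / R
    d = np.sqrt(1.0 - 2.0 * x * c + x * x)
    pref = 1.0 / (4.0 * np.pi * (sigma * 1e-3) * R * R)
    # radial: (1/x) [ 2x(c - x)/d^3 + 1/d - 1 ]
    if x > 1e-12:
        v_r = pref * (2.0 * (c - x) / d ** 3 + (1.0 / d - 1.0) / x)
    else:
        v_r = pref * 3.0 * c      # n=1 limit: (2n+1)/n * P_1 = 3 c
    # tangential: (1/x) { 2 s x / d^3 + [ (x - c)/d + c ] / s }
    with np.errstate(divide="ignore", invalid="ignore"):
        v_t = pref * (2.0 * s / d ** 3
                      + ((x - c) / d + c) / np.maximum(s * x, 1e-300))
    v_t = np.where(s < 1e-12, 0.0, v_t) * cos_p
    u = q_r * v_r + q_t * v_t
    return u - u.mean()
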