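"""Sparse SPD solvers for the transfer-matrix equations.

scipy's SuperLU fill-in explodes on 3D P1 stiffness matrices beyond ~10^5
unknowns, and its ILU is not a symmetric preconditioner (invalid for CG), so
the workhorse here is conjugate gradients preconditioned with a zero-fill
incomplete Cholesky factorization (IC(0)), both jitted with numba when
available.  IC(0) breakdown (non-positive pivot, possible since P1 stiffness
is not always an M-matrix) is handled by retrying with an increasing
diagonal shift.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import sparse

log = logging.getLogger(__name__)

__all__ = ["IChol0", "pcg"]

try:
    import numba

    njit = numba.njit(cache=True)
except Exception:  # pragma: no cover
    def njit(f):
        return f


@njit
def _ic0_kernel(n, indptr, indices, data, diag_shift):
    """IC(0) on the lower triangle (CSR, sorted column indices, diag last).

    Returns 0 on success, the failing row + 1 on breakdown.
    data is overwritten with the factor L (same sparsity)."""
    for i in range(n):
        s0, e0 = indptr[i], indptr[i + 1]
        # off-diagonal entries of row i
        for jj in range(s0, e0 - 1):
            j = indices[jj]
            # dot of rows i and j over shared columns < j
            s1, e1 = indptr[j], indptr[j + 1]
            acc = 0.0
            a, b = s0, s1
            while a < jj and b < e1 - 1:
                ca, cb = indices[a], indices[b]
                if ca == cb:
                    acc += data[a] * data[b]
                    a += 1
                    b += 1
                elif ca < cb:
                    a += 1
                else:
                    b += 1
            data[jj] = (data[jj] - acc) / data[e1 - 1]
        # diagonal
        acc = 0.0
        for a in range(s0, e0 - 1):
            acc += data[a] * data[a]
        d = data[e0 - 1] + diag_shift - acc
        if d <= 0.0:
            return i + 1
        data[e0 - 1] = np.sqrt(d)
    return 0


@njit
def _solve_lower(n, indptr, indices, data, b):
    x = b.copy()
    for i in range(n):
        s, e = indptr[i], indptr[i + 1]
        acc = x[i]
        for a in range(s, e - 1):
            acc -= data[a] * x[indices[a]]
        x[i] = acc / data[e - 1]
    return x


@njit
def _solve_upper(n, indptr, indices, data, b):
    # solves L^T x = b with L in lower-CSR layout (column sweeps)
    x = b.copy()
    for i in range(n - 1, -1, -1):
        s, e = indptr[i], indptr[i + 1]
        x[i] = x[i] / data[e - 1]
        xi = x[i]
        for a in range(s, e - 1):
            x[indices[a]] -= data[a] * xi
    return x


class IChol0:
    """Zero-fill incomplete Cholesky preconditioner for an SPD csr matrix."""

    def __init__(self, A: sparse.csr_matrix, max_tries: int = 6):
        A = A.tocsr()
        A.sort_indices()
        low = sparse.tril(A, format="csr")
        low.sort_indices()
        self.n = A.shape[0]
        self.indptr = low.indptr
        self.indices = low.indices
        base = low.data.copy()
        mean_diag = float(A.diagonal().mean())
        shift = 0.0
        for attempt in range(max_tries):
            data = base.copy()
            fail = _ic0_kernel(self.n, self.indptr, self.indices, data, shift)
            if fail == 0:
                self.data = data
                if attempt:
                    log.info("IC(0) succeeded with diagonal shift %.2e", shift)
                return
            shift = mean_diag * (1e-3 * 10 ** attempt)
        raise RuntimeError("IC(0) breakdown despite diagonal shifts")

    def solve(self, b: np.ndarray) -> np.ndarray:
        y = _solve_lower(self.n, self.indptr, self.indices, self.data, b)
        return _solve_upper(self.n, self.indptr, self.indices, self.data, y)


def pcg(A: sparse.csr_matrix, b: np.ndarray, M: IChol0,
        rtol: float = 1e-8, maxiter: int = 10000,
        x0: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Preconditioned conjugate gradients; returns (x, iterations).

    Raises RuntimeError if the relative residual does not reach rtol.
    """
    x = np.zeros_like(b) if x0 is None else x0.copy()
    r = b - A @ x if x0 is not None else b.copy()
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        return x, 0
    z = M.solve(r)
    p = z.copy()
    rz = float(r @ z)
    for it in range(1, maxiter + 1):
        Ap = A @ p
        alpha = rz / float(p @ Ap)
        x += alpha * p
        r -= alpha * Ap
        if np.linalg.norm(r) <= rtol * bnorm:
            return x, it
        z = M.solve(r)
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
    res = np.linalg.norm(A @ x - b) / bnorm
    raise RuntimeError(f"PCG did not converge in {maxiter} iterations "
                       f"(relative residual {res:.2e})")
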