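"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own code paths: the FTCS update is
expressed as a dense affine map assembled node by node, forces are summed
over all pairs, and steady states come from a sparse linear solve.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def dense_ftcs_operator(shape, h, D, lam, A_plus, A_minus, dt,
                        dirichlet_value=None):
    """Dense affine map u' = B u + c of one FTCS step with ghost-node
    mirroring (Neumann) or fixed boundary nodes (Dirichlet)."""
    nx, ny, nz = shape
    n = nx * ny * nz

    def lin(i, j, k):
        return (i * ny + j) * nz + k

    B = np.zeros((n, n))
    c = np.zeros(n)
    ap = np.broadcast_to(A_plus, shape)
    am = np.broadcast_to(A_minus, shape)
    r = D * dt / h ** 2
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                row = lin(i, j, k)
                B[row, row] += (1.0 - lam * dt - 6.0 * r
                                - dt * ap[i, j, k] - dt * am[i, j, k])
                c[row] += dt * ap[i, j, k]
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                        B[row, lin(ii, jj, kk)] += r
                    else:
                        B[row, row] += r  # mirrored ghost node
    if dirichlet_value is not None:
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if (i in (0, nx - 1) or j in (0, ny - 1)
                            or k in (0, nz - 1)):
                        row = lin(i, j, k)
                        B[row, :] = 0.0
                        c[row] = dirichlet_value
    return B, c


def brute_force_forces(positions, r_physical, r_action, c_rep, c_adh):
    """All-pairs sum of the documented piecewise force law."""
    n = len(positions)
    forces = np.zeros((n, 3))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diff = positions[i] - positions[j]
            d = np.linalg.norm(diff)
            ra = r_action[i] + r_action[j]
            rp = r_physical[i] + r_physical[j]
            if d >= ra or d == 0.0:
                continue
            if d < rp:
                f = c_rep * (rp - d) / rp
            else:
                f = -c_adh * (ra - d) * (d - rp) / (ra - rp) ** 2
            forces[i] += f * diff / d
    return forces


def sparse_steady_state(shape, h, D, lam, A_plus, A_minus):
    """Steady state of  lam u - D Lap u + (A+ + A-) u = A+  with zero-flux
    boundaries, via a sparse direct solve."""
    nx, ny, nz = shape
    n = nx * ny * nz

    def lin(i, j, k):
        return (i * ny + j) * nz + k

    ap = np.broadcast_to(A_plus, shape).ravel()
    am = np.broadcast_to(A_minus, shape).ravel()
    rows, cols, vals = [], [], []
    r = D / h ** 2
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                row = lin(i, j, k)
                diag = lam + ap[row] + am[row]
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                        rows.append(row)
                        cols.append(lin(ii, jj, kk))
                        vals.append(-r)
                        diag += r
                rows.append(row)
                cols.append(row)
                vals.append(diag)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    u = sp.linalg.spsolve(A, ap)
    return u.reshape(shape)
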