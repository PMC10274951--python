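"""Reaction-diffusion fields on a uniform cubic lattice (FTCS scheme).

Each substance (nutrients, VEGF, DOX, TRA) lives on its own scalar field
u(i,j,k) in [0, 1] with diffusion coefficient D (um^2/h), linear decay
lambda (1/h) and either zero-flux Neumann or constant-value Dirichlet
boundaries.  One explicit step reads

    u' = (1 - lam dt) u + (D dt / h^2) Lap6(u)
         + dt (1 - u) A+  -  dt u A-

with the 6-point Laplacian; sources enter with prefactor (1 - u) and sinks
with prefactor u, which together with the stability bound
(lam + 12 D / h^2) dt <= 2 keeps u in [0, 1].
"""

from __future__ import annotations

import numpy as np

_STAB_EPS = 1e-9


def max_stable_dt(D: float, lam: float, h: float) -> float:
    """Largest dt (hours) satisfying (lam + 12 D / h^2) dt <= 2."""
    if D <= 0 or h <= 0:
        raise ValueError("D and h must be positive")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    return 2.0 / (lam + 12.0 * D / h ** 2)


class SubstanceGrid:
    """One scalar concentration field on a uniform cubic lattice.

    Nodes sit at ``origin + h * (i, j, k)``; the domain for point lookups is
    the lattice's bounding box.  ``bc`` is ``"neumann"`` (zero flux, ghost
    node mirroring) or ``("dirichlet", value)`` (boundary nodes held fixed).
    """

    def __init__(self, name: str, shape, h: float, D: float, lam: float,
                 bc="neumann", origin=(0.0, 0.0, 0.0), initial: float = 0.0):
        if name not in ("nutrients", "VEGF", "DOX", "TRA"):
            raise ValueError(f"unknown substance {name!r}")
        self.name = name
        self.h = float(h)
        self.D = float(D)
        self.lam = float(lam)
        if isinstance(bc, str):
            if bc != "neumann":
                raise ValueError("string bc must be 'neumann'")
            self.bc = ("neumann", None)
        else:
            kind, value = bc
            if kind != "dirichlet":
                raise ValueError("tuple bc must be ('dirichlet', value)")
            self.bc = ("dirichlet", float(value))
        self.origin = np.asarray(origin, dtype=float)
        self.values = np.full(tuple(shape), float(initial))
        if self.bc[0] == "dirichlet":
            self._set_boundary(self.bc[1])

    @property
    def shape(self):
        return self.values.shape

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.h * (np.array(self.shape) - 1)

    def _set_boundary(self, value: float) -> None:
        v = self.values
        v[0, :, :] = v[-1, :, :] = value
        v[:, 0, :] = v[:, -1, :] = value
        v[:, :, 0] = v[:, :, -1] = value

    # ---- point lookups -------------------------------------------------

    def node_index(self, points) -> tuple[np.ndarray, ...]:
        """Nearest lattice node per point (ties broken toward lower index)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if np.any(pts < self.origin - 1e-9) or np.any(pts > self.upper + 1e-9):
            raise ValueError("point outside the lattice domain")
        q = (pts - self.origin) / self.h
        idx = np.ceil(q - 0.5).astype(np.int64)
        idx = np.clip(idx, 0, np.array(self.shape) - 1)
        return idx[:, 0], idx[:, 1], idx[:, 2]

    def sample_at(self, point):
        """Concentration at the nearest lattice node."""
        i, j, k = self.node_index(point)
        out = self.values[i, j, k]
        return float(out[0]) if out.size == 1 and np.ndim(point) == 1 else out

    def gradient_at(self, point):
        """Central-difference gradient at the nearest node (one-sided at
        boundaries), in concentration per micrometer."""
        i, j, k = self.node_index(point)
        single = np.ndim(point) == 1
        grads = np.empty((i.size, 3))
        v = self.values
        for axis, idx in enumerate((i, j, k)):
            nmax = self.shape[axis] - 1
            up = np.minimum(idx + 1, nmax)
            dn = np.maximum(idx - 1, 0)
            sel_up = [i, j, k]
            sel_dn = [i, j, k]
            sel_up[axis] = up
            sel_dn[axis] = dn
            span = (up - dn) * self.h
            span[span == 0] = self.h  # degenerate single-layer axis
            grads[:, axis] = (v[tuple(sel_up)] - v[tuple(sel_dn)]) / span
        return grads[0] if single else grads

    # ---- time stepping -------------------------------------------------

    def ftcs_step(self, A_plus, A_minus, dt: float) -> None:
        """One explicit forward-time centered-space step (in place)."""
        bound = max_stable_dt(self.D, self.lam, self.h)
        if dt > bound * (1.0 + _STAB_EPS):
            raise RuntimeError(
                f"unstable time step dt={dt} h for substance {self.name}: "
                f"stability requires dt <= {bound} h")
        u = self.values
        if A_plus is None:
            A_plus = 0.0
        if A_minus is None:
            A_minus = 0.0
        padded = np.pad(u, 1, mode="edge")  # zero-flux ghost mirror
        lap = (padded[2:, 1:-1, 1:-1] + padded[:-2, 1:-1, 1:-1]
               + padded[1:-1, 2:, 1:-1] + padded[1:-1, :-2, 1:-1]
               + padded[1:-1, 1:-1, 2:] + padded[1:-1, 1:-1, :-2]
               - 6.0 * u)
        new = ((1.0 - self.lam * dt) * u
               + (self.D * dt / self.h ** 2) * lap
               + dt * (1.0 - u) * A_plus
               - dt * u * A_minus)
        if not np.all(np.isfinite(new)):
            raise RuntimeError(f"non-finite values in substance {self.name}")
        self.values = new
        if self.bc[0] == "dirichlet":
            self._set_boundary(self.bc[1])

    def advance(self, A_plus, A_minus, dt: float) -> int:
        """Advance by ``dt`` using the fewest stable FTCS substeps.

        The source/sink fields are held fixed across substeps (operator
        splitting at the agent step).  Besides the von Neumann bound, the
        substep honours the monotonicity bound
        ``(lam + 6 D / h^2 + max(A+ + A-)) dt' <= 1`` so that strong point
        sources cannot push u outside [0, 1].  Returns the substep count.
        """
        bound = max_stable_dt(self.D, self.lam, self.h)
        a_max = 0.0
        if A_plus is not None or A_minus is not None:
            a_tot = 0.0
            if A_plus is not None:
                a_tot = a_tot + np.asarray(A_plus)
            if A_minus is not None:
                a_tot = a_tot + np.asarray(A_minus)
            a_max = float(np.max(a_tot)) if np.ndim(a_tot) else float(a_tot)
        mono = 1.0 / (self.lam + 6.0 * self.D / self.h ** 2 + a_max)
        bound = min(bound, mono)
        m = max(1, int(np.ceil(dt / bound - _STAB_EPS)))
        sub = dt / m
        for _ in range(m):
            self.ftcs_step(A_plus, A_minus, sub)
        return m

    # ---- snapshots -----------------------------------------------------

    def write_snapshot(self, path) -> None:
        """Portable binary snapshot (.npz) with a JSON-style text header."""
        import json

        header = {"name": self.name, "h": self.h,
                  "origin": self.origin.tolist(), "shape": list(self.shape),
                  "D": self.D, "lam": self.lam}
        np.savez(path, header=json.dumps(header), values=self.values)
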