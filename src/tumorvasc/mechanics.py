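"""Cell-cell forces, neighbor search and overdamped displacement updates.

Cells interact through a two-particle central force depending on the center
distance d.  The force vanishes for d >= RA (sum of the two action radii).
The implemented law is a documented piecewise-polynomial surrogate:

* repulsive branch, d < RP (sum of physical radii):
  f(d) = c_repulsion * (RP - d) / RP         (> 0, pushes apart)
* adhesive well, RP <= d < RA:
  f(d) = -c_adhesion * (RA - d)(d - RP) / (RA - RP)^2   (< 0, pulls together)
* f(d) = 0 for d >= RA.

The law is continuous in d, antisymmetric between the pair, zero exactly at
d = RP (the equilibrium separation) and at d = RA.  Positions follow the
overdamped update x(t+dt) = x(t) + eta * F * dt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ForceParams:
    """Force scales and viscosity (displacement per force per hour)."""

    c_repulsion: float = 10.0
    c_adhesion: float = 0.4
    eta: float = 2.0

    def __post_init__(self) -> None:
        if min(self.c_repulsion, self.c_adhesion, self.eta) < 0:
            raise ValueError("force parameters must be nonnegative")


def force_magnitude(d, rp_sum, ra_sum, params: ForceParams):
    """Signed scalar force along the center line (positive = repulsive)."""
    d = np.asarray(d, dtype=float)
    rp_sum = np.asarray(rp_sum, dtype=float)
    ra_sum = np.asarray(ra_sum, dtype=float)
    rep = params.c_repulsion * (rp_sum - d) / rp_sum
    span = np.maximum(ra_sum - rp_sum, 1e-300)
    adh = -params.c_adhesion * (ra_sum - d) * (d - rp_sum) / span ** 2
    out = np.where(d < rp_sum, rep, np.where(d < ra_sum, adh, 0.0))
    return out


def pairwise_force(cell_i, cell_j, params: ForceParams,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Force exerted on cell i by cell j (3-vector, micro-Newton scale units).

    Zero beyond the action range; antisymmetric by construction.  Coincident
    centers repel along a random unit direction (tie-break; requires ``rng``).
    """
    xi = np.asarray(cell_i.position, dtype=float)
    xj = np.asarray(cell_j.position, dtype=float)
    diff = xi - xj
    d = float(np.linalg.norm(diff))
    ra_sum = cell_i.r_action + cell_j.r_action
    rp_sum = cell_i.r_physical + cell_j.r_physical
    if d >= ra_sum:
        return np.zeros(3)
    if d == 0.0:
        if rng is None:
            rng = np.random.default_rng()
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        return params.c_repulsion * u
    f = force_magnitude(d, rp_sum, ra_sum, params)
    return float(f) * diff / d


class NeighborGrid:
    """Uniform spatial hash over buckets of edge ``h_grid``.

    ``h_grid`` must be at least the interaction cutoff (2 x the largest
    action radius): every pair at distance <= h_grid is then guaranteed to be
    found among the 27-bucket neighborhoods.
    """

    # 13 forward offsets + the self bucket cover all 27 neighbors once
    _HALF_OFFSETS = np.array(
        [(1, 0, 0), (0, 1, 0), (0, 0, 1),
         (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
         (0, 1, 1), (0, 1, -1),
         (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)], dtype=np.int64)

    def __init__(self, positions: np.ndarray, h_grid: float) -> None:
        if h_grid <= 0:
            raise ValueError("h_grid must be positive")
        self.positions = np.asarray(positions, dtype=float)
        self.h = float(h_grid)
        coords = np.floor(self.positions / self.h).astype(np.int64)
        coords -= coords.min(axis=0) if len(coords) else 0
        self._coords = coords
        span = (coords.max(axis=0) + 3) if len(coords) else np.ones(3, int)
        self._base = np.array(
            [span[1] * span[2], span[2], 1], dtype=np.int64)
        keys = coords @ self._base
        self._order = np.argsort(keys, kind="stable")
        self._sorted_keys = keys[self._order]
        self._keys = keys

    def _lookup(self, query_keys: np.ndarray):
        lo = np.searchsorted(self._sorted_keys, query_keys, side="left")
        hi = np.searchsorted(self._sorted_keys, query_keys, side="right")
        return lo, hi

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """All unique candidate index pairs (i, j) from neighboring buckets."""
        n = len(self.positions)
        if n < 2:
            return (np.empty(0, dtype=np.int64),) * 2
        i_out, j_out = [], []

        # self bucket: i < j within the same key
        lo, hi = self._lookup(self._keys)
        counts = hi - lo
        rank = np.empty(n, dtype=np.int64)  # position of each cell in order
        rank[self._order] = np.arange(n)
        # pair each cell with later cells in its own bucket
        later = hi - rank - 1
        total = int(later.sum())
        if total:
            i_rep = np.repeat(np.arange(n), later)
            starts = np.repeat(rank + 1, later)
            offs = np.arange(total) - np.repeat(
                np.cumsum(later) - later, later)
            j_idx = self._order[starts + offs]
            i_out.append(i_rep)
            j_out.append(j_idx)

        # forward neighbor buckets
        for off in self._HALF_OFFSETS:
            qkeys = self._keys + off @ self._base
            lo, hi = self._lookup(qkeys)
            counts = hi - lo
            total = int(counts.sum())
            if not total:
                continue
            i_rep = np.repeat(np.arange(n), counts)
            starts = np.repeat(lo, counts)
            offs = np.arange(total) - np.repeat(
                np.cumsum(counts) - counts, counts)
            j_idx = self._order[starts + offs]
            i_out.append(i_rep)
            j_out.append(j_idx)

        if not i_out:
            return (np.empty(0, dtype=np.int64),) * 2
        return np.concatenate(i_out), np.concatenate(j_out)


def total_forces(positions: np.ndarray, r_physical: np.ndarray,
                 r_action: np.ndarray, params: ForceParams,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Sum of pairwise forces on every cell, via the uniform neighbor grid.

    Equals the brute-force all-pairs sum: the grid spacing is twice the
    instantaneous maximum action radius, so no interacting pair is missed.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    forces = np.zeros((n, 3))
    if n < 2:
        return forces
    r_physical = np.asarray(r_physical, dtype=float)
    r_action = np.asarray(r_action, dtype=float)
    h_grid = 2.0 * float(r_action.max())
    grid = NeighborGrid(positions, h_grid)
    i_idx, j_idx = grid.pairs()
    if i_idx.size == 0:
        return forces
    diff = positions[i_idx] - positions[j_idx]
    d = np.linalg.norm(diff, axis=1)
    ra_sum = r_action[i_idx] + r_action[j_idx]
    active = d < ra_sum
    i_idx, j_idx, diff, d, ra_sum = (a[active] for a in
                                     (i_idx, j_idx, diff, d, ra_sum))
    if i_idx.size == 0:
        return forces
    rp_sum = r_physical[i_idx] + r_physical[j_idx]
    coincident = d == 0.0
    if np.any(coincident):
        if rng is None:
            rng = np.random.default_rng()
        k = int(coincident.sum())
        u = rng.standard_normal((k, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        diff[coincident] = u
        d[coincident] = 1.0  # unit direction; magnitude set below
    f = force_magnitude(d, rp_sum, ra_sum, params)
    if np.any(coincident):
        f = np.where(coincident, params.c_repulsion, f)
    fvec = (f / d)[:, None] * diff
    np.add.at(forces, i_idx, fvec)
    np.add.at(forces, j_idx, -fvec)
    return forces


def apply_displacements(positions: np.ndarray, forces: np.ndarray,
                        eta: float, dt: float) -> np.ndarray:
    """Overdamped update: x <- x + eta * F * dt."""
    return np.asarray(positions, dtype=float) + eta * dt * np.asarray(forces)


def reflect_into_box(positions: np.ndarray, lo, hi) -> np.ndarray:
    """Reflect positions into the axis-aligned box [lo, hi]^3.

    Keeps agents inside the continuum domain so concentration lookups stay
    defined; cells are otherwise unconfined.
    """
    p = np.array(positions, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    span = hi - lo
    q = np.mod(p - lo, 2.0 * span)
    q = np.where(q > span, 2.0 * span - q, q)
    return lo + q
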