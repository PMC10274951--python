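"""Stochastic five-state cell cycle of tumor agents.

Each tumor cell is a spherical agent with three radii (nuclear, physical,
action), a categorical state and an internal clock counting hours since the
last state change.  States:

* ``Q``   quiescent (idle),
* ``SG2`` DNA duplication and mitosis preparation,
* ``G1``  post-division growth back to natural size,
* ``H``   hypoxic (secretes VEGF),
* ``D``   dead (absorbing; no further transitions, no continuum coupling).

Reachable transitions are Q->SG2/H/D, SG2->G1/D/SG2 (clock reset), G1->Q and
H->Q/D.  Deterministic rules are clock timers (SG2->G1, G1->Q) and the
hypoxic nutrient threshold (Q<->H); all remaining transitions are stochastic
with per-step probabilities built from a smoothed Heaviside and a linear ramp
of the local substance concentrations, with multiplicative doxorubicin (DOX)
and trastuzumab (TRA) pharmacodynamic terms.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

# integer state codes used by the vectorized population
Q, SG2, G1, H, D = 0, 1, 2, 3, 4
STATE_NAMES = ("Q", "SG2", "G1", "H", "D")
STATE_CODES = {name: code for code, name in enumerate(STATE_NAMES)}

#: default radii in micrometers (physical, nuclear, action)
DEFAULT_R_PHYSICAL = 9.953
DEFAULT_R_NUCLEAR = 5.296
DEFAULT_R_ACTION = 12.083

_HALF_VOLUME_SCALE = 2.0 ** (-1.0 / 3.0)


@dataclass
class TumorCell:
    """A single spherical tumor agent (convenience record view).

    The simulation engine stores the population as arrays; this record is the
    unit-level interface used by tests and single-cell stepping.
    """

    id: int
    position: np.ndarray
    r_nuclear: float = DEFAULT_R_NUCLEAR
    r_physical: float = DEFAULT_R_PHYSICAL
    r_action: float = DEFAULT_R_ACTION
    state: str = "Q"
    clock: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not (0.0 < self.r_nuclear <= self.r_physical <= self.r_action):
            raise ValueError(
                "radii must satisfy 0 < r_nuclear <= r_physical <= r_action, "
                f"got ({self.r_nuclear}, {self.r_physical}, {self.r_action})"
            )
        if self.state not in STATE_NAMES:
            raise ValueError(f"unknown cell state {self.state!r}")
        if self.clock < 0:
            raise ValueError("clock must be nonnegative")


@dataclass
class CellCycleParams:
    """The 20 scalar parameters of the stochastic cell cycle.

    Times in hours, rates in 1/h, thresholds as dimensionless concentrations
    in [0, 1], suppression/amplification constants dimensionless and >= 0.
    """

    # deterministic timers and hypoxic threshold
    T_SG2: float = 10.0           # residence time in SG2 [h]
    T_G1: float = 7.0             # residence time in G1 [h]
    u_n_hypoxic: float = 0.12     # nutrient threshold for Q<->H

    # Q -> SG2 : linear ramp in nutrients, TRA-suppressed
    c_Q_SG2: float = 0.05
    u_n_Q_SG2: float = 0.1
    lambda_Q_SG2: float = 60.0

    # Q -> D : smoothed Heaviside in nutrients, drug-amplified
    a_Q_D: float = 1.0e-3
    b_Q_D: float = 30.0
    u_n_Q_D: float = 0.02
    xi_d_Q_D: float = 0.5
    xi_t_Q_D: float = 0.5
    xi_dt_Q_D: float = 6000.0

    # SG2 -> SG2 (clock reset) : linear ramp in DOX
    c_SG2_SG2: float = 1.0
    u_d_SG2_SG2: float = 0.05

    # SG2 -> D : linear ramp in nutrients
    c_SG2_D: float = 1.0e-3
    u_n_SG2_D: float = 0.9

    # H -> D : constant rate, drug-amplified
    r_H_D: float = 0.01
    xi_d_H_D: float = 0.5
    xi_t_H_D: float = 0.5
    xi_dt_H_D: float = 6000.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"cell-cycle parameter {f.name} must be >= 0")
        for name in ("u_n_hypoxic", "u_n_Q_SG2", "u_n_Q_D",
                     "u_d_SG2_SG2", "u_n_SG2_D"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold {name} must lie in [0, 1]")


def _check_unit_interval(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError(f"{name} must lie in [0, 1]")
    return x


def smoothed_heaviside(x, a: float, b: float, xbar: float, dt: float):
    """Per-step probability from a smoothed, decreasing Heaviside rate.

    sigma = 1 - exp(-(a + 1/(1 + exp(2 b (x - xbar)))) * dt)

    ``a`` offsets the rate, ``b`` sets the sharpness of the transition and
    ``xbar`` its location.  Monotonically non-increasing in ``x`` for b > 0.
    """
    x = _check_unit_interval(x, "x")
    _check_unit_interval(xbar, "xbar")
    if a < 0 or b < 0 or dt < 0:
        raise ValueError("a, b and dt must be nonnegative")
    from scipy.special import expit  # overflow-safe logistic

    rate = a + expit(-2.0 * b * (x - xbar))
    return 1.0 - np.exp(-rate * dt)


def linear_ramp(x, c: float, xbar: float, dt: float):
    """Per-step probability from a clamped linear rate ramp.

    rho = 1 - exp(-max(c (x - xbar) / (1 - xbar), 0) * dt)

    Zero for x <= xbar, monotonically non-decreasing in ``x``.
    """
    x = _check_unit_interval(x, "x")
    if not 0.0 <= xbar < 1.0:
        raise ValueError("xbar must lie in [0, 1) for the ramp")
    if c < 0 or dt < 0:
        raise ValueError("c and dt must be nonnegative")
    rate = np.maximum(c * (x - xbar) / (1.0 - xbar), 0.0)
    return 1.0 - np.exp(-rate * dt)


def transition_probabilities(u_n, u_v, u_d, u_t,
                             params: CellCycleParams, dt: float) -> dict:
    """Closed-form per-step probabilities of the five stochastic transitions.

    All inputs are local dimensionless concentrations in [0, 1] (scalars or
    equally shaped arrays).  Every returned probability is clamped to [0, 1].
    VEGF (``u_v``) does not enter any transition; it is accepted so the
    signature mirrors the set of modeled substances.
    """
    p = params
    u_n = _check_unit_interval(u_n, "u_n")
    _check_unit_interval(u_v, "u_v")
    u_d = _check_unit_interval(u_d, "u_d")
    u_t = _check_unit_interval(u_t, "u_t")

    p_q_sg2 = linear_ramp(u_n, p.c_Q_SG2, p.u_n_Q_SG2, dt) \
        * np.exp(-p.lambda_Q_SG2 * u_t)
    drug_qd = 1.0 + p.xi_d_Q_D * u_d + p.xi_t_Q_D * u_t \
        + p.xi_dt_Q_D * u_d * u_t
    p_q_d = smoothed_heaviside(u_n, p.a_Q_D, p.b_Q_D, p.u_n_Q_D, dt) * drug_qd
    p_sg2_sg2 = linear_ramp(u_d, p.c_SG2_SG2, p.u_d_SG2_SG2, dt)
    p_sg2_d = linear_ramp(u_n, p.c_SG2_D, p.u_n_SG2_D, dt)
    drug_hd = 1.0 + p.xi_d_H_D * u_d + p.xi_t_H_D * u_t \
        + p.xi_dt_H_D * u_d * u_t
    p_h_d = p.r_H_D * dt * drug_hd

    clamp = lambda v: np.clip(v, 0.0, 1.0)
    return {
        "Q->SG2": clamp(p_q_sg2),
        "Q->D": clamp(p_q_d),
        "SG2->SG2": clamp(p_sg2_sg2),
        "SG2->D": clamp(p_sg2_d),
        "H->D": clamp(p_h_d),
    }


class CellPopulation:
    """Structure-of-arrays container for the tumor cell population.

    Cells are stored in ascending-id order (ids are never reused and dead
    cells are kept: they retain mechanical presence but are excluded from all
    continuum coupling).  ``nat_*`` hold the natural (fully grown) radii a
    cell regrows to during G1.
    """

    def __init__(self) -> None:
        self.ids = np.empty(0, dtype=np.int64)
        self.pos = np.empty((0, 3), dtype=float)
        self.r_n = np.empty(0, dtype=float)
        self.r_p = np.empty(0, dtype=float)
        self.r_a = np.empty(0, dtype=float)
        self.nat_r_n = np.empty(0, dtype=float)
        self.nat_r_p = np.empty(0, dtype=float)
        self.nat_r_a = np.empty(0, dtype=float)
        self.state = np.empty(0, dtype=np.int8)
        self.clock = np.empty(0, dtype=float)
        self._next_id = 0

    def __len__(self) -> int:
        return self.ids.size

    @classmethod
    def from_positions(cls, positions, state: str = "Q",
                       r_nuclear: float = DEFAULT_R_NUCLEAR,
                       r_physical: float = DEFAULT_R_PHYSICAL,
                       r_action: float = DEFAULT_R_ACTION) -> "CellPopulation":
        pop = cls()
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = positions.shape[0]
        code = STATE_CODES[state]
        pop.ids = np.arange(n, dtype=np.int64)
        pop._next_id = n
        pop.pos = positions.copy()
        pop.r_n = np.full(n, r_nuclear)
        pop.r_p = np.full(n, r_physical)
        pop.r_a = np.full(n, r_action)
        pop.nat_r_n = np.full(n, r_nuclear)
        pop.nat_r_p = np.full(n, r_physical)
        pop.nat_r_a = np.full(n, r_action)
        pop.state = np.full(n, code, dtype=np.int8)
        pop.clock = np.zeros(n)
        return pop

    def _append(self, pos, r_n, r_p, r_a, nat_r_n, nat_r_p, nat_r_a,
                state_code, clock) -> None:
        k = len(pos)
        new_ids = np.arange(self._next_id, self._next_id + k, dtype=np.int64)
        self._next_id += k
        self.ids = np.concatenate([self.ids, new_ids])
        self.pos = np.vstack([self.pos, pos])
        self.r_n = np.concatenate([self.r_n, r_n])
        self.r_p = np.concatenate([self.r_p, r_p])
        self.r_a = np.concatenate([self.r_a, r_a])
        self.nat_r_n = np.concatenate([self.nat_r_n, nat_r_n])
        self.nat_r_p = np.concatenate([self.nat_r_p, nat_r_p])
        self.nat_r_a = np.concatenate([self.nat_r_a, nat_r_a])
        self.state = np.concatenate(
            [self.state, np.full(k, state_code, dtype=np.int8)])
        self.clock = np.concatenate([self.clock, np.full(k, clock)])

    @property
    def living(self) -> np.ndarray:
        """Boolean mask of non-dead cells."""
        return self.state != D

    def counts(self) -> dict:
        out = {name: int(np.count_nonzero(self.state == code))
               for name, code in STATE_CODES.items()}
        out["living"] = int(np.count_nonzero(self.living))
        out["total"] = len(self)
        return out

    def as_cell(self, i: int) -> TumorCell:
        return TumorCell(
            id=int(self.ids[i]), position=self.pos[i].copy(),
            r_nuclear=float(self.r_n[i]), r_physical=float(self.r_p[i]),
            r_action=float(self.r_a[i]),
            state=STATE_NAMES[self.state[i]], clock=float(self.clock[i]))

    def write_snapshot(self, path) -> None:
        """Delimited-text snapshot, one row per cell."""
        with open(path, "w") as fh:
            fh.write("id,x,y,z,r_nuclear,r_physical,r_action,state,clock\n")
            for i in range(len(self)):
                nums = [*self.pos[i], self.r_n[i], self.r_p[i], self.r_a[i]]
                cols = ",".join(repr(float(v)) for v in nums)
                fh.write(f"{self.ids[i]},{cols},"
                         f"{STATE_NAMES[self.state[i]]},"
                         f"{repr(float(self.clock[i]))}\n")


def step_cells(pop: CellPopulation, u_n, u_v, u_d, u_t,
               params: CellCycleParams, dt: float,
               rng: np.random.Generator) -> int:
    """Advance every cell by one step of length ``dt`` hours (in place).

    Rule order (fixed, at most one state change per cell per step):

    1. G1 cells regrow their radii linearly toward natural size.
    2. deterministic timers: SG2->G1 (volume-preserving division producing a
       daughter at distance r_physical along a uniformly random direction),
       then G1->Q;
    3. hypoxia switch: Q->H if u_n < threshold, H->Q otherwise;
    4. one stochastic draw per still-unchanged Q/SG2/H cell against the
       closed-form transition probabilities (sequential thresholds on a
       single uniform variate per cell, ascending array order).

    Every state change (including the SG2->SG2 clock reset) resets the clock.
    Dead cells never change.  Returns the number of daughters created.
    """
    n = len(pop)
    if n == 0:
        return 0
    if np.any(pop.state > D) or np.any(pop.state < 0):
        raise RuntimeError("unknown cell state code in population")
    u_n = np.broadcast_to(np.asarray(u_n, dtype=float), (n,))
    u_d = np.broadcast_to(np.asarray(u_d, dtype=float), (n,))
    u_t = np.broadcast_to(np.asarray(u_t, dtype=float), (n,))
    u_v = np.broadcast_to(np.asarray(u_v, dtype=float), (n,))

    changed = np.zeros(n, dtype=bool)
    state = pop.state

    # 1. G1 regrowth (linear over T_G1 from half-volume radii to natural)
    g1 = state == G1
    if np.any(g1) and params.T_G1 > 0:
        frac = (1.0 - _HALF_VOLUME_SCALE) * dt / params.T_G1
        for cur, nat in ((pop.r_n, pop.nat_r_n), (pop.r_p, pop.nat_r_p),
                         (pop.r_a, pop.nat_r_a)):
            cur[g1] = np.minimum(cur[g1] + nat[g1] * frac, nat[g1])

    # 2. deterministic timers (daughters are appended after the whole step
    # so that array views stay valid; daughters start in G1 with clock 0)
    dividing = (state == SG2) & (pop.clock >= params.T_SG2)
    n_new = int(np.count_nonzero(dividing))
    daughter_rows = None
    if n_new:
        idx = np.flatnonzero(dividing)
        dirs = rng.standard_normal((n_new, 3))
        norms = np.linalg.norm(dirs, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        dirs /= norms
        # both mother and daughter take half the mother's volume
        for arr in (pop.r_n, pop.r_p, pop.r_a):
            arr[idx] *= _HALF_VOLUME_SCALE
        daughter_pos = pop.pos[idx] + dirs * pop.r_p[idx][:, None]
        state[idx] = G1
        pop.clock[idx] = 0.0
        changed[idx] = True
        daughter_rows = (daughter_pos,
                         pop.r_n[idx].copy(), pop.r_p[idx].copy(),
                         pop.r_a[idx].copy(), pop.nat_r_n[idx].copy(),
                         pop.nat_r_p[idx].copy(), pop.nat_r_a[idx].copy())

    to_q = (state == G1) & ~changed & (pop.clock >= params.T_G1)
    state[to_q] = Q
    pop.clock[to_q] = 0.0
    changed[to_q] = True

    # 3. hypoxia switch
    to_h = (state == Q) & ~changed & (u_n < params.u_n_hypoxic)
    state[to_h] = H
    pop.clock[to_h] = 0.0
    changed[to_h] = True
    from_h = (state == H) & ~changed & (u_n >= params.u_n_hypoxic)
    state[from_h] = Q
    pop.clock[from_h] = 0.0
    changed[from_h] = True

    # 4. one stochastic draw for unchanged Q/SG2/H cells
    eligible = ~changed & ((state == Q) | (state == SG2) | (state == H))
    stoch_changed = np.zeros(n, dtype=bool)
    if np.any(eligible):
        e = np.flatnonzero(eligible)
        probs = transition_probabilities(
            u_n[e], u_v[e], u_d[e], u_t[e], params, dt)
        u = rng.random(e.size)
        st = state[e]

        is_q = st == Q
        p1, p2 = probs["Q->SG2"], probs["Q->D"]
        go_sg2 = is_q & (u < p1)
        go_d = is_q & ~go_sg2 & (u < p1 + p2)
        state[e[go_sg2]] = SG2
        state[e[go_d]] = D

        is_sg2 = st == SG2
        p1, p2 = probs["SG2->SG2"], probs["SG2->D"]
        reset = is_sg2 & (u < p1)  # DOX interrupts DNA duplication
        die = is_sg2 & ~reset & (u < p1 + p2)
        state[e[die]] = D

        is_h = st == H
        h_die = is_h & (u < probs["H->D"])
        state[e[h_die]] = D

        any_change = go_sg2 | go_d | reset | die | h_die
        stoch_changed[e[any_change]] = True
        pop.clock[e[any_change]] = 0.0

    # advance clocks of unchanged, living cells
    untouched = ~changed & ~stoch_changed & (state != D)
    pop.clock[untouched] += dt

    if daughter_rows is not None:
        pop._append(*daughter_rows, state_code=G1, clock=0.0)
    return n_new


def step_cell(cell: TumorCell, concentrations, params: CellCycleParams,
              dt: float, rng: np.random.Generator
              ) -> tuple[TumorCell, Optional[TumorCell]]:
    """Single-cell wrapper over :func:`step_cells`.

    ``concentrations`` is a mapping with keys ``u_n, u_v, u_d, u_t``.
    Returns the updated cell and the daughter (or ``None``).  Dead cells are
    returned unchanged.
    """
    if cell.state == "D":
        return cell, None
    pop = CellPopulation.from_positions(
        cell.position[None, :], state=cell.state,
        r_nuclear=cell.r_nuclear, r_physical=cell.r_physical,
        r_action=cell.r_action)
    pop.ids[0] = cell.id
    pop.clock[0] = cell.clock
    step_cells(pop, concentrations["u_n"], concentrations["u_v"],
               concentrations["u_d"], concentrations["u_t"], params, dt, rng)
    updated = pop.as_cell(0)
    updated.id = cell.id
    daughter = pop.as_cell(1) if len(pop) > 1 else None
    return updated, daughter
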