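"""Discrete-continuum coupling and parameter-derivation utilities.

Agents enter the reaction-diffusion fields as regularized delta sources:
every living tumor cell deposits its coefficient onto the single nearest
lattice node (a product of Kronecker deltas); a cylindrical vessel agent is
reduced to m points along its center line, each carrying an equal share of
the lateral surface 2 pi r l (a line-delta), deposited the same way.

Sign conventions (right-hand sides of the substance equations):

* tumor cells are sinks for nutrients, DOX and TRA and sources of VEGF
  (hypoxic cells only; dead cells couple to nothing);
* vessels are sources of nutrients, DOX (scaled by the supply factor phi and
  gated by the DOX treatment window) and TRA (gated), and sinks for VEGF.

Also provided: the mass-scaled diffusion rule D ~ m^(-1/3) anchored at
glucose, half-life -> decay conversion, and the homogenized effective decay
lambda' = lambda + r * rho used to compare against exponential surrogates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cell_model import CellPopulation, H
from .vasculature import VesselAgent, VesselTree

#: reference molecular masses (g/mol)
MASS_GLUCOSE = 180.0
MASS_VEGF_MONOMER = 19.3e3
MASS_VEGF_DIMER = 38.6e3
MASS_DOX = 543.0
MASS_TRA = 145.0e3

#: nutrient (glucose) diffusion anchor, um^2/h
D_NUTRIENTS = 50.0


@dataclass
class CouplingParams:
    """Source/sink strengths: alphas per tumor cell (1/h), betas per unit of
    vessel lateral surface (1/(um^2 h))."""

    alpha_n: float = 0.1      # nutrient consumption per cell
    alpha_v: float = 0.1      # VEGF secretion per hypoxic cell
    alpha_d: float = 0.005    # DOX uptake per cell
    alpha_t: float = 0.005    # TRA uptake per cell
    beta_n: float = 1e-3      # nutrient supply per vessel surface
    beta_v: float = 1e-3      # VEGF removal per vessel surface
    beta_d: float = 1e-3      # DOX supply (treatment windows only)
    beta_t: float = 1e-3      # TRA supply (treatment windows only)

    def __post_init__(self) -> None:
        for name in ("alpha_n", "alpha_v", "alpha_d", "alpha_t",
                     "beta_n", "beta_v", "beta_d", "beta_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"coupling strength {name} must be >= 0")


@dataclass
class GridGeometry:
    """Shared lattice geometry for field assembly."""

    shape: tuple
    h: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.shape = tuple(int(s) for s in self.shape)

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.h * (np.array(self.shape) - 1)

    def nearest_nodes(self, points: np.ndarray,
                      what: str = "point") -> tuple[np.ndarray, ...]:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if np.any(pts < self.origin - 1e-9) or np.any(pts > self.upper + 1e-9):
            raise RuntimeError(f"{what} outside the continuum domain")
        q = (pts - self.origin) / self.h
        idx = np.ceil(q - 0.5).astype(np.int64)
        idx = np.clip(idx, 0, np.array(self.shape) - 1)
        return idx[:, 0], idx[:, 1], idx[:, 2]


def tumor_source_sink_fields(pop: CellPopulation, geom: GridGeometry,
                             params: CouplingParams) -> dict:
    """Assemble the tumor-cell contributions to all four substances.

    Returns ``{"A_minus_n", "A_minus_d", "A_minus_t", "A_plus_v"}``; every
    living cell adds alpha onto its nearest node, only hypoxic cells secrete
    VEGF, dead cells contribute nothing.  A living cell outside the domain is
    fatal (the mechanics step must have confined it).
    """
    sink_n = np.zeros(geom.shape)
    sink_d = np.zeros(geom.shape)
    sink_t = np.zeros(geom.shape)
    src_v = np.zeros(geom.shape)
    living = pop.living
    if np.any(living):
        idx = geom.nearest_nodes(pop.pos[living], what="living cell")
        np.add.at(sink_n, idx, params.alpha_n)
        np.add.at(sink_d, idx, params.alpha_d)
        np.add.at(sink_t, idx, params.alpha_t)
        hyp = (pop.state[living] == H)
        if np.any(hyp):
            hidx = tuple(a[hyp] for a in idx)
            np.add.at(src_v, hidx, params.alpha_v)
    return {"A_minus_n": sink_n, "A_minus_d": sink_d,
            "A_minus_t": sink_t, "A_plus_v": src_v}


def vessel_line_delta(agent: VesselAgent, h_min: float
                      ) -> list[tuple[np.ndarray, float]]:
    """Sample points and weights of the agent's line-delta.

    m = max(3, ceil(2 l / h_min + 1)) points at midpoint parameters
    (k - 1/2)/m along the center line, each carrying 2 pi r l / m (the
    lateral surface split evenly).  Zero-length agents yield no points.
    """
    length = agent.length
    if length <= 0:
        return []
    m = max(3, math.ceil(2.0 * length / h_min + 1.0))
    r = 0.5 * agent.diameter
    weight = 2.0 * math.pi * r * length / m
    chord = agent.end - agent.start
    return [(agent.start + ((k - 0.5) / m) * chord, weight)
            for k in range(1, m + 1)]


def vessel_line_delta_field(tree: VesselTree, geom: GridGeometry
                            ) -> np.ndarray:
    """Sum of all agents' line-deltas deposited on the lattice (surface-
    weighted; multiply by a beta to obtain a source/sink field)."""
    field = np.zeros(geom.shape)
    points, weights = [], []
    for agent in tree:
        for p, w in vessel_line_delta(agent, geom.h):
            points.append(p)
            weights.append(w)
    if points:
        idx = geom.nearest_nodes(np.array(points), what="vessel point")
        np.add.at(field, idx, np.array(weights))
    return field


def vessel_source_sink_fields(tree: VesselTree, geom: GridGeometry,
                              params: CouplingParams, phi: float,
                              dox_active: bool, tra_active: bool) -> dict:
    """Assemble the vessel contributions to all four substances.

    Nutrients are always supplied; the DOX source is scaled by the supply
    factor phi(t) >= 1 and active only inside DOX windows, the TRA source
    only inside TRA windows; VEGF is removed along all vessels.
    """
    if phi < 1.0:
        raise ValueError("supply factor phi must be >= 1")
    delta = vessel_line_delta_field(tree, geom)
    zero = np.zeros(geom.shape)
    return {
        "A_plus_n": params.beta_n * delta,
        "A_plus_d": phi * params.beta_d * delta if dox_active else zero,
        "A_plus_t": params.beta_t * delta if tra_active else zero.copy(),
        "A_minus_v": params.beta_v * delta,
    }


# ---- parameter derivations ----------------------------------------------

def scaled_diffusion(mass: float, ref_mass: float = MASS_GLUCOSE,
                     ref_D: float = D_NUTRIENTS) -> tuple[float, float]:
    """Mass-scaled diffusion coefficient via D ~ m^(-1/3).

    Returns (alpha, D) with alpha = mass / ref_mass and
    D = ref_D * alpha^(-1/3); anchored at glucose (180 g/mol, 50 um^2/h).
    """
    if mass <= 0 or ref_mass <= 0:
        raise ValueError("masses must be positive")
    alpha = mass / ref_mass
    return alpha, ref_D * alpha ** (-1.0 / 3.0)


def halflife_to_decay(half_life_hours: float) -> float:
    """Decay constant ln(2) / t_half in 1/h."""
    if half_life_hours <= 0:
        raise ValueError("half-life must be positive")
    return math.log(2.0) / half_life_hours


def effective_decay(lam: float, r: float, density: float) -> float:
    """Homogenized decay lambda' = lambda + r * rho.

    ``r`` is the consumed amount per cell and hour, ``rho`` the cell number
    density; used to compare the model against exponential surrogates.
    """
    if lam < 0 or r < 0 or density < 0:
        raise ValueError("arguments must be nonnegative")
    return lam + r * density


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero to ``ndigits`` (report convention)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def diffusion_table() -> list[dict]:
    """Mass ratios and scaled diffusion coefficients for the four substances
    (plus the VEGF dimer).

    Report convention: alpha rounded to an integer, the scale alpha^(-1/3) to
    two decimals, and the tabulated D as ref_D times the *rounded* scale (the
    two-step rounding used in the reference tabulation); ``D_rule`` carries
    the unrounded D = 50 alpha^(-1/3) that the simulator itself uses.
    """
    rows = []
    for name, mass in (("glucose (nutrients)", MASS_GLUCOSE),
                       ("VEGF (monomer)", MASS_VEGF_MONOMER),
                       ("VEGF (dimer)", MASS_VEGF_DIMER),
                       ("DOX", MASS_DOX),
                       ("TRA", MASS_TRA)):
        alpha, D = scaled_diffusion(mass)
        scale = round_half_away(alpha ** (-1.0 / 3.0), 2)
        rows.append({
            "substance": name,
            "mass_g_per_mol": mass,
            "alpha": round_half_away(alpha, 0),
            "alpha_scale": scale,
            "D_um2_per_h": round_half_away(D_NUTRIENTS * scale, 1),
            "D_rule": D,
        })
    return rows
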