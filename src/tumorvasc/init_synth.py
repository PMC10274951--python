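"""Initial-state construction: packed tumor spheroids and synthetic
vasculature.

The spheroid initializer places N cells uniformly in a ball whose radius
follows the random-close-packing relation r_spheroid = r_cell (N / 0.64)^(1/3)
(0.64 is the random close packing fraction of equal spheres).

The vasculature generator is an original, documented stand-in for a
data-derived capillary network: parent vessels are traced as bounded random
walks through the domain, chopped into ~10 um cylindrical agents with slowly
tapering diameters (5-20+ um), avoiding an empty exclusion ball around the
tumor seed; vessels are added until the total length density reaches a
target (within 20%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cell_model import CellPopulation, DEFAULT_R_PHYSICAL
from .vasculature import VesselTree

PACKING_FRACTION = 0.64


def spheroid_radius(n_cells: int, r_cell: float) -> float:
    """Radius of a randomly-close-packed spheroid of ``n_cells`` cells."""
    if n_cells < 1:
        raise ValueError("need at least one cell")
    if r_cell <= 0:
        raise ValueError("cell radius must be positive")
    return r_cell * (n_cells / PACKING_FRACTION) ** (1.0 / 3.0)


def place_spheroid(n_cells: int, r_cell: float, center,
                   rng: np.random.Generator) -> np.ndarray:
    """N positions uniformly random inside the packed-spheroid ball."""
    center = np.asarray(center, dtype=float)
    radius = spheroid_radius(n_cells, r_cell)
    dirs = rng.standard_normal((n_cells, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = radius * rng.random(n_cells) ** (1.0 / 3.0)
    return center + dirs * radii[:, None]


def make_spheroid_population(n_cells: int, center, state: str,
                             rng: np.random.Generator,
                             r_cell: float = DEFAULT_R_PHYSICAL
                             ) -> CellPopulation:
    """Packed spheroid as a cell population, all cells in ``state``
    (Q for nutrient-supplied starts, H for avascular/no-nutrient starts)."""
    positions = place_spheroid(n_cells, r_cell, center, rng)
    return CellPopulation.from_positions(positions, state=state)


@dataclass
class VasculatureGenSpec:
    """Specification for the synthetic initial vasculature.

    Lengths in micrometers.  ``target_length_density`` is total vessel length
    per domain volume (um/um^3); the generator adds vessels beyond
    ``n_parents`` until the achieved density is within 20% of the target.
    """

    domain_lo: tuple = (-200.0, -200.0, -200.0)
    domain_hi: tuple = (200.0, 200.0, 200.0)
    n_parents: int = 6
    parent_diameter_range: tuple = (10.0, 22.0)
    waviness: float = 0.15            # rms angular step per segment, rad
    exclusion_radius: float = 80.0    # empty ball around the tumor seed
    exclusion_center: tuple = (0.0, 0.0, 0.0)
    target_length_density: float = 5e-5
    segment_length: float = 10.0
    max_extra_vessels: int = 500

    def __post_init__(self) -> None:
        lo = np.asarray(self.domain_lo, dtype=float)
        hi = np.asarray(self.domain_hi, dtype=float)
        if np.any(hi <= lo):
            raise ValueError("domain_hi must exceed domain_lo")
        if self.exclusion_radius >= 0.5 * float(np.min(hi - lo)):
            raise ValueError("exclusion ball must fit inside the domain")
        if self.n_parents < 0 or self.segment_length <= 0:
            raise ValueError("invalid generator spec")
        if self.target_length_density < 0:
            raise ValueError("target length density must be >= 0")

    @property
    def domain_volume(self) -> float:
        lo = np.asarray(self.domain_lo, dtype=float)
        hi = np.asarray(self.domain_hi, dtype=float)
        return float(np.prod(hi - lo))


def _random_rotation_kick(direction: np.ndarray, sigma: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Perturb a unit direction by a small random angular step."""
    kick = rng.standard_normal(3) * sigma
    v = direction + kick
    n = np.linalg.norm(v)
    return v / n if n > 0 else direction


def _trace_parent(tree: VesselTree, spec: VasculatureGenSpec,
                  rng: np.random.Generator,
                  max_length: float = math.inf) -> float:
    """Trace one parent vessel as a random-walk chain of agents.

    Starts on a random domain face heading inward, steps ``segment_length``
    with angular waviness, stops on leaving the domain or reaching the
    exclusion ball.  Returns the traced length.
    """
    lo = np.asarray(spec.domain_lo, dtype=float)
    hi = np.asarray(spec.domain_hi, dtype=float)
    center = np.asarray(spec.exclusion_center, dtype=float)

    # entry point on a random face, slightly inset
    face = rng.integers(0, 6)
    axis, side = face // 2, face % 2
    pos = lo + rng.random(3) * (hi - lo)
    pos[axis] = lo[axis] + 1e-6 if side == 0 else hi[axis] - 1e-6
    direction = rng.standard_normal(3)
    direction[axis] = abs(direction[axis]) * (1.0 if side == 0 else -1.0)
    direction /= np.linalg.norm(direction)

    diameter = rng.uniform(*spec.parent_diameter_range)
    max_steps = int(4 * np.max(hi - lo) / spec.segment_length)
    mother = None
    traced = 0.0
    for _ in range(max_steps):
        if traced + spec.segment_length > max_length:
            break
        direction = _random_rotation_kick(direction, spec.waviness, rng)
        nxt = pos + spec.segment_length * direction
        if np.any(nxt < lo) or np.any(nxt > hi):
            break
        # keep the exclusion ball empty (segment endpoints and midpoint)
        mid = 0.5 * (pos + nxt)
        if (np.linalg.norm(nxt - center) < spec.exclusion_radius
                or np.linalg.norm(mid - center) < spec.exclusion_radius):
            break
        if mother is None:
            mother = tree.add_root(pos, nxt, diameter)
        else:
            if len(mother.daughter_ids) >= 1:
                break  # safety; chains are linear by construction
            mother = tree.add_daughter(mother, nxt, diameter)
        traced += spec.segment_length
        diameter = max(5.0, 0.98 * diameter)  # taper, no cap for parents
        pos = nxt
    return traced


def generate_vasculature(spec: VasculatureGenSpec,
                         rng: np.random.Generator) -> VesselTree:
    """Generate a synthetic forest of connected vessel chains.

    Traces ``n_parents`` random-walk vessels, then keeps adding vessels until
    the length density reaches at least 80% of the target (never knowingly
    exceeding 120%).  Zero parents with zero target yields an empty forest.
    """
    tree = VesselTree()
    target = spec.target_length_density * spec.domain_volume
    for _ in range(spec.n_parents):
        _trace_parent(tree, spec, rng)
    extra = 0
    while (target > 0 and tree.total_length() < 0.8 * target
           and extra < spec.max_extra_vessels):
        budget = 1.1 * target - tree.total_length()
        _trace_parent(tree, spec, rng, max_length=budget)
        extra += 1
    return tree
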