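"""Linked tree of cylindrical vessel agents and sprouting angiogenesis.

The vasculature is a forest of cylinder chains: every agent has at most one
mother and 0, 1 or 2 daughters (0 = tip cell, 1 = regular segment,
2 = branching point), with daughter.start_point == mother.end_point.

Angiogenesis rules:

* a regular segment (one mother, one daughter) may sprout a second daughter
  when the local VEGF exceeds a threshold, no tip cell lies within ``d_tip``
  of its midpoint, and the arc length along the vessel to the nearest
  branching point in both directions exceeds ``d_branch``; the sprout axis is
  drawn on a cone around the VEGF gradient and succeeds with probability
  ``p_s_rate * dt``;
* tip cells elongate at ``speed`` along the normalized direction
  w1 * grad(u_v) + w2 * axis + w3 * X3 (X3 ~ U(-1,1)^3), provided the
  gradient magnitude is at least ``g_min``; growth stops permanently once it
  reaches ``g_stop``; at length 10 um the cylinder is split into a 9 um
  segment plus a 1 um tip with a tapered diameter;
* diameters: branches take max(5, min(0.8 d0, 20)) um, tapering along a
  vessel takes max(5, min(0.98 d0, 20)) um.

Vessels are rigid and exert/receive no mechanical forces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

D_MIN = 5.0    # um, absolute lower diameter bound
D_MAX = 20.0   # um, cap for new microvasculature


def branch_diameter(d0: float) -> float:
    """Diameter of a new branch sprouting from a vessel of diameter d0."""
    if d0 <= 0:
        raise ValueError("diameter must be positive")
    return max(D_MIN, min(0.8 * d0, D_MAX))


def taper_diameter(d0: float) -> float:
    """Diameter after one tapering step along a growing vessel."""
    if d0 <= 0:
        raise ValueError("diameter must be positive")
    return max(D_MIN, min(0.98 * d0, D_MAX))


@dataclass
class AngiogenesisParams:
    """Tunable parameters of the sprouting rules (lengths um, times hours)."""

    u_v_threshold: float = 1e-3   # minimum VEGF to consider branching
    d_tip: float = 60.0           # minimum distance to the closest tip cell
    d_branch: float = 40.0        # minimum arc length between branch points
    p_s_rate: float = 0.04        # sprouting rate, 1/h (p_s = rate * dt << 1)
    w1: float = 100.0             # weight of the VEGF gradient
    w2: float = 0.5               # weight of the current axis (inertia)
    w3: float = 0.2               # weight of the random kick
    g_min: float = 1e-6           # minimum gradient magnitude for tip growth
    g_stop: float = 1e-2          # gradient magnitude that stops growth
    speed: float = 2.0            # tip extension rate, um/h
    split_length: float = 10.0    # cylinder length at which tips split, um
    sprout_length: float = 1.0    # initial sprout length, um
    cone_half_angle: float = math.radians(30.0)

    def __post_init__(self) -> None:
        for name in ("u_v_threshold", "d_tip", "d_branch", "p_s_rate",
                     "w1", "w2", "w3", "g_min", "g_stop", "speed",
                     "split_length", "sprout_length", "cone_half_angle"):
            if getattr(self, name) < 0:
                raise ValueError(f"angiogenesis parameter {name} must be >= 0")
        if self.w1 + self.w2 + self.w3 <= 0:
            raise ValueError("w1 + w2 + w3 must be positive")


@dataclass
class VesselAgent:
    """One cylindrical vessel segment in the linked tree."""

    id: int
    start: np.ndarray
    end: np.ndarray
    diameter: float
    mother_id: Optional[int] = None
    daughter_ids: list = field(default_factory=list)
    growth_stopped: bool = False  # set when a tip hits the g_stop criterion

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float).reshape(3)
        self.end = np.asarray(self.end, dtype=float).reshape(3)
        if self.diameter < D_MIN:
            raise ValueError(f"diameter {self.diameter} below {D_MIN} um")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def axis(self) -> np.ndarray:
        v = self.end - self.start
        n = np.linalg.norm(v)
        return v / n if n > 0 else np.zeros(3)

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @property
    def is_tip(self) -> bool:
        return len(self.daughter_ids) == 0

    @property
    def is_branch_point(self) -> bool:
        return len(self.daughter_ids) == 2


class VesselTree:
    """Forest of vessel agents with integrity auditing and text I/O."""

    def __init__(self) -> None:
        self.agents: dict[int, VesselAgent] = {}
        self._next_id = 0
        self.topology_version = 0  # bumped on any structural change

    def __len__(self) -> int:
        return len(self.agents)

    def __iter__(self):
        return iter(self.agents.values())

    def _new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def add_root(self, start, end, diameter: float) -> VesselAgent:
        agent = VesselAgent(self._new_id(), start, end, diameter)
        self.agents[agent.id] = agent
        self.topology_version += 1
        return agent

    def add_daughter(self, mother: VesselAgent, end,
                     diameter: float) -> VesselAgent:
        if len(mother.daughter_ids) >= 2:
            raise ValueError("branching points cannot take more daughters")
        agent = VesselAgent(self._new_id(), mother.end.copy(), end, diameter,
                            mother_id=mother.id)
        self.agents[agent.id] = agent
        mother.daughter_ids.append(agent.id)
        self.topology_version += 1
        return agent

    def tips(self) -> list[VesselAgent]:
        return [a for a in self.agents.values() if a.is_tip]

    def tip_endpoints(self) -> np.ndarray:
        tips = self.tips()
        if not tips:
            return np.empty((0, 3))
        return np.array([t.end for t in tips])

    def roots(self) -> list[VesselAgent]:
        return [a for a in self.agents.values() if a.mother_id is None]

    def total_length(self) -> float:
        return sum(a.length for a in self.agents.values())

    def total_lateral_surface(self) -> float:
        return sum(math.pi * a.diameter * a.length
                   for a in self.agents.values())

    def validate(self) -> None:
        """Full tree audit: references, connectivity, acyclicity, diameters."""
        for a in self.agents.values():
            if a.mother_id is not None:
                mother = self.agents.get(a.mother_id)
                if mother is None or a.id not in mother.daughter_ids:
                    raise AssertionError(f"broken mother link at agent {a.id}")
                if not np.allclose(a.start, mother.end):
                    raise AssertionError(
                        f"agent {a.id} start does not meet mother end")
            if len(a.daughter_ids) > 2:
                raise AssertionError(f"agent {a.id} has >2 daughters")
            for d in a.daughter_ids:
                dd = self.agents.get(d)
                if dd is None or dd.mother_id != a.id:
                    raise AssertionError(f"broken daughter link at {a.id}")
            if a.diameter < D_MIN - 1e-12:
                raise AssertionError(f"agent {a.id} diameter below minimum")
        # acyclicity: walking mothers must terminate
        for a in self.agents.values():
            seen = set()
            cur = a
            while cur.mother_id is not None:
                if cur.id in seen:
                    raise AssertionError("cycle detected in vessel tree")
                seen.add(cur.id)
                cur = self.agents[cur.mother_id]

    # ---- text I/O (round-trip exact) ------------------------------------

    HEADER = "id\tmother_id\tx_start\ty_start\tz_start\tx_end\ty_end\tz_end\tdiameter\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.HEADER)
            for a in sorted(self.agents.values(), key=lambda x: x.id):
                m = "" if a.mother_id is None else str(a.mother_id)
                nums = [*a.start, *a.end, a.diameter]
                cols = "\t".join(repr(float(v)) for v in nums)
                fh.write(f"{a.id}\t{m}\t{cols}\n")

    @classmethod
    def read(cls, path) -> "VesselTree":
        tree = cls()
        with open(path) as fh:
            header = fh.readline()
            if header != cls.HEADER:
                raise ValueError("unrecognized vessel-tree file header")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                aid = int(parts[0])
                mother = None if parts[1] == "" else int(parts[1])
                vals = [float(v) for v in parts[2:9]]
                agent = VesselAgent(aid, vals[0:3], vals[3:6], vals[6],
                                    mother_id=mother)
                tree.agents[aid] = agent
        for a in tree.agents.values():
            if a.mother_id is not None:
                tree.agents[a.mother_id].daughter_ids.append(a.id)
        for a in tree.agents.values():
            a.daughter_ids.sort()
        tree._next_id = max(tree.agents) + 1 if tree.agents else 0
        tree.topology_version += 1
        return tree


def nearest_tip_distance(point, tip_points: np.ndarray) -> float:
    """Exact minimum Euclidean distance from ``point`` to any tip endpoint.

    Returns +inf for an empty registry (an empty tip set never blocks
    branching).
    """
    tip_points = np.asarray(tip_points, dtype=float).reshape(-1, 3)
    if tip_points.shape[0] == 0:
        return math.inf
    d, _ = cKDTree(tip_points).query(np.asarray(point, dtype=float))
    return float(d)


def arc_lengths_to_branch_points(tree: VesselTree,
                                 agent: VesselAgent) -> tuple[float, float]:
    """(upstream, downstream) arc lengths from the agent's midpoint to the
    preceding and succeeding branching points.

    A branching point sits at the end point of an agent with two daughters.
    Walking off a tree end (root upstream, tip downstream) without meeting a
    branching point yields +inf: ends always satisfy the separation
    criterion.
    """
    # upstream: junction is the near end of the branching mother
    up = 0.5 * agent.length
    cur = agent
    while True:
        if cur.mother_id is None:
            up = math.inf
            break
        mother = tree.agents[cur.mother_id]
        if mother.is_branch_point:
            break
        up += mother.length
        cur = mother
    # downstream: junction is the far end of the branching descendant
    down = 0.5 * agent.length
    cur = agent
    while True:
        if cur.is_tip:
            down = math.inf
            break
        nxt = tree.agents[cur.daughter_ids[0]]
        down += nxt.length
        if nxt.is_branch_point:
            break
        if nxt.is_tip:
            down = math.inf
            break
        cur = nxt
    return up, down


def can_branch(agent: VesselAgent, u_v: float, tip_points: np.ndarray,
               tree: VesselTree, params: AngiogenesisParams) -> bool:
    """Branching candidacy of a regular segment (one mother, one daughter).

    Requires (i) local VEGF above threshold, (ii) the nearest tip farther
    than ``d_tip`` from the agent midpoint, and (iii) arc length to the
    preceding and succeeding branching points above ``d_branch``.  Tips,
    roots and branching points are never candidates.
    """
    if agent.mother_id is None or len(agent.daughter_ids) != 1:
        return False
    if u_v < params.u_v_threshold:
        return False
    if nearest_tip_distance(agent.midpoint, tip_points) <= params.d_tip:
        return False
    up, down = arc_lengths_to_branch_points(tree, agent)
    return up > params.d_branch and down > params.d_branch


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.zeros(3)


def sample_cone(axis: np.ndarray, half_angle: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit vector on the cone surface of ``half_angle`` around ``axis``
    (uniform azimuth); a zero axis falls back to the uniform sphere."""
    a = _unit(np.asarray(axis, dtype=float))
    if not np.any(a):
        v = rng.standard_normal(3)
        return _unit(v)
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(a[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(a, helper))
    e2 = np.cross(a, e1)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    return (math.cos(half_angle) * a
            + math.sin(half_angle) * (math.cos(phi) * e1 + math.sin(phi) * e2))


def try_sprout(agent: VesselAgent, grad_uv, tree: VesselTree,
               params: AngiogenesisParams, dt: float,
               rng: np.random.Generator) -> Optional[VesselAgent]:
    """Stochastic sprout initiation on a branching candidate.

    With probability ``p_s_rate * dt`` creates a second daughter tip of
    initial length ``sprout_length`` whose axis lies on a cone around the
    VEGF gradient, with diameter :func:`branch_diameter` of the parent.
    """
    p_s = params.p_s_rate * dt
    if rng.random() >= p_s:
        return None
    direction = sample_cone(np.asarray(grad_uv, dtype=float),
                            params.cone_half_angle, rng)
    end = agent.end + params.sprout_length * direction
    return tree.add_daughter(agent, end, branch_diameter(agent.diameter))


def grow_tip(tip: VesselAgent, grad_uv, tree: VesselTree,
             params: AngiogenesisParams, dt: float,
             rng: np.random.Generator) -> Optional[VesselAgent]:
    """Elongate a tip cell along the weighted growth direction.

    No-op below ``g_min`` gradient magnitude; permanently stops at
    ``g_stop``.  When the cylinder reaches ``split_length`` it is split into
    a 9 um proximal segment and a 1 um distal tip (no residual carried), the
    tip taking a tapered diameter.  Returns the new tip if a split occurred.
    """
    if not tip.is_tip:
        raise ValueError("grow_tip called on a non-tip agent")
    if tip.growth_stopped:
        return None
    grad = np.asarray(grad_uv, dtype=float)
    gmag = float(np.linalg.norm(grad))
    if gmag >= params.g_stop:
        tip.growth_stopped = True
        return None
    if gmag < params.g_min:
        return None
    x3 = rng.uniform(-1.0, 1.0, 3)
    direction = _unit(params.w1 * grad + params.w2 * tip.axis + params.w3 * x3)
    if not np.any(direction):
        return None
    tip.end = tip.end + params.speed * dt * direction
    if tip.length >= params.split_length:
        return _split_tip(tip, tree)
    return None


def _split_tip(tip: VesselAgent, tree: VesselTree) -> VesselAgent:
    """Split a full-length tip into a 9 um segment + 1 um tapered tip."""
    chord = tip.end - tip.start
    u = _unit(chord)
    proximal_len = 9.0
    distal_len = 1.0
    tip.end = tip.start + proximal_len * u
    new_end = tip.end + distal_len * u
    new_tip = tree.add_daughter(tip, new_end, taper_diameter(tip.diameter))
    new_tip.growth_stopped = tip.growth_stopped
    return new_tip
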