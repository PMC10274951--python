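"""Time-stepping orchestration of the hybrid model.

One agent step of length dt advances, in fixed order:

1. assemble the agent source/sink fields A+/A- from the current cells and
   vessels (treatment window flags and the supply factor phi evaluated at
   the step's start time);
2. advance each enabled substance by the required number of stable FTCS
   substeps (fields held fixed across substeps);
3. update the treatment supply state chi;
4. cell-cycle updates for all cells (sampling each substance at the nearest
   lattice node);
5. vessel branching and tip growth, unless past the shutoff day;
6. force computation and overdamped displacement, with reflection into the
   domain box;
7. per-cadence output of the state-count series.

Identical (config, seed) pairs produce identical outputs: a single RNG
stream is consumed in a fixed documented order (division directions, cell
draws, branching candidates by ascending id, tips by ascending id).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import __version__
from .cell_model import CellPopulation, step_cells
from .config import SimulationConfig, config_to_dict
from .continuum import SubstanceGrid
from .coupling import GridGeometry, tumor_source_sink_fields, vessel_line_delta
from .init_synth import generate_vasculature, make_spheroid_population
from .mechanics import apply_displacements, reflect_into_box, total_forces
from .treatment import phi as phi_of_chi, windows_active
from .vasculature import (VesselTree, arc_lengths_to_branch_points,
                          grow_tip, try_sprout)

PACKING_FRACTION = 0.64


@dataclass
class SimResult:
    """Outputs of a run: per-cadence series and the final state."""

    series: pd.DataFrame
    population: CellPopulation
    tree: VesselTree
    grids: dict
    config: SimulationConfig
    initial_max_vessel_id: int  # vessels with larger ids grew during the run

    def new_tip_positions(self) -> np.ndarray:
        """End points of tip cells created during the run."""
        pts = [a.end for a in self.tree
               if a.is_tip and a.id > self.initial_max_vessel_id]
        return np.array(pts) if pts else np.empty((0, 3))


class Simulation:
    """A fully assembled hybrid simulation (cells + vessels + fields)."""

    def __init__(self, config: SimulationConfig,
                 tree: VesselTree | None = None) -> None:
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        half = config.domain_edge / 2.0
        self.lo = np.array([-half, -half, -half])
        self.hi = np.array([half, half, half])
        shape = (config.grid_points,) * 3
        self.geom = GridGeometry(shape, config.grid_h, self.lo)

        self.grids: dict[str, SubstanceGrid] = {}
        for name, sc in config.substances.items():
            if not sc.enabled:
                continue
            self.grids[name] = SubstanceGrid(
                name, shape, config.grid_h, sc.D, sc.lam,
                bc=sc.bc_spec(), origin=self.lo, initial=sc.initial)

        if config.n_cells > 0:
            self.population = make_spheroid_population(
                config.n_cells, (0.0, 0.0, 0.0), config.initial_cell_state,
                self.rng)
        else:
            self.population = CellPopulation()
        if tree is not None:
            self.tree = tree
        elif config.vessel_file:
            self.tree = VesselTree.read(config.vessel_file)
        elif config.generate_vessels:
            self.tree = generate_vasculature(config.vasc_gen, self.rng)
        else:
            self.tree = VesselTree()
        self.initial_max_vessel_id = (max(self.tree.agents)
                                      if self.tree.agents else -1)
        self.treatment = config.treatment_state()
        self.t = 0.0
        self.step_count = 0
        self.records: list[dict] = []
        # caches for the (rigid) non-tip vessel delta field
        self._static_delta = None
        self._static_delta_version = -1
        self._candidate_cache = None
        self._candidate_version = -1
        self._record()

    # ---- field assembly --------------------------------------------------

    def _vessel_delta_field(self) -> np.ndarray:
        """Surface-weighted line-delta field of the whole tree.

        Non-tip agents are rigid, so their contribution is cached and only
        rebuilt when the topology changes; moving tips are re-deposited every
        step.
        """
        version = self.tree.topology_version
        if self._static_delta_version != version:
            static = np.zeros(self.geom.shape)
            pts, wts = [], []
            for agent in self.tree:
                if agent.is_tip:
                    continue
                for p, w in vessel_line_delta(agent, self.geom.h):
                    pts.append(p)
                    wts.append(w)
            if pts:
                idx = self.geom.nearest_nodes(np.array(pts), "vessel point")
                np.add.at(static, idx, np.array(wts))
            self._static_delta = static
            self._static_delta_version = version
        total = self._static_delta.copy()
        pts, wts = [], []
        for agent in self.tree.tips():
            for p, w in vessel_line_delta(agent, self.geom.h):
                pts.append(p)
                wts.append(w)
        if pts:
            idx = self.geom.nearest_nodes(np.array(pts), "vessel point")
            np.add.at(total, idx, np.array(wts))
        return total

    def _assemble_fields(self, dox_active: bool, tra_active: bool,
                         phi: float) -> dict:
        cp = self.config.coupling
        tumor = tumor_source_sink_fields(self.population, self.geom, cp)
        fields = {
            "nutrients": [None, tumor["A_minus_n"]],
            "VEGF": [tumor["A_plus_v"], None],
            "DOX": [None, tumor["A_minus_d"]],
            "TRA": [None, tumor["A_minus_t"]],
        }
        if len(self.tree):
            delta = self._vessel_delta_field()
            fields["nutrients"][0] = cp.beta_n * delta
            if self.config.vegf_vessel_sink:
                fields["VEGF"][1] = cp.beta_v * delta
            if dox_active:
                fields["DOX"][0] = phi * cp.beta_d * delta
            if tra_active:
                fields["TRA"][0] = cp.beta_t * delta
        return fields

    # ---- vessel updates ---------------------------------------------------

    def _branching_candidates(self):
        """(ids, midpoints) of regular segments, cached per topology."""
        version = self.tree.topology_version
        if self._candidate_version != version:
            ids, mids = [], []
            for aid in sorted(self.tree.agents):
                a = self.tree.agents[aid]
                if a.mother_id is not None and len(a.daughter_ids) == 1:
                    ids.append(aid)
                    mids.append(a.midpoint)
            arc_ok = {}
            params = self.config.angiogenesis
            for aid in ids:
                up, down = arc_lengths_to_branch_points(
                    self.tree, self.tree.agents[aid])
                arc_ok[aid] = (up > params.d_branch
                               and down > params.d_branch)
            self._candidate_cache = (
                np.array(ids, dtype=np.int64),
                np.array(mids).reshape(-1, 3), arc_ok)
            self._candidate_version = version
        return self._candidate_cache

    def _step_vessels(self) -> None:
        grid = self.grids.get("VEGF")
        if grid is None:
            return
        params = self.config.angiogenesis
        dt = self.config.dt

        # branching: criteria evaluated against the start-of-step snapshot
        ids, mids, arc_ok = self._branching_candidates()
        sprouted = []
        if ids.size:
            u_v = np.atleast_1d(grid.sample_at(mids))
            mask = u_v >= params.u_v_threshold
            if np.any(mask):
                tips = self.tree.tip_endpoints()
                if len(tips):
                    d, _ = cKDTree(tips).query(mids[mask])
                    far = np.atleast_1d(d) > params.d_tip
                else:
                    far = np.ones(int(mask.sum()), dtype=bool)
                cand = ids[mask][far]
                for aid in cand:
                    if not arc_ok[aid]:
                        continue
                    agent = self.tree.agents[aid]
                    grad = grid.gradient_at(agent.midpoint)
                    new = try_sprout(agent, grad, self.tree, params, dt,
                                     self.rng)
                    if new is not None:
                        np.clip(new.end, self.lo, self.hi, out=new.end)
                        sprouted.append(new.id)

        # tip growth (tips existing at the start of the step, ascending id)
        tip_ids = sorted(a.id for a in self.tree.tips()
                         if a.id not in sprouted)
        for tid in tip_ids:
            tip = self.tree.agents[tid]
            if not tip.is_tip:
                continue
            grad = grid.gradient_at(
                np.clip(tip.end, self.lo, self.hi))
            new = grow_tip(tip, grad, self.tree, params, dt, self.rng)
            # keep tips inside the domain (rigid vessels; clamp, no reflection)
            np.clip(tip.end, self.lo, self.hi, out=tip.end)
            if new is not None:
                # a split daughter starts where the (clamped) mother ends
                new.start = tip.end.copy()
                np.clip(new.end, self.lo, self.hi, out=new.end)

    # ---- cell updates -----------------------------------------------------

    def _sample(self, name: str) -> np.ndarray:
        n = len(self.population)
        grid = self.grids.get(name)
        if grid is None or n == 0:
            return np.zeros(n)
        return np.atleast_1d(grid.sample_at(self.population.pos))

    def step(self) -> None:
        cfg = self.config
        dt = cfg.dt

        # (1) treatment flags at step start + field assembly
        dox_active, tra_active = windows_active(self.t, self.treatment)
        phi = phi_of_chi(self.treatment.chi)
        fields = self._assemble_fields(dox_active, tra_active, phi)

        # (2) substance substeps
        for name, grid in self.grids.items():
            a_plus, a_minus = fields[name]
            grid.advance(a_plus, a_minus, dt)

        # (3) treatment supply state
        self.treatment.step(self.t, dt)

        # (4) cell cycle
        if len(self.population):
            u_n = self._sample("nutrients")
            u_v = self._sample("VEGF")
            u_d = self._sample("DOX")
            u_t = self._sample("TRA")
            step_cells(self.population, u_n, u_v, u_d, u_t,
                       cfg.cell_cycle, dt, self.rng)

        # (5) vessels
        shutoff = cfg.vessel_shutoff_day
        if (cfg.angiogenesis_enabled and len(self.tree)
                and (shutoff is None or self.t < shutoff * 24.0)):
            self._step_vessels()

        # (6) mechanics
        pop = self.population
        if len(pop) > 1:
            forces = total_forces(pop.pos, pop.r_p, pop.r_a, cfg.forces,
                                  self.rng)
            pop.pos = apply_displacements(pop.pos, forces, cfg.forces.eta, dt)
        if len(pop):
            pop.pos = reflect_into_box(pop.pos, self.lo, self.hi)

        self.t += dt
        self.step_count += 1

        # (7) output cadence
        if self.step_count % cfg.output_cadence_steps == 0:
            self._record()

    def _record(self) -> None:
        counts = self.population.counts()
        if counts["living"] + counts["D"] != counts["total"]:
            raise RuntimeError("cell accounting violated")
        r_p = (float(np.mean(self.population.nat_r_p))
               if len(self.population) else 0.0)
        v_cell = 4.0 / 3.0 * math.pi * r_p ** 3
        rec = {
            "t_hours": self.t,
            "day": self.t / 24.0,
            **{k: counts[k] for k in ("Q", "SG2", "G1", "H", "D",
                                      "living", "total")},
            "tumor_volume_um3": counts["total"] * v_cell / PACKING_FRACTION,
            "n_vessels": len(self.tree),
            "n_tips": len(self.tree.tips()),
            "vessel_length_um": self.tree.total_length(),
            "chi": self.treatment.chi,
        }
        living = self.population.living
        for name, grid in self.grids.items():
            rec[f"u_{name}_max"] = float(grid.values.max())
            if np.any(living):
                vals = np.atleast_1d(grid.sample_at(self.population.pos[living]))
                rec[f"u_{name}_cell_mean"] = float(vals.mean())
            else:
                rec[f"u_{name}_cell_mean"] = 0.0
        self.records.append(rec)

    def run(self) -> SimResult:
        n_steps = self.config.n_steps
        for _ in range(n_steps):
            self.step()
        return SimResult(
            series=pd.DataFrame(self.records),
            population=self.population,
            tree=self.tree,
            grids=self.grids,
            config=self.config,
            initial_max_vessel_id=self.initial_max_vessel_id,
        )


def run(config: SimulationConfig,
        tree: VesselTree | None = None) -> SimResult:
    """Run a simulation from a validated config (pure in (config, seed))."""
    return Simulation(config, tree=tree).run()


def write_outputs(result: SimResult, out_dir) -> None:
    """State series, final snapshots and a run manifest."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    result.series.to_csv(os.path.join(out_dir, "state_series.csv"),
                         index=False)
    result.population.write_snapshot(os.path.join(out_dir, "cells.csv"))
    result.tree.write(os.path.join(out_dir, "vessels.tsv"))
    for name, grid in result.grids.items():
        grid.write_snapshot(os.path.join(out_dir, f"field_{name}.npz"))
    cfg_dict = config_to_dict(result.config)
    blob = json.dumps(cfg_dict, sort_keys=True).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": result.config.seed,
        "code_version": __version__,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
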