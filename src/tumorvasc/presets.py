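"""Shipped scenario presets at desk scale.

Three families, mirroring the canonical computational experiments:

* ``spheroid`` — avascular spheroid growth under a Dirichlet nutrient supply
  (u_n = 0.5 at the boundary and initially); the hypoxic threshold selects
  the regime between "growth stops and the tumor dies off" (high threshold)
  and a persistent proliferative hull around a necrotic core (low threshold).
* ``angiogenesis`` — a hypoxic spheroid secreting VEGF into a surrounding
  synthetic vasculature; the VEGF vessel-sink coupling toggles between
  straight tumor-directed growth (off) and a diffuse tumor-surrounding
  network (on).
* ``treatment`` — the fully coupled model with a static supplying network
  and the four DOX/TRA protocol variants on three delivery slots.

The numeric choices here are the package's reference study conditions; see
docs/methods.md for the rationale.
"""

from __future__ import annotations

from .config import SimulationConfig, config_from_dict

#: hypoxic thresholds bracketing the two spheroid regimes at this scale
SPHEROID_SWEEP = (0.40, 0.05)

#: the three delivery slots (days) of the treatment scenarios
TREATMENT_SLOTS = ([8.0, 9.0], [10.0, 11.0], [12.0, 13.0])

#: drug assignment per slot for each protocol
TREATMENT_PROTOCOLS = {
    "untreated": {"dox_days": [], "tra_days": []},
    "dox_only": {"dox_days": list(TREATMENT_SLOTS), "tra_days": []},
    "tra_only": {"dox_days": [], "tra_days": list(TREATMENT_SLOTS)},
    "tra_dox": {"dox_days": [TREATMENT_SLOTS[2]],
                "tra_days": [TREATMENT_SLOTS[0], TREATMENT_SLOTS[1]]},
    "dox_tra": {"dox_days": [TREATMENT_SLOTS[0]],
                "tra_days": [TREATMENT_SLOTS[1], TREATMENT_SLOTS[2]]},
}


def spheroid_config(hypoxic_threshold: float = 0.40, seed: int = 0,
                    total_days: float = 30.0) -> SimulationConfig:
    """Avascular spheroid: 200 cells, 40^3 lattice, 6-minute steps,
    Dirichlet nutrient supply at 0.5."""
    return config_from_dict({
        "seed": seed,
        "domain_edge": 600.0,
        "grid_points": 40,
        "dt": 0.1,
        "total_days": total_days,
        "output_cadence_steps": 60,
        "n_cells": 200,
        "initial_cell_state": "Q",
        "angiogenesis_enabled": False,
        "substances": {
            "nutrients": {"bc": "dirichlet", "bc_value": 0.5,
                          "initial": 0.5},
            "VEGF": {"enabled": False},
            "DOX": {"enabled": False},
            "TRA": {"enabled": False},
        },
        "cell_cycle": {"u_n_hypoxic": hypoxic_threshold},
    })


def angiogenesis_config(vegf_vessel_sink: bool = True, seed: int = 0,
                        total_days: float = 7.0) -> SimulationConfig:
    """Sprouting angiogenesis toward a fixed hypoxic VEGF source.

    Cells start hypoxic with no nutrient field; their death rate is zeroed so
    the VEGF source stays constant and the two coupling variants differ only
    through the vessel sink term.
    """
    return config_from_dict({
        "seed": seed,
        "domain_edge": 400.0,
        "grid_points": 21,
        "dt": 0.25,
        "total_days": total_days,
        "output_cadence_steps": 48,
        "n_cells": 100,
        "initial_cell_state": "H",
        "generate_vessels": True,
        "angiogenesis_enabled": True,
        "vegf_vessel_sink": vegf_vessel_sink,
        "substances": {
            "nutrients": {"enabled": False},
            "VEGF": {"enabled": True},
            "DOX": {"enabled": False},
            "TRA": {"enabled": False},
        },
        "cell_cycle": {"r_H_D": 0.0},
        "coupling": {"alpha_v": 0.2, "beta_v": 2e-3},
        "angiogenesis": {
            "u_v_threshold": 5e-3,
            "d_tip": 40.0,
            "d_branch": 30.0,
            "p_s_rate": 0.08,
            "g_min": 1e-6,
            "g_stop": 5e-3,
            "speed": 6.0,
        },
        "vasc_gen": {
            "domain_lo": [-200.0, -200.0, -200.0],
            "domain_hi": [200.0, 200.0, 200.0],
            "n_parents": 8,
            "exclusion_radius": 90.0,
            "target_length_density": 4e-5,
        },
    })


def treatment_config(protocol: str = "untreated", seed: int = 0,
                     total_days: float = 16.0) -> SimulationConfig:
    """Vascularized tumor under one of the four DOX/TRA protocols.

    A static synthetic network supplies nutrients and delivers the drugs in
    three one-day slots; trastuzumab charges the DOX supply factor.
    """
    if protocol not in TREATMENT_PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; choose from "
                         f"{sorted(TREATMENT_PROTOCOLS)}")
    sched = TREATMENT_PROTOCOLS[protocol]
    return config_from_dict({
        "seed": seed,
        "domain_edge": 400.0,
        "grid_points": 21,
        "dt": 0.25,
        "total_days": total_days,
        "output_cadence_steps": 24,
        "n_cells": 100,
        "initial_cell_state": "Q",
        "generate_vessels": True,
        "angiogenesis_enabled": False,
        "substances": {
            "nutrients": {"initial": 0.5},
            "VEGF": {"enabled": False},
            "DOX": {"enabled": True},
            "TRA": {"enabled": True},
        },
        "cell_cycle": {"u_n_hypoxic": 0.05},
        "coupling": {"beta_n": 2e-3, "beta_d": 6e-3, "beta_t": 8e-3},
        "treatment": {**sched, "chi_max": 0.75, "tau_up": 12.0,
                      "tau_down": 48.0},
        "vasc_gen": {
            "domain_lo": [-200.0, -200.0, -200.0],
            "domain_hi": [200.0, 200.0, 200.0],
            "n_parents": 10,
            "exclusion_radius": 70.0,
            "target_length_density": 8e-5,
        },
    })


PRESETS = {
    "spheroid": lambda: spheroid_config(),
    "spheroid-high-threshold": lambda: spheroid_config(SPHEROID_SWEEP[0]),
    "spheroid-low-threshold": lambda: spheroid_config(SPHEROID_SWEEP[1]),
    "angiogenesis-coupled": lambda: angiogenesis_config(True),
    "angiogenesis-uncoupled": lambda: angiogenesis_config(False),
    **{f"treatment-{name}": (lambda n=name: treatment_config(n))
       for name in TREATMENT_PROTOCOLS},
}


def get_preset(name: str) -> SimulationConfig:
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from "
                         f"{sorted(PRESETS)}") from None
    return factory()
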