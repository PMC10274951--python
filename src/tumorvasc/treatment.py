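"""Treatment schedules and the TRA-induced DOX supply factor.

Trastuzumab normalizes the tumor vasculature and transiently improves drug
delivery.  The model captures this with a dimensionless supply state chi
obeying a capacitor-like ODE,

    dchi/dt = (chi_max - chi) / tau_up   while TRA is being delivered,
    dchi/dt = -chi / tau_down            otherwise,

integrated with explicit Euler and clamped to [0, chi_max].  The DOX vessel
source is multiplied by phi(t) = 1 + chi(t) >= 1.  chi never reads the DOX
state.  Treatment windows are half-open intervals [start, end) in simulation
hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def _validate_windows(windows, label: str) -> list[tuple[float, float]]:
    out = []
    prev_end = None
    for w in windows:
        start, end = float(w[0]), float(w[1])
        if end <= start:
            raise ValueError(f"{label} window {w} must have end > start")
        if prev_end is not None and start < prev_end:
            raise ValueError(f"{label} windows must be sorted, non-overlapping")
        prev_end = end
        out.append((start, end))
    return out


@dataclass
class TreatmentState:
    """Per-drug delivery windows plus the scalar supply state chi."""

    dox_windows: list = field(default_factory=list)   # [(start, end)] hours
    tra_windows: list = field(default_factory=list)
    chi: float = 0.0
    chi_max: float = 0.75      # ceiling (~75% extra DOX delivery)
    tau_up: float = 12.0       # charging time constant, h
    tau_down: float = 48.0     # discharging time constant, h

    def __post_init__(self) -> None:
        self.dox_windows = _validate_windows(self.dox_windows, "DOX")
        self.tra_windows = _validate_windows(self.tra_windows, "TRA")
        if not 0.0 <= self.chi <= self.chi_max:
            raise ValueError("chi must lie in [0, chi_max]")
        if self.tau_up <= 0 or self.tau_down <= 0:
            raise ValueError("time constants must be positive")

    def step(self, t: float, dt: float) -> tuple[bool, bool]:
        """Advance chi by one Euler step; returns (dox_active, tra_active)
        evaluated at time ``t``."""
        dox_active, tra_active = windows_active(t, self)
        self.chi = chi_step(self.chi, tra_active, self.tau_up, self.tau_down,
                            self.chi_max, dt)
        return dox_active, tra_active

    @property
    def phi(self) -> float:
        return phi(self.chi)


def chi_step(chi: float, tra_active: bool, tau_up: float, tau_down: float,
             chi_max: float, dt: float) -> float:
    """One explicit-Euler update of the supply state, clamped to
    [0, chi_max]."""
    if tau_up <= 0 or tau_down <= 0:
        raise ValueError("time constants must be positive")
    if not 0.0 <= chi <= chi_max:
        raise ValueError("chi out of [0, chi_max]")
    if tra_active:
        chi = chi + dt * (chi_max - chi) / tau_up
    else:
        chi = chi - dt * chi / tau_down
    return min(max(chi, 0.0), chi_max)


def phi(chi: float) -> float:
    """DOX supply factor phi = 1 + chi (always >= 1)."""
    if chi < 0:
        raise ValueError("chi must be nonnegative")
    return 1.0 + chi


def windows_active(t: float, state: TreatmentState) -> tuple[bool, bool]:
    """Half-open membership t in [start, end) per drug."""
    dox = any(s <= t < e for s, e in state.dox_windows)
    tra = any(s <= t < e for s, e in state.tra_windows)
    return dox, tra
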