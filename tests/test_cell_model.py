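import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorvasc.cell_model import (CellCycleParams, CellPopulation, TumorCell,
                                  STATE_CODES, linear_ramp, smoothed_heaviside,
                                  step_cell, step_cells,
                                  transition_probabilities)

ALLOWED_TRANSITIONS = {("Q", "SG2"), ("Q", "H"), ("Q", "D"),
                       ("SG2", "G1"), ("SG2", "D"),
                       ("G1", "Q"), ("H", "Q"), ("H", "D")}


# ---- smoothed Heaviside and linear ramp ---------------------------------

def test_smoothed_heaviside_half_rate_at_transition_point():
    # at x = xbar the logistic term is exactly 1/2 regardless of sharpness
    for b in (0.1, 1.0, 50.0):
        assert smoothed_heaviside(0.4, 0.0, b, 0.4, 1.0) == pytest.approx(
            1.0 - math.exp(-0.5), rel=1e-12)


def test_smoothed_heaviside_vanishes_above_sharp_transition():
    assert smoothed_heaviside(1.0, 0.0, 1e3, 0.5, 1.0) == pytest.approx(
        0.0, abs=1e-12)


def test_smoothed_heaviside_closed_form_value():
    # independent high-precision evaluation of
    # 1 - exp(-(0.1 + 1/(1 + exp(2*10*(0.2-0.5)))) * 0.5)
    expected = 0.4223364587828928  # frozen from extended-precision eval
    assert smoothed_heaviside(0.2, 0.1, 10.0, 0.5, 0.5) == pytest.approx(
        expected, rel=1e-12)


def test_smoothed_heaviside_rejects_out_of_domain():
    with pytest.raises(ValueError):
        smoothed_heaviside(1.2, 0.0, 1.0, 0.5, 1.0)
    with pytest.raises(ValueError):
        smoothed_heaviside(0.5, 0.0, 1.0, -0.1, 1.0)


def test_linear_ramp_zero_below_onset():
    for x in (0.0, 0.2, 0.4):
        assert linear_ramp(x, 5.0, 0.4, 2.0) == 0.0


def test_linear_ramp_full_rate_at_one():
    assert linear_ramp(1.0, 1.0, 0.0, 1.0) == pytest.approx(
        1.0 - math.exp(-1.0), rel=1e-12)


def test_linear_ramp_closed_form_value():
    # rate = 2 (0.7 - 0.4) / 0.6 = 1, probability = 1 - exp(-0.25)
    assert linear_ramp(0.7, 2.0, 0.4, 0.25) == pytest.approx(
        1.0 - math.exp(-0.25), rel=1e-12)


def test_linear_ramp_rejects_unit_onset():
    with pytest.raises(ValueError):
        linear_ramp(0.5, 1.0, 1.0, 1.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(x=st.floats(0, 1), a=st.floats(0, 5), b=st.floats(0, 100),
       xbar=st.floats(0, 1), c=st.floats(0, 10),
       xbar2=st.floats(0, 0.99), dt=st.floats(0, 10))
def test_rate_functions_yield_probabilities(x, a, b, xbar, c, xbar2, dt):
    s = smoothed_heaviside(x, a, b, xbar, dt)
    r = linear_ramp(x, c, xbar2, dt)
    # mathematically < 1; large rates round to 1.0 in double precision
    assert 0.0 <= s <= 1.0
    assert 0.0 <= r <= 1.0


def test_monotonicity_on_grid():
    # sigma non-increasing, rho non-decreasing in x
    xs = np.linspace(0.0, 1.0, 201)
    s = smoothed_heaviside(xs, 0.05, 20.0, 0.5, 1.0)
    r = linear_ramp(xs, 2.0, 0.3, 1.0)
    assert np.all(np.diff(s) <= 1e-15)
    assert np.all(np.diff(r) >= -1e-15)


# ---- transition probabilities -------------------------------------------

def test_transition_probabilities_reduce_without_drugs():
    p = CellCycleParams()
    dt = 1.0
    probs = transition_probabilities(0.5, 0.0, 0.0, 0.0, p, dt)
    bare = linear_ramp(0.5, p.c_Q_SG2, p.u_n_Q_SG2, dt)
    assert probs["Q->SG2"] == pytest.approx(bare, rel=1e-12)
    bare_d = smoothed_heaviside(0.5, p.a_Q_D, p.b_Q_D, p.u_n_Q_D, dt)
    assert probs["Q->D"] == pytest.approx(bare_d, rel=1e-12)
    assert probs["H->D"] == pytest.approx(p.r_H_D * dt, rel=1e-12)
    assert probs["SG2->SG2"] == 0.0


def test_tra_suppresses_proliferation():
    p = CellCycleParams(lambda_Q_SG2=500.0)
    probs = transition_probabilities(1.0, 0.0, 0.0, 1.0, p, 1.0)
    assert probs["Q->SG2"] == pytest.approx(0.0, abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(u_n=st.floats(0, 1), u_d=st.floats(0, 1), u_t=st.floats(0, 1),
       dt=st.floats(0.01, 10))
def test_all_transition_probabilities_clamped(u_n, u_d, u_t, dt):
    p = CellCycleParams()
    probs = transition_probabilities(u_n, 0.0, u_d, u_t, p, dt)
    for v in probs.values():
        assert 0.0 <= v <= 1.0


# ---- cell stepping -------------------------------------------------------

def _uniform_pop(n, state, rng, spacing=50.0):
    pos = rng.random((n, 3)) * spacing
    return CellPopulation.from_positions(pos, state=state)


def test_sg2_timer_divides_with_volume_conservation(rng):
    pop = _uniform_pop(1, "SG2", rng)
    pop.clock[:] = 10.0  # == T_SG2 default
    r0 = pop.r_p[0]
    vol0 = r0 ** 3
    step_cells(pop, 1.0, 0.0, 0.0, 0.0, CellCycleParams(), 0.1, rng)
    assert len(pop) == 2
    assert all(pop.state == STATE_CODES["G1"])
    assert pop.r_p[0] == pytest.approx(pop.r_p[1])
    # halved volume each, slightly regrown during the same G1 step
    assert pop.r_p[0] ** 3 <= vol0 / 2 * 1.05
    # daughter placed one physical radius away from the mother
    d = np.linalg.norm(pop.pos[1] - pop.pos[0])
    assert d == pytest.approx(pop.r_p[0], rel=1e-9)
    assert np.all(pop.clock[:2] == 0.0)


def test_g1_regrows_to_natural_size(rng):
    params = CellCycleParams()
    pop = _uniform_pop(1, "SG2", rng)
    pop.clock[:] = params.T_SG2
    step_cells(pop, 1.0, 0, 0, 0, params, 0.1, rng)
    for _ in range(int(params.T_G1 / 0.1) + 5):
        step_cells(pop, 1.0, 0, 0, 0, params, 0.1, rng)
    assert np.allclose(pop.r_p, pop.nat_r_p)
    assert np.allclose(pop.r_a, pop.nat_r_a)


def test_hypoxia_switch_is_deterministic(rng):
    params = CellCycleParams()
    eps = 1e-6
    pop = _uniform_pop(4, "Q", rng)
    step_cells(pop, params.u_n_hypoxic - eps, 0, 0, 0, params, 0.1, rng)
    assert all(pop.state == STATE_CODES["H"])
    step_cells(pop, params.u_n_hypoxic, 0, 0, 0, params, 0.1, rng)
    assert all(pop.state == STATE_CODES["Q"])


def test_dead_cells_are_absorbing(rng):
    pop = _uniform_pop(10, "D", rng)
    pop_pos = pop.pos.copy()
    for _ in range(50):
        step_cells(pop, 0.0, 0.0, 1.0, 1.0, CellCycleParams(), 1.0, rng)
    assert all(pop.state == STATE_CODES["D"])
    assert np.array_equal(pop.pos, pop_pos)


def test_only_allowed_transitions_occur(rng):
    params = CellCycleParams(r_H_D=0.2, a_Q_D=0.05, c_SG2_D=0.5,
                             u_n_SG2_D=0.1, T_SG2=2.0, T_G1=1.0)
    pop = _uniform_pop(200, "Q", rng)
    names = np.array(["Q", "SG2", "G1", "H", "D"])
    for step in range(60):
        u_n = rng.random()
        before = names[pop.state].copy()
        n0 = len(pop)
        step_cells(pop, u_n, 0.0, rng.random(), rng.random(), params,
                   1.0, rng)
        after = names[pop.state[:n0]]
        for s0, s1 in zip(before, after):
            if s0 != s1:
                assert (s0, s1) in ALLOWED_TRANSITIONS


def test_monte_carlo_frequency_matches_closed_form(rng):
    params = CellCycleParams()
    n = 10_000
    dt = 1.0
    u = (0.5, 0.0, 0.0, 0.0)
    pop = _uniform_pop(n, "Q", rng, spacing=2000.0)
    probs = transition_probabilities(*u, params, dt)
    step_cells(pop, *u, params, dt, rng)
    freq = np.count_nonzero(pop.state[:n] == STATE_CODES["SG2"]) / n
    p = float(probs["Q->SG2"])
    se = math.sqrt(p * (1 - p) / n)
    assert abs(freq - p) <= 3 * se


def test_hypoxic_mean_lifetime_matches_rate(rng):
    # with u_n = 0 every cell is hypoxic and dies at rate r; the mean
    # lifetime of the discrete process is dt/p with p = r dt
    params = CellCycleParams(r_H_D=0.02)
    n = 3000
    pop = _uniform_pop(n, "H", rng, spacing=2000.0)
    dt = 1.0
    death_step = np.full(n, -1.0)
    for step in range(1, 2000):
        alive_before = pop.state[:n] != STATE_CODES["D"]
        step_cells(pop, 0.0, 0.0, 0.0, 0.0, params, dt, rng)
        died = alive_before & (pop.state[:n] == STATE_CODES["D"])
        death_step[died] = step
        if not np.any(pop.state[:n] != STATE_CODES["D"]):
            break
    assert np.all(death_step > 0)
    mean_lifetime = death_step.mean() * dt
    p = params.r_H_D * dt
    expected = dt / p  # geometric mean waiting time
    se = expected / math.sqrt(n)  # geometric sd ~ mean for small p
    assert abs(mean_lifetime - expected) <= 3 * se


def test_population_grows_under_full_nutrients(rng):
    params = CellCycleParams()
    pop = _uniform_pop(50, "Q", rng, spacing=500.0)
    for _ in range(300):
        step_cells(pop, 1.0, 0.0, 0.0, 0.0, params, 1.0, rng)
    counts = pop.counts()
    assert counts["living"] > 50


def test_step_cell_single_interface(rng):
    cell = TumorCell(id=7, position=(0, 0, 0), state="SG2", clock=10.0)
    updated, daughter = step_cell(
        cell, {"u_n": 1.0, "u_v": 0.0, "u_d": 0.0, "u_t": 0.0},
        CellCycleParams(), 0.1, rng)
    assert updated.state == "G1" and daughter is not None
    dead = TumorCell(id=8, position=(0, 0, 0), state="D", clock=3.0)
    same, none = step_cell(dead, {"u_n": 0, "u_v": 0, "u_d": 1, "u_t": 1},
                           CellCycleParams(), 0.1, rng)
    assert same.state == "D" and none is None


def test_tumor_cell_invariants():
    with pytest.raises(ValueError):
        TumorCell(id=0, position=(0, 0, 0), r_nuclear=10.0, r_physical=5.0)
    with pytest.raises(ValueError):
        TumorCell(id=0, position=(0, 0, 0), state="X")
    with pytest.raises(ValueError):
        CellCycleParams(T_SG2=-1.0)
    with pytest.raises(ValueError):
        CellCycleParams(u_n_hypoxic=1.5)


def test_cell_cycle_has_twenty_parameters():
    import dataclasses

    assert len(dataclasses.fields(CellCycleParams)) == 20


def test_snapshot_writer_roundtrip(tmp_path, rng):
    pop = _uniform_pop(5, "Q", rng)
    path = tmp_path / "cells.csv"
    pop.write_snapshot(path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 6
    assert lines[0].startswith("id,x,y,z")
    first = lines[1].split(",")
    assert int(first[0]) == 0 and first[7] == "Q"
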