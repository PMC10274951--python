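import math

import numpy as np
import pytest

from tumorvasc.vasculature import (AngiogenesisParams, VesselTree,
                                   arc_lengths_to_branch_points,
                                   branch_diameter, can_branch, grow_tip,
                                   nearest_tip_distance, sample_cone,
                                   taper_diameter, try_sprout)


@pytest.mark.parametrize("d0,expected", [(30.0, 20.0), (4.0, 5.0),
                                         (10.0, 8.0)])
def test_branch_diameter(d0, expected):
    assert branch_diameter(d0) == pytest.approx(expected)


@pytest.mark.parametrize("d0,expected", [(25.0, 20.0), (5.0, 5.0),
                                         (10.0, 9.8)])
def test_taper_diameter(d0, expected):
    assert taper_diameter(d0) == pytest.approx(expected)


def _chain(tree, start, direction, n, length=10.0, diameter=10.0,
           mother=None):
    """Append a straight chain of n segments; returns the list of agents."""
    direction = np.asarray(direction, dtype=float)
    agents = []
    pos = np.asarray(start, dtype=float)
    for k in range(n):
        end = pos + length * direction
        if mother is None:
            mother = tree.add_root(pos, end, diameter)
        else:
            mother = tree.add_daughter(mother, end, diameter)
        agents.append(mother)
        pos = end
    return agents


def _branching_chain():
    """A branching point followed by ten collinear 10-um segments.

    The root gets two daughters (a one-segment stub and the chain head), so
    the root's end point is a branching point; the chain's last segment is a
    tip.
    """
    tree = VesselTree()
    root = tree.add_root((0, 0, -10.0), (0, 0, 0.0), 10.0)
    tree.add_daughter(root, (0, 10.0, 0.0), 10.0)  # stub -> root branches
    chain = _chain(tree, (0, 0, 0.0), (0, 0, 1.0), 10, mother=root)
    return tree, root, chain


def test_arc_length_walk_matches_hand_count():
    tree, root, chain = _branching_chain()
    tree.validate()
    # upstream distance from segment k's midpoint to the junction at the
    # root's end is (k-1)*10 + 5; downstream there is no branching point
    for k, agent in enumerate(chain, start=1):
        up, down = arc_lengths_to_branch_points(tree, agent)
        if agent.is_tip:
            continue
        assert up == pytest.approx((k - 1) * 10.0 + 5.0)
        assert down == math.inf


def test_can_branch_selects_segments_beyond_branch_distance():
    tree, root, chain = _branching_chain()
    params = AngiogenesisParams(u_v_threshold=0.1, d_tip=1.0, d_branch=45.0)
    tips = tree.tip_endpoints()
    expected_true = {6, 7, 8, 9}  # 10th is the tip, never a candidate
    got = {k for k, agent in enumerate(chain, start=1)
           if can_branch(agent, 0.5, tips, tree, params)}
    assert got == expected_true


def test_can_branch_requires_vegf_threshold():
    tree, root, chain = _branching_chain()
    params = AngiogenesisParams(u_v_threshold=0.1, d_tip=1.0, d_branch=0.0)
    tips = tree.tip_endpoints()
    assert not can_branch(chain[5], 0.0999, tips, tree, params)


def test_can_branch_empty_tip_set_passes():
    # isolated long chain, no branching points, no tips registered
    tree = VesselTree()
    chain = _chain(tree, (0, 0, 0), (1, 0, 0), 8)
    params = AngiogenesisParams(u_v_threshold=0.1, d_tip=1e9, d_branch=10.0)
    assert can_branch(chain[3], 0.5, np.empty((0, 3)), tree, params)


def test_tips_and_branch_points_never_candidates():
    tree, root, chain = _branching_chain()
    params = AngiogenesisParams(u_v_threshold=0.0, d_tip=0.0, d_branch=0.0)
    tips = tree.tip_endpoints()
    assert not can_branch(chain[-1], 1.0, tips, tree, params)  # tip
    assert not can_branch(root, 1.0, tips, tree, params)       # 2 daughters


def test_nearest_tip_distance(rng):
    assert nearest_tip_distance((0, 0, 0), np.empty((0, 3))) == math.inf
    assert nearest_tip_distance((0, 0, 0),
                                np.array([[100.0, 0, 0]])) == 100.0
    tips = rng.random((200, 3)) * 500.0
    point = rng.random(3) * 500.0
    brute = np.linalg.norm(tips - point, axis=1).min()
    assert nearest_tip_distance(point, tips) == pytest.approx(brute)


def test_sprout_rate_matches_bernoulli(rng):
    params = AngiogenesisParams(p_s_rate=0.08)
    dt = 0.25  # p_s = 0.02
    n, hits = 10_000, 0
    for _ in range(n):
        tree = VesselTree()
        chain = _chain(tree, (0, 0, 0), (1, 0, 0), 3)
        new = try_sprout(chain[1], np.array([0, 0, 1.0]), tree, params, dt,
                         rng)
        hits += new is not None
    p = params.p_s_rate * dt
    se = math.sqrt(p * (1 - p) / n)
    assert abs(hits / n - p) <= 3 * se


def test_sprout_never_with_zero_rate(rng):
    params = AngiogenesisParams(p_s_rate=0.0)
    tree = VesselTree()
    chain = _chain(tree, (0, 0, 0), (1, 0, 0), 3)
    for _ in range(200):
        assert try_sprout(chain[1], np.ones(3), tree, params, 1.0,
                          rng) is None


def test_degenerate_cone_is_parallel(rng):
    grad = np.array([1.0, 2.0, -0.5])
    axis = sample_cone(grad, 0.0, rng)
    assert np.allclose(axis, grad / np.linalg.norm(grad), atol=1e-12)
    # zero gradient falls back to a unit vector on the sphere
    v = sample_cone(np.zeros(3), 0.3, rng)
    assert np.linalg.norm(v) == pytest.approx(1.0)


def test_sprout_geometry_and_diameter(rng):
    params = AngiogenesisParams(p_s_rate=1e9, cone_half_angle=0.0)
    tree = VesselTree()
    chain = _chain(tree, (0, 0, 0), (1, 0, 0), 3, diameter=12.0)
    grad = np.array([0.0, 1.0, 0.0])
    new = try_sprout(chain[1], grad, tree, params, 1.0, rng)
    assert new is not None
    assert np.allclose(new.start, chain[1].end)
    assert new.length == pytest.approx(params.sprout_length)
    assert np.allclose(new.axis, grad)
    assert new.diameter == pytest.approx(branch_diameter(12.0))
    tree.validate()


def test_tip_growth_inertial_limit(rng):
    params = AngiogenesisParams(w1=0.0, w2=1.0, w3=0.0, speed=2.0,
                                g_min=1e-9, g_stop=1e9)
    tree = VesselTree()
    (tip,) = _chain(tree, (0, 0, 0), (1, 0, 0), 1, length=5.0)
    grad = np.array([0.0, 1e-3, 0.0])
    grow_tip(tip, grad, tree, params, 1.0, rng)
    assert np.allclose(tip.end, [7.0, 0, 0])  # straight along its axis


def test_tip_growth_follows_gradient(rng):
    params = AngiogenesisParams(w1=1.0, w2=0.0, w3=0.0, speed=2.0,
                                g_min=1e-9, g_stop=1e9)
    tree = VesselTree()
    (tip,) = _chain(tree, (0, 0, 0), (1, 0, 0), 1, length=2.0)
    grad = np.array([0.0, 2e-3, 0.0])
    for _ in range(3):
        grow_tip(tip, grad, tree, params, 1.0, rng)
    assert np.allclose(tip.end, [2.0, 6.0, 0.0])


def test_tip_splits_into_nine_plus_one(rng):
    params = AngiogenesisParams(w1=0.0, w2=1.0, w3=0.0, speed=1.0,
                                g_min=1e-9, g_stop=1e9)
    tree = VesselTree()
    (tip,) = _chain(tree, (0, 0, 0), (1, 0, 0), 1, length=9.5, diameter=10.0)
    new = grow_tip(tip, np.array([1e-3, 0, 0]), tree, params, 1.0, rng)
    assert new is not None
    assert tip.length == pytest.approx(9.0)
    assert new.length == pytest.approx(1.0)
    assert new.diameter == pytest.approx(taper_diameter(10.0))
    assert tip.daughter_ids == [new.id]
    tree.validate()


def test_tip_growth_gradient_thresholds(rng):
    params = AngiogenesisParams(w1=1.0, w2=0.0, w3=0.0, speed=2.0,
                                g_min=1e-4, g_stop=1e-2)
    tree = VesselTree()
    (tip,) = _chain(tree, (0, 0, 0), (1, 0, 0), 1, length=5.0)
    end0 = tip.end.copy()
    grow_tip(tip, np.array([1e-5, 0, 0]), tree, params, 1.0, rng)
    assert np.array_equal(tip.end, end0)  # below g_min: no-op
    grow_tip(tip, np.array([1.0, 0, 0]), tree, params, 1.0, rng)
    assert tip.growth_stopped and np.array_equal(tip.end, end0)
    # permanently stopped, even for moderate gradients afterwards
    grow_tip(tip, np.array([1e-3, 0, 0]), tree, params, 1.0, rng)
    assert np.array_equal(tip.end, end0)


def test_tree_roundtrip_is_exact(tmp_path, rng):
    tree = VesselTree()
    chain = _chain(tree, (0.1, -0.2, 0.3), rng.standard_normal(3), 5,
                   length=9.7, diameter=11.234567891234)
    tree.add_daughter(chain[2], chain[2].end + [1.5, 2.5, -3.5], 6.25)
    path = tmp_path / "vessels.tsv"
    tree.write(path)
    back = VesselTree.read(path)
    assert set(back.agents) == set(tree.agents)
    for aid, a in tree.agents.items():
        b = back.agents[aid]
        assert np.array_equal(a.start, b.start)
        assert np.array_equal(a.end, b.end)
        assert a.diameter == b.diameter
        assert a.mother_id == b.mother_id
        assert sorted(a.daughter_ids) == sorted(b.daughter_ids)
    back.validate()


def test_tree_audit_catches_broken_links():
    tree = VesselTree()
    chain = _chain(tree, (0, 0, 0), (1, 0, 0), 3)
    tree.validate()
    chain[1].mother_id = 99  # corrupt
    with pytest.raises(AssertionError):
        tree.validate()
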