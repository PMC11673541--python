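"""Tip-cell migration, branching law and anastomosis detection."""

from __future__ import annotations

import numpy as np
import pytest

from angiomesh.network import VascularNetwork
from angiomesh.rpim import RpimParams, VegfField, discretize_domain
from angiomesh.scenario import generate_cam_like_scenario
from angiomesh.sprouting import (
    HOURS_PER_ITERATION,
    SproutingParams,
    TipCell,
    branch_distance,
    detect_anastomosis,
    maybe_branch,
    migration_direction,
    run_angiogenesis,
    sample_branch_angle,
    step_tip,
)
from angiomesh.units import substream


def linear_field(slope_x=1.0, spacing=0.1):
    dom = discretize_domain((0, 0, 1, 1), spacing)
    return VegfField(domain=dom, nodal_values=slope_x * dom.node_coords[:, 0],
                     params=RpimParams())


def test_params_validation():
    with pytest.raises(ValueError):
        SproutingParams(theta_max=2.0)
    with pytest.raises(ValueError):
        SproutingParams(angle_same_mean=30.0)  # outside (45, 127)
    with pytest.raises(ValueError):
        SproutingParams(step_default=0.0)
    with pytest.raises(ValueError):
        SproutingParams(max_order=0)
    assert SproutingParams().snap_tolerance == pytest.approx(0.025)


def test_migration_direction_rotation():
    d = migration_direction((0.0, 2.0), 0.0)
    assert d == pytest.approx([0.0, 1.0])
    d = migration_direction((0.0, 2.0), np.pi / 2)
    assert d == pytest.approx([-1.0, 0.0], abs=1e-12)
    assert np.linalg.norm(migration_direction((3.0, 4.0), 0.7)) \
        == pytest.approx(1.0)


def test_migration_direction_zero_gradient_fallback():
    prev = np.array([0.6, 0.8])
    d = migration_direction((0.0, 0.0), 0.0, prev_direction=prev)
    assert d == pytest.approx(prev)
    assert migration_direction((0.0, 0.0), 0.0) is None


def test_branch_distance_law():
    p = SproutingParams()
    assert branch_distance(1, p) == pytest.approx(0.9286 * np.exp(-0.219))
    assert branch_distance(1, p) > branch_distance(2, p) > branch_distance(3, p)
    with pytest.raises(ValueError):
        branch_distance(0, p)


def test_sample_branch_angle_ranges_and_means():
    p = SproutingParams()
    rng = substream(99, "branching")
    same = np.array([sample_branch_angle(rng, p, True) for _ in range(400)])
    diff = np.array([sample_branch_angle(rng, p, False) for _ in range(400)])
    assert same.min() >= 45.0 and same.max() <= 127.0
    assert diff.min() >= 44.0 and diff.max() <= 117.0
    assert abs(same.mean() - 68.0) <= 2.0
    assert abs(diff.mean() - 86.0) <= 2.0


def _tip_on_network(x=0.5, y=0.5):
    net = VascularNetwork()
    nid = net.add_node(x, y)
    tip = TipCell(position=np.array([x, y]), prev_position=None, order=1,
                  diameter=0.05, attached_node=nid)
    return net, tip


def test_step_tip_moves_up_gradient_one_step():
    fld = linear_field()
    net, tip = _tip_on_network()
    p = SproutingParams(theta_max=1e-9)
    out = step_tip(tip, fld, net, p, substream(1, "migration"))
    assert out == "stepped"
    assert net.n_segments == 1 and net.n_nodes == 2
    # first step has length step_default, directed along +x (the gradient)
    assert np.linalg.norm(tip.position - [0.5, 0.5]) == pytest.approx(0.05, rel=1e-6)
    assert tip.position[0] > 0.5 + 0.04
    assert tip.dist_since_branch == pytest.approx(0.05, rel=1e-6)


def test_step_tip_snaps_to_nearby_node():
    fld = linear_field()
    net, tip = _tip_on_network()
    near = net.add_node(0.55, 0.5)  # within snap tolerance of the landing point
    p = SproutingParams(theta_max=1e-9)
    step_tip(tip, fld, net, p, substream(1, "migration"))
    assert tip.attached_node == near
    assert net.n_nodes == 2  # no new node created


def test_step_tip_deactivates_outside_domain():
    fld = linear_field()
    net, tip = _tip_on_network(x=0.98, y=0.5)
    p = SproutingParams(theta_max=1e-9)
    out = step_tip(tip, fld, net, p, substream(1, "migration"))
    assert out == "left-domain" and not tip.active
    assert net.n_segments == 0


def test_maybe_branch_creates_daughter_with_sampled_angle():
    net, tip = _tip_on_network()
    tip.prev_position = np.array([0.45, 0.5])  # moving along +x
    tip.dist_since_branch = 1.0  # beyond d(1) = 0.746
    p = SproutingParams()
    daughter = maybe_branch(tip, net, p, substream(3, "branching"))
    assert daughter is not None
    assert daughter.order == 2 and tip.order == 1
    assert tip.dist_since_branch == 0.0
    ev = net.branch_events[-1]
    assert not ev.same_order
    assert 44.0 <= ev.angle_deg <= 117.0
    # the daughter's first segment realises the sampled angle geometrically
    v = daughter.position - tip.position
    ang = np.degrees(np.arccos(np.clip(v @ [1.0, 0.0] / np.linalg.norm(v), -1, 1)))
    assert ang == pytest.approx(ev.angle_deg, abs=1e-9)
    assert daughter.diameter == pytest.approx(0.05 * p.daughter_diameter_factor)


def test_maybe_branch_caps_order_as_same_order():
    net, tip = _tip_on_network()
    tip.order = 3
    tip.prev_position = np.array([0.45, 0.5])
    tip.dist_since_branch = 1.0
    daughter = maybe_branch(tip, net, SproutingParams(), substream(4, "branching"))
    assert daughter.order == 3
    assert net.branch_events[-1].same_order
    assert daughter.diameter == tip.diameter


def test_maybe_branch_requires_distance():
    net, tip = _tip_on_network()
    tip.prev_position = np.array([0.45, 0.5])
    tip.dist_since_branch = 0.1
    assert maybe_branch(tip, net, SproutingParams(), substream(5, "b")) is None


def _trailed_tip(net, pts, diameter=0.05):
    """Build a chain of nodes along ``pts`` and a tip at the last one."""
    ids = [net.add_node(*p) for p in pts]
    sids = [net.add_segment(a, b, diameter, order=2)
            for a, b in zip(ids[:-1], ids[1:])]
    return TipCell(position=np.array(pts[-1], float), prev_position=np.array(pts[-2], float),
                   order=2, diameter=diameter, attached_node=ids[-1],
                   own_segments=sids)


def test_anastomosis_node_merge():
    net = VascularNetwork()
    target = net.add_node(0.0, 0.0)
    tip = _trailed_tip(net, [(1.0, 0.0), (0.5, 0.0), (0.02, 0.0)])
    events = detect_anastomosis(net, [tip], radius=0.025)
    assert [e["type"] for e in events] == ["node-merge"]
    assert events[0]["target"] == target
    assert not tip.active
    assert net.n_segments == 3  # connector added


def test_anastomosis_min_trail_blocks_young_tip():
    net = VascularNetwork()
    net.add_node(0.0, 0.0)
    ids = [net.add_node(0.5, 0.0), net.add_node(0.02, 0.0)]
    sid = net.add_segment(ids[0], ids[1], 0.05, order=2)
    tip = TipCell(position=np.array([0.02, 0.0]), prev_position=np.array([0.5, 0.0]),
                  order=2, diameter=0.05, attached_node=ids[1], own_segments=[sid])
    assert detect_anastomosis(net, [tip], radius=0.025) == []
    assert tip.active


def test_anastomosis_segment_split():
    net = VascularNetwork()
    f1 = net.add_node(0.0, -1.0)
    f2 = net.add_node(0.0, 1.0)
    net.add_segment(f1, f2, 0.08, order=1)
    tip = _trailed_tip(net, [(1.0, 0.3), (0.5, 0.3), (0.02, 0.3)])
    n_before = net.n_segments
    events = detect_anastomosis(net, [tip], radius=0.025)
    assert [e["type"] for e in events] == ["segment-merge"]
    assert not tip.active
    # split replaces 1 segment by 2 and adds the connector
    assert net.n_segments == n_before + 2
    junction = events[0]["target"]
    assert net.node_position(junction) == pytest.approx([0.0, 0.3])
    assert net.g.nodes[junction]["kind"] == "junction"


def test_anastomosis_head_on_deactivates_both():
    net = VascularNetwork()
    tip_a = _trailed_tip(net, [(-1.0, 0.0), (-0.5, 0.0), (-0.01, 0.0)])
    tip_b = _trailed_tip(net, [(1.0, 0.1), (0.5, 0.1), (0.01, 0.0)])
    events = detect_anastomosis(net, [tip_a, tip_b], radius=0.025)
    types = sorted(e["type"] for e in events)
    assert types == ["head-on", "node-merge"]
    assert not tip_a.active and not tip_b.active


def test_anastomosis_rejects_bad_radius():
    with pytest.raises(ValueError):
        detect_anastomosis(VascularNetwork(), [], radius=0.0)


def test_run_angiogenesis_small_scenario():
    sc = generate_cam_like_scenario(5, n_tips=3, spacing=0.25)
    net, log = run_angiogenesis(sc, n_steps=4, seed=sc.seed)
    assert len(log) == 4
    assert log[0]["hours"] == pytest.approx(HOURS_PER_ITERATION)
    assert log[-1]["n_segments"] == net.n_segments
    assert net.n_segments > 20  # parent discretization + 3 tips x 4 steps
    assert net.bounds_check(sc.bounds)
    for key in ("iteration", "active_tips", "n_branches", "n_merges",
                "boundary_exits"):
        assert key in log[0]
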