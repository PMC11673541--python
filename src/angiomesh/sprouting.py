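"""Agent-based tip-cell migration, branching and anastomosis.

Tip cells climb the VEGF gradient: at each iteration a tip's direction is
the normalised field gradient rotated by a uniform random perturbation
theta in [-theta_max, theta_max] radians, and the step length equals the
distance between its current and previous positions (bootstrapped by
``step_default`` on the first step, so effectively one endothelial-cell
length per iteration; one iteration corresponds to ~6.7 h).

Branching follows the capillary-order rule: a new branch forms once the
distance travelled since the last branch exceeds

    d(O) = 0.9286 * exp(-0.219 * O)   [mm]

for capillary order O (1 = highest calibre).  The daughter increases its
order (capped at ``max_order``) while the parent keeps its own; branch
angles are drawn from CAM-calibrated distributions (mean 68 deg between
same-order capillaries, 86 deg across orders, clipped to the measured
ranges).  Anastomosis merges a tip into any nearby foreign node or segment
and deactivates it, closing perfusable loops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Sequence

import numpy as np

from angiomesh.network import BranchEvent, VascularNetwork
from angiomesh.rpim import (
    DiffusionProblem,
    RpimParams,
    ShapeCache,
    VegfField,
    assemble_system,
    build_integration_mesh,
    discretize_domain,
    solve_vegf,
)
from angiomesh.units import substream

#: Simulated duration of one growth iteration (hours).
HOURS_PER_ITERATION = 6.7


@dataclass(frozen=True)
class SproutingParams:
    """Calibrated migration and branching parameters.

    Angles are in degrees, lengths in mm, ``theta_max`` in radians.
    ``branch_a``/``branch_b`` parameterise the inter-branch distance law;
    the four angle fields hold the CAM-measured means and ranges.
    """

    theta_max: float = 0.24
    branch_a: float = 0.9286
    branch_b: float = 0.219
    angle_same_mean: float = 68.0
    angle_same_range: tuple[float, float] = (45.0, 127.0)
    angle_diff_mean: float = 86.0
    angle_diff_range: tuple[float, float] = (44.0, 117.0)
    step_default: float = 0.05
    anastomosis_radius: float = 0.025
    max_order: int = 3
    daughter_diameter_factor: float = 0.8
    min_diameter: float = 0.01
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.theta_max < math.pi / 2:
            raise ValueError("theta_max must lie in (0, pi/2) radians")
        for lo_hi, mean, name in (
            (self.angle_same_range, self.angle_same_mean, "same-order"),
            (self.angle_diff_range, self.angle_diff_mean, "cross-order"),
        ):
            if not lo_hi[0] <= mean <= lo_hi[1]:
                raise ValueError(f"{name} angle range must contain its mean")
        if not (self.branch_a > 0 and self.step_default > 0 and self.anastomosis_radius > 0):
            raise ValueError("branch_a, step_default and anastomosis_radius must be positive")
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")

    @property
    def snap_tolerance(self) -> float:
        return self.step_default / 2.0


@dataclass
class TipCell:
    """Migrating leading cell of one sprout."""

    position: np.ndarray
    prev_position: Optional[np.ndarray]
    order: int
    diameter: float
    attached_node: int
    dist_since_branch: float = 0.0
    active: bool = True
    prev_direction: Optional[np.ndarray] = None
    own_segments: list[int] = dc_field(default_factory=list)


def migration_direction(
    gradient: Sequence[float],
    theta: float,
    prev_direction: Optional[np.ndarray] = None,
) -> Optional[np.ndarray]:
    """Unit migration direction: normalised gradient rotated by ``theta``.

    A (numerically) zero gradient falls back to the previous direction;
    with no previous direction available, returns ``None`` (caller
    deactivates the tip).
    """
    g = np.asarray(gradient, dtype=float)
    norm = np.linalg.norm(g)
    if norm < 1e-300 or not np.isfinite(norm):
        if prev_direction is None:
            return None
        g, norm = np.asarray(prev_direction, float), float(np.linalg.norm(prev_direction))
        if norm == 0:
            return None
    u = g / norm
    c, s = math.cos(theta), math.sin(theta)
    return np.array([c * u[0] - s * u[1], s * u[0] + c * u[1]])


def _rotate_deg(direction: np.ndarray, angle_deg: float) -> np.ndarray:
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([c * direction[0] - s * direction[1],
                     s * direction[0] + c * direction[1]])


def branch_distance(order: int, params: SproutingParams) -> float:
    """Inter-branch distance d = a * exp(-b * order) in mm (decreasing in order)."""
    if order < 1:
        raise ValueError("capillary order must be >= 1")
    return params.branch_a * math.exp(-params.branch_b * order)


def sample_branch_angle(rng: np.random.Generator, params: SproutingParams,
                        same_order: bool) -> float:
    """Draw a branch-angle magnitude (degrees) from the calibrated law.

    Angles are normal around the measured mean with sigma set so the nearer
    measured extreme sits three sigma away, then clipped to the measured
    range; the clipping is far enough out that the sample mean recovers the
    calibration mean.
    """
    if same_order:
        mean, (lo, hi) = params.angle_same_mean, params.angle_same_range
    else:
        mean, (lo, hi) = params.angle_diff_mean, params.angle_diff_range
    sigma = min(mean - lo, hi - mean) / 3.0
    return float(np.clip(rng.normal(mean, sigma), lo, hi))


def step_tip(
    tip: TipCell,
    fld: VegfField,
    network: VascularNetwork,
    params: SproutingParams,
    rng: np.random.Generator,
    generation: int = 0,
) -> Optional[str]:
    """Advance one active tip a single step up the perturbed VEGF gradient.

    The step length is the distance between the tip's current and previous
    positions (``step_default`` on the first step).  If the new position is
    within the snap tolerance of an existing network node that node is
    adopted; otherwise a new node and segment are created.  A tip stepping
    outside the domain is deactivated and the event reported.
    """
    if not tip.active:
        return None
    grad = fld.gradient(tip.position)
    theta = rng.uniform(-params.theta_max, params.theta_max)
    direction = migration_direction(grad, theta, tip.prev_direction)
    if direction is None:
        tip.active = False
        return "zero-gradient"
    if tip.prev_position is None:
        step_len = params.step_default
    else:
        step_len = float(np.linalg.norm(tip.position - tip.prev_position))
        if step_len == 0.0:
            step_len = params.step_default
    new_pos = tip.position + step_len * direction
    if not fld.domain.contains(new_pos):
        tip.active = False
        return "left-domain"
    exclude = {tip.attached_node}
    if tip.own_segments:
        try:  # the trailing segment may have been split by an anastomosis
            a, b, _ = network.segment_by_id(tip.own_segments[-1])
            exclude |= {a, b}
        except KeyError:
            pass
    target, dist = network.nearest_node(new_pos, exclude=exclude)
    if target is not None and dist <= params.snap_tolerance:
        node_id = target
        new_pos = network.node_position(target)
    else:
        node_id = network.add_node(new_pos[0], new_pos[1], kind="sprout")
    sid = network.add_segment(tip.attached_node, node_id, tip.diameter,
                              tip.order, generation=generation)
    tip.own_segments.append(sid)
    tip.prev_position = tip.position
    tip.prev_direction = direction
    tip.position = np.asarray(new_pos, float)
    tip.attached_node = node_id
    tip.dist_since_branch += step_len
    return "stepped"


def maybe_branch(
    tip: TipCell,
    network: VascularNetwork,
    params: SproutingParams,
    rng: np.random.Generator,
    bounds: Optional[tuple[float, float, float, float]] = None,
    generation: int = 0,
) -> Optional[TipCell]:
    """Create a daughter tip if the distance since the last branch exceeds d.

    Branching is strict (``dist_since_branch > d``).  The daughter order is
    the parent's plus one, capped at ``max_order`` (in which case the
    same-order angle calibration applies); its first segment is laid
    immediately along the sampled branch direction so the junction geometry
    carries the sampled angle, and the parent's distance counter resets.
    """
    if not tip.active:
        return None
    if not tip.dist_since_branch > branch_distance(tip.order, params):
        return None
    if tip.prev_position is None:
        return None
    parent_dir = tip.position - tip.prev_position
    n = np.linalg.norm(parent_dir)
    if n == 0:
        return None
    parent_dir = parent_dir / n
    daughter_order = min(tip.order + 1, params.max_order)
    same_order = daughter_order == tip.order
    angle = sample_branch_angle(rng, params, same_order)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    d_dir = _rotate_deg(parent_dir, sign * angle)
    d_pos = tip.position + params.step_default * d_dir
    if bounds is not None:
        xmin, ymin, xmax, ymax = bounds
        if not (xmin <= d_pos[0] <= xmax and ymin <= d_pos[1] <= ymax):
            return None
    if same_order:
        d_diam = tip.diameter
    else:
        d_diam = max(tip.diameter * params.daughter_diameter_factor, params.min_diameter)
    node_id = network.add_node(d_pos[0], d_pos[1], kind="sprout")
    sid = network.add_segment(tip.attached_node, node_id, d_diam,
                              daughter_order, generation=generation)
    network.branch_events.append(BranchEvent(
        parent_order=tip.order, daughter_order=daughter_order,
        angle_deg=angle, node_id=tip.attached_node, same_order=same_order))
    tip.dist_since_branch = 0.0
    daughter = TipCell(
        position=d_pos.copy(), prev_position=tip.position.copy(),
        order=daughter_order, diameter=d_diam, attached_node=node_id,
        prev_direction=d_dir, own_segments=[sid],
    )
    return daughter


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray
                            ) -> tuple[float, float]:
    """(distance, parameter t in [0,1]) from point ``p`` to segment ``ab``."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return float(np.linalg.norm(p - a)), 0.0
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    proj = a + t * ab
    return float(np.linalg.norm(p - proj)), t


def detect_anastomosis(
    network: VascularNetwork,
    tips: list[TipCell],
    radius: float,
    generation: int = 0,
    min_trail: int = 2,
) -> list[dict]:
    """Merge tips into nearby foreign structure and deactivate them.

    A tip within ``radius`` of a node or segment that is not part of its
    own recent trail (its last two own segments and their nodes) is
    connected there: node hits gain a connecting segment; segment-interior
    hits split the segment at the projection point.  When two tips merge
    head-on both are deactivated.  A tip younger than ``min_trail`` own
    segments does not fuse yet: a nascent sprout (one step from the vessel
    or branch point it just left) must elongate before it can anastomose.
    """
    if not radius > 0:
        raise ValueError("anastomosis radius must be positive")
    events: list[dict] = []
    tip_by_node = {t.attached_node: t for t in tips if t.active}
    for tip in tips:
        if not tip.active or len(tip.own_segments) < min_trail:
            continue
        excl_nodes = {tip.attached_node}
        excl_segs = set(tip.own_segments[-2:])
        for sid in tip.own_segments[-2:]:
            try:  # own segments may have been split by an earlier merge
                a, b, _ = network.segment_by_id(sid)
                excl_nodes |= {a, b}
            except KeyError:
                continue
        # nearest foreign node
        best_node, best_nd = None, np.inf
        for nid in network.node_ids():
            if nid in excl_nodes:
                continue
            d = float(np.linalg.norm(network.node_position(nid) - tip.position))
            if d < best_nd:
                best_node, best_nd = nid, d
        if best_node is not None and best_nd <= radius:
            network.add_segment(tip.attached_node, best_node, tip.diameter,
                                tip.order, generation=generation)
            tip.active = False
            events.append({"type": "node-merge", "tip_node": tip.attached_node,
                           "target": best_node})
            other = tip_by_node.get(best_node)
            if other is not None and other is not tip:
                other.active = False
                events.append({"type": "head-on", "tip_node": best_node,
                               "target": tip.attached_node})
            continue
        # nearest foreign segment interior
        best_sid, best_sd, best_t = None, np.inf, 0.0
        for sid, a, b, d in network.segments():
            if sid in excl_segs or a in excl_nodes or b in excl_nodes:
                continue
            dist, t = _point_segment_distance(
                tip.position, network.node_position(a), network.node_position(b))
            if dist < best_sd:
                best_sid, best_sd, best_t = sid, dist, t
        if best_sid is not None and best_sd <= radius:
            a, b, _ = network.segment_by_id(best_sid)
            pa, pb = network.node_position(a), network.node_position(b)
            if best_t <= 1e-9 or best_t >= 1 - 1e-9:
                target = a if best_t <= 0.5 else b
            else:
                target = network.split_segment(best_sid, pa + best_t * (pb - pa))
            network.add_segment(tip.attached_node, target, tip.diameter,
                                tip.order, generation=generation)
            tip.active = False
            events.append({"type": "segment-merge", "tip_node": tip.attached_node,
                           "target": target})
    return events


def build_parent_network(parent_vessels, node_spacing: float = 0.25) -> VascularNetwork:
    """Discretize parent-vessel polylines into a network of parent segments.

    Terminal nodes carry the artery/vein pressure-boundary tags of their
    vessel; interior nodes are plain parent nodes.
    """
    net = VascularNetwork()
    for pv in parent_vessels:
        poly = np.asarray(pv.polyline, dtype=float)
        pts = [poly[0]]
        for i in range(len(poly) - 1):
            seg = poly[i + 1] - poly[i]
            L = np.linalg.norm(seg)
            n = max(int(math.ceil(L / node_spacing)), 1)
            for k in range(1, n + 1):
                pts.append(poly[i] + seg * (k / n))
        ids = []
        for j, p in enumerate(pts):
            bc = None
            if j == 0:
                bc = pv.start_bc
            elif j == len(pts) - 1:
                bc = pv.end_bc
            ids.append(net.add_node(p[0], p[1], kind="parent", bc=bc))
        for a, b in zip(ids[:-1], ids[1:]):
            net.add_segment(a, b, pv.diameter, order=1, generation=0, parent=True)
    return net


def run_angiogenesis(scenario, n_steps: int, seed: Optional[int] = None
                     ) -> tuple[VascularNetwork, list[dict]]:
    """Grow a capillary network on a scenario for ``n_steps`` iterations.

    Per iteration: the VEGF field is re-solved with all sprout/junction
    nodes inserted into the meshless node cloud, every active tip advances
    one step and may branch, and anastomoses are detected.  The log records
    simulated hours (6.7 h per iteration), tip counts and merge events.
    Growth stops early once no tip is active.
    """
    if seed is None:
        seed = scenario.seed
    rng_mig = substream(seed, "migration")
    rng_branch = substream(seed, "branching")
    sp = scenario.sprouting
    rp = scenario.rpim

    network = build_parent_network(scenario.parent_vessels)
    base = discretize_domain(scenario.bounds, scenario.spacing)
    build_integration_mesh(base, gauss_order=rp.gauss_order)
    bc_ids = scenario.vegf_bc_node_ids(base)
    problem = scenario.vegf_problem()
    cache = ShapeCache()

    tips: list[TipCell] = []
    for (x, y, order) in scenario.initial_tips:
        nid, _ = network.nearest_node((x, y))
        pos = network.node_position(nid)
        diam = scenario.parent_vessels[0].diameter * sp.daughter_diameter_factor
        tips.append(TipCell(position=pos, prev_position=None, order=int(order),
                            diameter=max(diam, sp.min_diameter), attached_node=nid))

    log: list[dict] = []
    extra_accepted: list[np.ndarray] = []
    seen_nodes = -1
    min_sep = scenario.spacing * 0.05

    for it in range(1, n_steps + 1):
        # sprout/junction nodes join the meshless cloud (deduplicated)
        for nid in network.node_ids():
            if nid <= seen_nodes:
                continue
            if network.g.nodes[nid]["kind"] == "parent":
                continue
            p = network.node_position(nid)
            d_base, _ = base.tree.query(p)
            ok = d_base > min_sep
            if ok and extra_accepted:
                dmin = min(float(np.linalg.norm(p - q)) for q in extra_accepted)
                ok = dmin > min_sep
            if ok:
                extra_accepted.append(p)
        seen_nodes = network._next_node - 1
        dom = base.with_extra_nodes(np.array(extra_accepted)) if extra_accepted else base
        system = assemble_system(problem, dom, rp, cache=cache)
        fld = solve_vegf(system, [(bc_ids, scenario.vegf_bc_value)])

        boundary_exits = 0
        new_tips: list[TipCell] = []
        for tip in tips:
            outcome = step_tip(tip, fld, network, sp, rng_mig, generation=it)
            if outcome == "left-domain":
                boundary_exits += 1
            daughter = maybe_branch(tip, network, sp, rng_branch,
                                    bounds=scenario.bounds, generation=it)
            if daughter is not None:
                new_tips.append(daughter)
        tips.extend(new_tips)
        merges = detect_anastomosis(network, tips, sp.anastomosis_radius, generation=it)
        n_active = sum(t.active for t in tips)
        log.append({
            "iteration": it,
            "hours": HOURS_PER_ITERATION * it,
            "active_tips": n_active,
            "n_nodes": network.n_nodes,
            "n_segments": network.n_segments,
            "n_branches": len(new_tips),
            "n_merges": len(merges),
            "boundary_exits": boundary_exits,
        })
        if n_active == 0:
            break
    return network, log
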