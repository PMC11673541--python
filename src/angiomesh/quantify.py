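"""CAM-style quantification of simulated capillary networks.

Mirrors how vascularisation is scored on chorioallantoic-membrane images:
the region of interest is divided into a 5 x 5 grid of square patches and
the capillary "volume fraction" of each patch is computed.  Because the
networks (like the assay images) are 2D projections, the volume fraction is
implemented as a projected area fraction: sum of clipped segment length
times diameter over the patch area.  Branch-angle statistics and
stress-distribution summaries complete the quantification.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from angiomesh.adaptation import AdaptationParams, StimulusSet
from angiomesh.hemodynamics import FlowState
from angiomesh.network import VascularNetwork


@dataclass
class FractionMap:
    """Patchwise area fractions on an n x n grid over a rectangular ROI."""

    grid: np.ndarray
    total: float
    roi: tuple[float, float, float, float]


def _clip_segment_to_patch(
    p0: np.ndarray, p1: np.ndarray,
    patch: tuple[float, float, float, float],
    half_open_x: bool, half_open_y: bool,
) -> float:
    """Length of segment p0-p1 inside a patch (Liang–Barsky clipping).

    Patch boundaries are half-open on the high side ([x0, x1), [y0, y1))
    wherever the patch abuts another patch, so a segment lying exactly on
    an interior gridline is counted once.
    """
    x0, y0, x1, y1 = patch
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for (pcoef, qcoef) in (
        (-d[0], p0[0] - x0), (d[0], x1 - p0[0]),
        (-d[1], p0[1] - y0), (d[1], y1 - p0[1]),
    ):
        if pcoef == 0.0:
            if qcoef < 0:
                return 0.0
            continue
        t = qcoef / pcoef
        if pcoef < 0:
            t0 = max(t0, t)
        else:
            t1 = min(t1, t)
        if t0 > t1:
            return 0.0
    length = float(np.linalg.norm(d)) * (t1 - t0)
    if length <= 0.0:
        # zero-extent overlap (touching the patch at a point): not counted
        return 0.0
    # half-open rule: a piece lying entirely on the shared high boundary
    # belongs to the neighbouring patch
    a = p0 + t0 * d
    b = p0 + t1 * d
    tol = 1e-12
    if half_open_x and abs(a[0] - x1) < tol and abs(b[0] - x1) < tol:
        return 0.0
    if half_open_y and abs(a[1] - y1) < tol and abs(b[1] - y1) < tol:
        return 0.0
    return length


def volume_fraction_map(
    network: VascularNetwork,
    roi: tuple[float, float, float, float],
    n: int = 5,
) -> FractionMap:
    """Patchwise capillary area fractions on an ``n`` x ``n`` grid over ``roi``.

    Per patch: fraction = sum(clipped segment length x diameter) / patch
    area.  ``grid[i, j]`` is row i (bottom to top), column j (left to
    right); ``total`` is the area-weighted mean over patches, identical to
    the direct whole-ROI computation because the clipping partitions each
    segment exactly.  An empty network yields an all-zero map.
    """
    xmin, ymin, xmax, ymax = roi
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate ROI")
    hx = (xmax - xmin) / n
    hy = (ymax - ymin) / n
    grid = np.zeros((n, n))
    patch_area = hx * hy
    for sid, a, b, d in network.segments():
        p0 = network.node_position(a)
        p1 = network.node_position(b)
        for i in range(n):
            for j in range(n):
                patch = (xmin + j * hx, ymin + i * hy,
                         xmin + (j + 1) * hx, ymin + (i + 1) * hy)
                length = _clip_segment_to_patch(
                    p0, p1, patch,
                    half_open_x=(j < n - 1), half_open_y=(i < n - 1))
                grid[i, j] += length * d["diameter"]
    grid /= patch_area
    total = float(grid.mean())  # equal patches: area-weighted mean
    return FractionMap(grid=grid, total=total, roi=roi)


def fraction_discrepancy(sim: FractionMap, ref: FractionMap) -> float:
    """Percent discrepancy 100 |total_sim - total_ref| / total_ref.

    The reference map normalises the comparison; passing the maps in the
    other order changes the denominator accordingly.
    """
    if not np.allclose(sim.roi, ref.roi):
        raise ValueError("fraction maps cover different ROIs")
    if ref.total == 0:
        raise ValueError("reference map has zero total fraction")
    return 100.0 * abs(sim.total - ref.total) / ref.total


def branch_angle_stats(network: VascularNetwork) -> dict:
    """Mean/min/max branch angle by order relation (same vs cross order).

    Uses the branch events recorded during growth when available (exact
    sampled angles); otherwise reconstructs angles geometrically at every
    junction of degree >= 3: the incident segment of lowest generation is
    the parent, the outgoing same-order segment of smallest deviation is
    the parent's continuation (excluded), and every other outgoing segment
    is a daughter.  Stats are invariant under rigid motions of the network.
    """
    groups: dict[str, list[float]] = {"same_order": [], "cross_order": []}
    if network.branch_events:
        for ev in network.branch_events:
            key = "same_order" if ev.same_order else "cross_order"
            groups[key].append(ev.angle_deg)
    else:
        for nid in network.node_ids():
            incident = [
                (d["sid"], a if b == nid else b, d)
                for a, b, d in network.g.edges(nid, data=True)
            ]
            if len(incident) < 3:
                continue
            incident.sort(key=lambda t: (t[2]["generation"], t[0]))
            parent_sid, parent_other, parent_d = incident[0]
            p_here = network.node_position(nid)
            v_parent = p_here - network.node_position(parent_other)
            npar = np.linalg.norm(v_parent)
            if npar == 0:
                continue
            v_parent /= npar
            angles = []
            for sid, other, d in incident[1:]:
                v = network.node_position(other) - p_here
                nv = np.linalg.norm(v)
                if nv == 0:
                    continue
                cosang = float(np.clip(v @ v_parent / nv, -1.0, 1.0))
                angles.append((math.degrees(math.acos(cosang)), d["order"], sid))
            same = [t for t in angles if t[1] == parent_d["order"]]
            if same:
                cont = min(same, key=lambda t: t[0])
                angles = [t for t in angles if t[2] != cont[2]]
            for ang, order, _ in angles:
                key = "same_order" if order == parent_d["order"] else "cross_order"
                groups[key].append(ang)
    out = {}
    for key, vals in groups.items():
        if vals:
            arr = np.asarray(vals)
            out[key] = {"mean": float(arr.mean()), "min": float(arr.min()),
                        "max": float(arr.max()), "n": int(arr.size)}
        else:
            out[key] = {"mean": math.nan, "min": math.nan, "max": math.nan, "n": 0}
    return out


def total_effective_stress(
    tau_w: np.ndarray, tau_e: np.ndarray, params: AdaptationParams
) -> np.ndarray:
    """Total effective stress tau_T = (tau_w + tau_ref) / tau_e^k_p.

    This is the exponentiated net hemodynamic stimulus
    10^(S_tau + k_p S_p): the single stress-like quantity a segment
    effectively experiences once the pressure set point is discounted.
    Isolated here so an alternative definition can be swapped in.
    """
    return (tau_w + params.tau_ref_dyn_cm2) / tau_e ** params.k_p


def stress_summary(
    network: VascularNetwork,
    flow_state: FlowState,
    stimuli: StimulusSet,
    params: Optional[AdaptationParams] = None,
) -> dict:
    """Ranges and quantiles of tau_w, tau_e and tau_T over the network.

    Reported separately for all segments and for neo-vessels (non-parent
    segments); quantiles at 0/25/50/75/100%.
    """
    if params is None:
        params = AdaptationParams()
    tau_t = total_effective_stress(stimuli.tau_w, stimuli.tau_e, params)
    parent_mask = np.array([
        network.segment_by_id(int(sid))[2]["parent"]
        for sid in stimuli.segment_ids
    ], dtype=bool)

    def _summ(arr: np.ndarray) -> dict:
        if arr.size == 0:
            return {"min": math.nan, "max": math.nan, "quantiles": []}
        return {
            "min": float(arr.min()), "max": float(arr.max()),
            "quantiles": [float(q) for q in
                          np.quantile(arr, [0, 0.25, 0.5, 0.75, 1.0])],
        }

    out = {}
    for name, arr in (("tau_w_dyn_cm2", stimuli.tau_w),
                      ("tau_e", stimuli.tau_e),
                      ("tau_T", tau_t)):
        out[name] = _summ(arr)
        out[name + "_neo"] = _summ(arr[~parent_mask])
    return out


def write_fraction_map(fmap: FractionMap, path: str | Path) -> None:
    """Export the grid as a delimited file plus a JSON total sidecar."""
    np.savetxt(str(path), fmap.grid, delimiter=",")
    with open(str(path) + ".total.json", "w") as fh:
        json.dump({"total_fraction": fmap.total, "roi_mm": list(fmap.roi)},
                  fh, indent=2)
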