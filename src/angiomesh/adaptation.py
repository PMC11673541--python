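"""Structural diameter adaptation of the capillary network.

Each segment responds to three stimuli, following the structural-adaptation
formulation of Pries and co-workers (all logarithms base 10):

* hemodynamic shear stimulus  S_tau = log10(tau_w + tau_ref), with a small
  offset tau_ref guarding the singularity at zero shear;
* pressure stimulus S_p = -log10(tau_e), where the circumferential
  wall-stress set point is the sigmoid

      tau_e(P) = 100 - 86 * exp(-5000 * (log10(log10 P))^5.4)

  of the transmural pressure P in mmHg (strictly increasing, bounded in
  (14, 100) on the admissible pressure range);
* metabolic stimulus S_m = log10(Q_ref / (Q_b * H) + 1), strongest in
  low-flow segments, with Q_ref the largest segment flow in the network
  and H the (constant) discharge haematocrit.

The diameter update per round is

    dD = [S_tau - k_p * log10(tau_e) + k_m * S_m - k_s] * D * dt

with the basal shrinking tendency k_s; diameters are clamped to
[d_min, d_max], parent-vessel diameters are frozen, and the flow field is
re-solved after every round until the largest relative diameter change
drops below ``conv_tol``.

Stimuli are evaluated with stresses on the dyn cm^-2 scale of the original
adaptation calibration (tau_ref is stored in mmHg and converted
internally), and segment pressure is the mean of its two node pressures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from angiomesh.hemodynamics import FlowParams, FlowState, solve_pressures
from angiomesh.network import VascularNetwork
from angiomesh.units import MMHG_TO_DYN_CM2

#: Pressures below this floor (mmHg) are clamped so the nested log10 in
#: tau_e stays defined.
PRESSURE_FLOOR_MMHG = 10.5

#: Flow floor for the metabolic stimulus, as a fraction of Q_ref.
ZERO_FLOW_EPS = 1e-6


@dataclass(frozen=True)
class AdaptationParams:
    """Adaptation constants (shear reference, sensitivities, clamps)."""

    tau_ref: float = 7.73e-5        # mmHg
    k_p: float = 0.68
    k_m: float = 0.7
    k_s: float = 1.72
    haematocrit: float = 0.45
    dt: float = 0.1                 # dimensionless per update round
    d_min: float = 0.004            # mm
    d_max: float = 0.25             # mm
    conv_tol: float = 1e-4
    max_rounds: int = 5000

    def __post_init__(self) -> None:
        if not (self.k_p > 0 and self.k_m > 0 and self.k_s > 0):
            raise ValueError("sensitivity constants k_p, k_m, k_s must be positive")
        if not 0 < self.haematocrit < 1:
            raise ValueError("haematocrit must lie in (0, 1)")
        if not 0 < self.d_min < self.d_max:
            raise ValueError("need 0 < d_min < d_max")
        if not (self.tau_ref > 0 and self.dt > 0):
            raise ValueError("tau_ref and dt must be positive")

    @property
    def tau_ref_dyn_cm2(self) -> float:
        return self.tau_ref * MMHG_TO_DYN_CM2


@dataclass
class StimulusSet:
    """Per-segment stimuli for one adaptation round (aligned arrays)."""

    segment_ids: np.ndarray
    s_tau: np.ndarray
    tau_e: np.ndarray
    s_p: np.ndarray
    s_m: np.ndarray
    tau_w: np.ndarray           # dyn cm^-2
    pressure: np.ndarray        # mmHg, segment mean
    q_ref: float
    total: np.ndarray           # the full update bracket


def s_tau(tau_w: float, tau_ref: float) -> float:
    """Shear stimulus log10(tau_w + tau_ref); tau_ref guards tau_w = 0."""
    if tau_w < 0:
        raise ValueError("wall shear stress must be non-negative")
    return math.log10(tau_w + tau_ref)


def tau_e(pressure: float | np.ndarray) -> float | np.ndarray:
    """Circumferential wall-stress set point for transmural pressure (mmHg).

    Strictly increasing in pressure; inputs below the floor are clamped
    (with a warning) so the nested logarithm stays defined.
    """
    p = np.asarray(pressure, dtype=float)
    if np.any(p < PRESSURE_FLOOR_MMHG):
        warnings.warn(
            f"pressure below {PRESSURE_FLOOR_MMHG} mmHg clamped in tau_e",
            RuntimeWarning, stacklevel=2,
        )
        p = np.maximum(p, PRESSURE_FLOOR_MMHG)
    inner = np.log10(np.log10(p))
    out = 100.0 - 86.0 * np.exp(-5000.0 * inner ** 5.4)
    return float(out) if np.isscalar(pressure) else out


def s_p(tau_e_value: float) -> float:
    """Pressure stimulus -log10(tau_e); decreasing in the set-point stress."""
    if not tau_e_value > 0:
        raise ValueError("tau_e must be positive")
    return -math.log10(tau_e_value)


def s_m(q_b: float, q_ref: float, haematocrit: float) -> float:
    """Metabolic stimulus log10(q_ref / (q_b H) + 1).

    Zero (or numerically zero) segment flow is capped at
    ``ZERO_FLOW_EPS * q_ref`` with a warning; a fully unperfused network
    (q_ref = 0) carries no metabolic information and returns 0.
    """
    if q_ref <= 0:
        return 0.0
    if q_b <= 0:
        warnings.warn("zero segment flow capped in metabolic stimulus",
                      RuntimeWarning, stacklevel=2)
        q_b = ZERO_FLOW_EPS * q_ref
    q_b = max(q_b, ZERO_FLOW_EPS * q_ref)
    return math.log10(q_ref / (q_b * haematocrit) + 1.0)


def delta_diameter(diameter: float, bracket: float, params: AdaptationParams) -> float:
    """Diameter change dD = bracket * D * dt (before clamping)."""
    return bracket * diameter * params.dt


def compute_stimuli(
    network: VascularNetwork,
    state: FlowState,
    params: AdaptationParams,
) -> StimulusSet:
    """Evaluate all per-segment stimuli from a solved flow state."""
    segs = network.segments()
    sids = np.array([sid for sid, _, _, _ in segs], dtype=int)
    tau_w_arr = np.array([state.wall_shear[sid] for sid in sids])
    p_seg = np.array([
        0.5 * (state.pressures[a] + state.pressures[b]) for _, a, b, _ in segs
    ])
    q_abs = np.array([abs(state.flows[sid]) for sid in sids])
    q_ref = float(q_abs.max()) if q_abs.size else 0.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        te = np.asarray(tau_e(p_seg))
        stau = np.log10(tau_w_arr + params.tau_ref_dyn_cm2)
        sp_arr = -np.log10(te)
        sm_arr = np.array([s_m(q, q_ref, params.haematocrit) for q in q_abs])
    total = stau - params.k_p * np.log10(te) + params.k_m * sm_arr - params.k_s
    return StimulusSet(segment_ids=sids, s_tau=stau, tau_e=te, s_p=sp_arr,
                       s_m=sm_arr, tau_w=tau_w_arr, pressure=p_seg,
                       q_ref=q_ref, total=total)


def run_adaptation(
    network: VascularNetwork,
    flow_params: FlowParams,
    adapt_params: AdaptationParams,
    boundary: Optional[dict[int, float]] = None,
    method: str = "direct",
    record: str = "summary",
) -> dict:
    """Iterate flow solve + diameter update until the structure converges.

    Non-parent diameters evolve by the update law; parent diameters are
    frozen.  Convergence: the maximum relative applied diameter change over
    free segments falls below ``conv_tol``.  If ``max_rounds`` is exhausted
    the best (smallest-change) state seen is restored and the result is
    flagged non-converged.  ``record="full"`` stores a per-round,
    per-segment diagnostics table; ``"summary"`` keeps one row per round.

    Returns a dict with the final ``state`` (FlowState), ``stimuli``,
    ``converged`` flag, ``rounds`` used and ``diagnostics`` DataFrame;
    the network is remodelled in place.
    """
    free_sids = [sid for sid, _, _, d in network.segments() if not d["parent"]]
    diag_rows: list[dict] = []
    converged = False
    best = None  # (max_rel_change, diameters, round)
    state = None
    stimuli = None
    warm: Optional[dict[int, float]] = None
    rounds = 0
    for rnd in range(1, adapt_params.max_rounds + 1):
        rounds = rnd
        state = solve_pressures(network, flow_params, boundary=boundary,
                                method=method, warm_start=warm)
        warm = state.pressures
        stimuli = compute_stimuli(network, state, adapt_params)
        if not free_sids:
            converged = True
            break
        bracket = dict(zip(stimuli.segment_ids.tolist(), stimuli.total))
        max_rel = 0.0
        for sid in free_sids:
            _, _, d = network.segment_by_id(sid)
            d_old = d["diameter"]
            d_new = d_old + delta_diameter(d_old, bracket[sid], adapt_params)
            d_new = min(max(d_new, adapt_params.d_min), adapt_params.d_max)
            if d_new != d_old:
                network.set_diameter(sid, d_new)
            max_rel = max(max_rel, abs(d_new - d_old) / d_old)
        if record == "full":
            seg_lookup = {s: i for i, s in enumerate(stimuli.segment_ids)}
            for sid in stimuli.segment_ids:
                i = seg_lookup[sid]
                _, _, d = network.segment_by_id(sid)
                diag_rows.append({
                    "round": rnd, "segment_id": int(sid),
                    "diameter_mm": d["diameter"],
                    "tau_w_dyn_cm2": stimuli.tau_w[i],
                    "tau_e": stimuli.tau_e[i], "s_tau": stimuli.s_tau[i],
                    "s_p": stimuli.s_p[i], "s_m": stimuli.s_m[i],
                    "bracket": stimuli.total[i],
                })
        else:
            diam = [network.segment_by_id(sid)[2]["diameter"] for sid in free_sids]
            diag_rows.append({
                "round": rnd, "max_rel_change": max_rel,
                "q_ref": stimuli.q_ref,
                "d_min": float(np.min(diam)), "d_max": float(np.max(diam)),
                "tau_w_max_dyn_cm2": float(stimuli.tau_w.max()),
            })
        if best is None or max_rel < best[0]:
            best = (max_rel, {sid: network.segment_by_id(sid)[2]["diameter"]
                              for sid in free_sids}, rnd)
        if max_rel < adapt_params.conv_tol:
            converged = True
            break
    if not converged and best is not None and free_sids:
        for sid, dval in best[1].items():
            network.set_diameter(sid, dval)
        state = solve_pressures(network, flow_params, boundary=boundary,
                                method=method, warm_start=warm)
        stimuli = compute_stimuli(network, state, adapt_params)
    return {
        "state": state,
        "stimuli": stimuli,
        "converged": converged,
        "rounds": rounds,
        "diagnostics": pd.DataFrame(diag_rows),
    }
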