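"""Poiseuille flow and nodal pressures on the capillary graph.

Laminar flow through each segment follows Poiseuille's law,

    Q = pi D^4 / (128 mu L) * (P_a - P_b),

and volumetric conservation (the net flow at every interior junction is
zero) closes the system.  Pressures are solved on the weighted graph
Laplacian either by Successive Over-Relaxation (SOR, the default) or by a
direct sparse factorisation; both agree to solver tolerance and the direct
route serves as an independent check on the iterative one.

Units: diameters/lengths in mm, viscosity in mPa s, pressures in mmHg,
flows in mm^3 s^-1; wall shear stress tau_w = 32 mu |Q| / (pi D^3) is
reported in dyn cm^-2.  Dead-end (degree-1 interior) nodes naturally
receive a no-flux condition from the conservation law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from angiomesh.network import VascularNetwork
from angiomesh.units import MPA_TO_DYN_CM2, POISEUILLE_UNIT_FACTOR


@dataclass(frozen=True)
class FlowParams:
    """Blood rheology, boundary pressures and SOR solver controls."""

    viscosity: float = 3.5          # mPa s
    p_artery: float = 45.0          # mmHg
    p_vein: float = 22.0            # mmHg
    sor_omega: float = 1.5
    sor_tol: float = 1e-8
    sor_maxiter: int = 50_000

    def __post_init__(self) -> None:
        if not self.viscosity > 0:
            raise ValueError("viscosity must be positive")
        if not self.p_artery > self.p_vein:
            raise ValueError("p_artery must exceed p_vein")
        if not 0 < self.sor_omega < 2:
            raise ValueError("sor_omega must lie in (0, 2)")


@dataclass
class FlowState:
    """Solved pressures, flows, conductances and wall shear stresses.

    ``pressures`` is keyed by node id (mmHg); ``flows`` by segment id
    (mm^3 s^-1, signed positive from node_a to node_b); ``wall_shear`` in
    dyn cm^-2.
    """

    pressures: dict[int, float]
    flows: dict[int, float]
    conductances: dict[int, float]
    wall_shear: dict[int, float]
    iterations_used: int = 0


def segment_conductance(
    diameter: float,
    length: float,
    viscosity: float,
    unit_factor: float = POISEUILLE_UNIT_FACTOR,
) -> float:
    """Poiseuille conductance g = pi D^4 / (128 mu L) * unit_factor.

    With the default factor, mm / mPa s / mmHg inputs yield flows in
    mm^3 s^-1; pass ``unit_factor=1`` for a fully consistent unit system.
    """
    if not (diameter > 0 and length > 0):
        raise ValueError("diameter and length must be positive")
    if not viscosity > 0:
        raise ValueError("viscosity must be positive")
    return np.pi * diameter ** 4 / (128.0 * viscosity * length) * unit_factor


def wall_shear(flow: float, diameter: float, viscosity: float) -> float:
    """Wall shear stress tau_w = 32 mu |Q| / (pi D^3) in dyn cm^-2."""
    if not diameter > 0:
        raise ValueError("diameter must be positive")
    return 32.0 * viscosity * abs(flow) / (np.pi * diameter ** 3) * MPA_TO_DYN_CM2


def _boundary_from_tags(network: VascularNetwork, params: FlowParams) -> dict[int, float]:
    out: dict[int, float] = {}
    for nid in network.node_ids():
        tag = network.g.nodes[nid].get("bc")
        if tag == "artery":
            out[nid] = params.p_artery
        elif tag == "vein":
            out[nid] = params.p_vein
    return out


def solve_pressures(
    network: VascularNetwork,
    params: FlowParams,
    boundary: Optional[dict[int, float]] = None,
    method: str = "sor",
    warm_start: Optional[dict[int, float]] = None,
) -> FlowState:
    """Solve nodal pressures and segment flows on the network.

    ``boundary`` maps node ids to imposed pressures; by default it is
    derived from the artery/vein tags on parent terminal nodes.  Every
    connected component must contain at least one boundary node.  The SOR
    iteration sweeps interior nodes with relaxation ``sor_omega`` until the
    relative residual drops below ``sor_tol``; ``method="direct"`` uses a
    sparse LU solve instead (used as the fast path during adaptation).
    """
    if boundary is None:
        boundary = _boundary_from_tags(network, params)
    ids = network.node_ids()
    if not ids:
        raise ValueError("empty network")
    index = {nid: k for k, nid in enumerate(ids)}
    n = len(ids)

    for comp in nx.connected_components(network.g):
        if not any(nid in boundary for nid in comp):
            raise ValueError(
                f"connected component containing node {min(comp)} has no "
                "pressure boundary node; flow system is unconstrained"
            )

    segs = network.segments()
    cond = {}
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for sid, a, b, d in segs:
        g = segment_conductance(d["diameter"], d["length"], params.viscosity)
        cond[sid] = g
        ia, ib = index[a], index[b]
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [-g, -g]
        diag[ia] += g
        diag[ib] += g
    L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr() + sp.diags(diag)

    fixed = np.zeros(n, dtype=bool)
    p = np.empty(n)
    p.fill(0.5 * (params.p_artery + params.p_vein))
    for nid, val in boundary.items():
        fixed[index[nid]] = True
        p[index[nid]] = float(val)
    if warm_start is not None:
        for nid, val in warm_start.items():
            if nid in index and not fixed[index[nid]]:
                p[index[nid]] = float(val)
    free = ~fixed
    iters = 0
    if free.any():
        L_csr = L.tocsr()
        b_vec = -(L_csr[free][:, fixed] @ p[fixed])
        A = L_csr[free][:, free].tocsr()
        if method == "direct":
            p[free] = spla.spsolve(A.tocsc(), b_vec)
        elif method == "sor":
            p_free = p[free].copy()
            indptr, indices, data = A.indptr, A.indices, A.data
            adiag = A.diagonal()
            if np.any(adiag <= 0):
                raise ValueError("singular flow system (isolated free node)")
            omega = params.sor_omega
            b_norm = np.linalg.norm(b_vec)
            scale = b_norm if b_norm > 0 else 1.0
            m = p_free.size
            for it in range(1, params.sor_maxiter + 1):
                for i in range(m):
                    acc = 0.0
                    for jj in range(indptr[i], indptr[i + 1]):
                        j = indices[jj]
                        if j != i:
                            acc += data[jj] * p_free[j]
                    p_free[i] += omega * ((b_vec[i] - acc) / adiag[i] - p_free[i])
                resid = np.linalg.norm(A @ p_free - b_vec) / scale
                if resid < params.sor_tol:
                    break
            else:
                resid = np.linalg.norm(A @ p_free - b_vec) / scale
                raise RuntimeError(
                    f"SOR did not converge in {params.sor_maxiter} iterations "
                    f"(relative residual {resid:.3e})"
                )
            iters = it
            p[free] = p_free
        else:
            raise ValueError(f"unknown method {method!r}")

    pressures = {nid: float(p[index[nid]]) for nid in ids}
    flows, shear = {}, {}
    for sid, a, b, d in segs:
        q = cond[sid] * (pressures[a] - pressures[b])
        flows[sid] = q
        shear[sid] = wall_shear(q, d["diameter"], params.viscosity)
    return FlowState(pressures=pressures, flows=flows, conductances=cond,
                     wall_shear=shear, iterations_used=iters)


def check_conservation(
    network: VascularNetwork,
    state: FlowState,
    tol: float = 1e-10,
    boundary: Optional[set[int]] = None,
) -> float:
    """Maximum relative net-flow imbalance over interior nodes.

    Imbalance is |sum of signed segment flows| at each non-boundary node,
    normalised by the largest segment flow magnitude (1 if all flows are
    zero); the solve is conservative iff the return value <= ``tol``.
    """
    if boundary is None:
        boundary = {nid for nid in network.node_ids()
                    if network.g.nodes[nid].get("bc")}
    net_flow = {nid: 0.0 for nid in network.node_ids()}
    for sid, a, b, _ in network.segments():
        q = state.flows[sid]
        net_flow[a] -= q
        net_flow[b] += q
    q_scale = max((abs(q) for q in state.flows.values()), default=0.0)
    if q_scale == 0.0:
        q_scale = 1.0
    interior = [nid for nid in net_flow if nid not in boundary]
    if not interior:
        return 0.0
    return max(abs(net_flow[nid]) for nid in interior) / q_scale


def flow_tables(network: VascularNetwork, state: FlowState
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and segment tables joined with the flow solution."""
    nodes = network.nodes_df()
    nodes["pressure_mmHg"] = nodes["id"].map(state.pressures)
    segs = network.segments_df()
    segs["flow_mm3_s"] = segs["id"].map(state.flows)
    segs["pressure_drop_mmHg"] = [
        state.pressures[a] - state.pressures[b]
        for a, b in zip(segs["node_a"], segs["node_b"])
    ]
    segs["wall_shear_dyn_cm2"] = segs["id"].map(state.wall_shear)
    return nodes, segs
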