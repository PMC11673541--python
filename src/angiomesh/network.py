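"""Capillary graph container shared by the growth, flow and adaptation stages.

A :class:`VascularNetwork` is a spatial multigraph: nodes carry 2D positions
(mm), a kind tag (``parent`` for the pre-existing vessel, ``sprout`` for
grown nodes, ``junction`` for branch/anastomosis points) and an optional
pressure-boundary tag (``artery`` / ``vein``).  Segments carry diameter,
length (always the Euclidean node distance), capillary order and the growth
iteration at which they appeared.  Parent segments are frozen during
structural adaptation.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

NODE_KINDS = ("parent", "sprout", "junction")


@dataclass
class BranchEvent:
    """Record of one branching: orders involved and the sampled angle."""

    parent_order: int
    daughter_order: int
    angle_deg: float
    node_id: int
    same_order: bool


class VascularNetwork:
    """Graph of spatial nodes and capillary segments."""

    def __init__(self) -> None:
        self.g = nx.MultiGraph()
        self._next_node = 0
        self._next_segment = 0
        self.branch_events: list[BranchEvent] = []

    # ------------------------------------------------------------------ nodes
    def add_node(self, x: float, y: float, kind: str = "sprout", bc: Optional[str] = None) -> int:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        nid = self._next_node
        self.g.add_node(nid, x=float(x), y=float(y), kind=kind, bc=bc)
        self._next_node += 1
        return nid

    def node_position(self, nid: int) -> np.ndarray:
        d = self.g.nodes[nid]
        return np.array([d["x"], d["y"]])

    def node_ids(self) -> list[int]:
        return sorted(self.g.nodes)

    def node_positions(self) -> np.ndarray:
        ids = self.node_ids()
        return np.array([[self.g.nodes[i]["x"], self.g.nodes[i]["y"]] for i in ids]) \
            if ids else np.empty((0, 2))

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_segments(self) -> int:
        return self.g.number_of_edges()

    # --------------------------------------------------------------- segments
    def add_segment(
        self,
        node_a: int,
        node_b: int,
        diameter: float,
        order: int,
        generation: int = 0,
        parent: bool = False,
    ) -> int:
        if node_a == node_b:
            raise ValueError("self-loop segments are not allowed")
        if not diameter > 0:
            raise ValueError("segment diameter must be positive")
        length = float(np.linalg.norm(self.node_position(node_a) - self.node_position(node_b)))
        if length <= 0:
            raise ValueError("zero-length segment (coincident nodes)")
        sid = self._next_segment
        self.g.add_edge(
            node_a, node_b,
            key=sid, sid=sid,
            diameter=float(diameter), length=length,
            order=int(order), generation=int(generation), parent=bool(parent),
        )
        self._next_segment += 1
        return sid

    def segments(self) -> list[tuple[int, int, int, dict]]:
        """(sid, node_a, node_b, attrs) sorted by segment id."""
        out = [(d["sid"], a, b, d) for a, b, d in self.g.edges(data=True)]
        return sorted(out, key=lambda t: t[0])

    def segment_by_id(self, sid: int) -> tuple[int, int, dict]:
        for a, b, k, d in self.g.edges(keys=True, data=True):
            if d["sid"] == sid:
                return a, b, d
        raise KeyError(f"no segment with id {sid}")

    def set_diameter(self, sid: int, diameter: float) -> None:
        _, _, d = self.segment_by_id(sid)
        if not diameter > 0:
            raise ValueError("segment diameter must be positive")
        d["diameter"] = float(diameter)

    def split_segment(self, sid: int, point: Iterable[float]) -> int:
        """Split a segment at ``point``, returning the new junction node id.

        Both halves inherit the diameter, order and generation of the
        original segment; the original segment id is retired.
        """
        a, b, d = self.segment_by_id(sid)
        self.g.remove_edge(a, b, key=sid)
        pt = np.asarray(tuple(point), dtype=float)
        nid = self.add_node(pt[0], pt[1], kind="junction")
        for end in (a, b):
            self.add_segment(end, nid, d["diameter"], d["order"],
                             generation=d["generation"], parent=d["parent"])
        return nid

    def nearest_node(
        self, point: Iterable[float], exclude: Optional[set[int]] = None
    ) -> tuple[Optional[int], float]:
        """Nearest node to ``point`` (id, distance), honouring exclusions."""
        pt = np.asarray(tuple(point), dtype=float)
        best, best_d = None, np.inf
        for nid in self.node_ids():
            if exclude and nid in exclude:
                continue
            d = float(np.linalg.norm(self.node_position(nid) - pt))
            if d < best_d:
                best, best_d = nid, d
        return best, best_d

    # ------------------------------------------------------------- dataframes
    def nodes_df(self) -> pd.DataFrame:
        rows = [
            {"id": nid, "x": self.g.nodes[nid]["x"], "y": self.g.nodes[nid]["y"],
             "kind": self.g.nodes[nid]["kind"],
             "bc": self.g.nodes[nid].get("bc") or ""}
            for nid in self.node_ids()
        ]
        return pd.DataFrame(rows, columns=["id", "x", "y", "kind", "bc"])

    def segments_df(self) -> pd.DataFrame:
        rows = [
            {"id": sid, "node_a": a, "node_b": b,
             "diameter_mm": d["diameter"], "length_mm": d["length"],
             "order": d["order"], "generation": d["generation"],
             "parent": int(d["parent"])}
            for sid, a, b, d in self.segments()
        ]
        return pd.DataFrame(rows, columns=["id", "node_a", "node_b", "diameter_mm",
                                           "length_mm", "order", "generation", "parent"])

    def events_df(self) -> pd.DataFrame:
        rows = [
            {"parent_order": e.parent_order, "daughter_order": e.daughter_order,
             "angle_deg": e.angle_deg, "node_id": e.node_id,
             "same_order": int(e.same_order)}
            for e in self.branch_events
        ]
        return pd.DataFrame(rows, columns=["parent_order", "daughter_order",
                                           "angle_deg", "node_id", "same_order"])

    # ------------------------------------------------------------------- I/O
    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.nodes_df().to_csv(directory / "nodes.csv", index=False)
        self.segments_df().to_csv(directory / "segments.csv", index=False)
        self.events_df().to_csv(directory / "branch_events.csv", index=False)
        with open(directory / "network.meta.json", "w") as fh:
            json.dump({"coordinates": "mm, lower-left origin",
                       "n_nodes": self.n_nodes, "n_segments": self.n_segments}, fh, indent=2)

    @classmethod
    def from_csv(cls, directory: str | Path) -> "VascularNetwork":
        directory = Path(directory)
        nodes = pd.read_csv(directory / "nodes.csv", keep_default_na=False)
        segs = pd.read_csv(directory / "segments.csv")
        net = cls()
        for _, r in nodes.iterrows():
            nid = net.add_node(r["x"], r["y"], kind=r["kind"], bc=(r["bc"] or None))
            if nid != int(r["id"]):  # keep original ids
                raise ValueError("node ids must be contiguous from 0 in nodes.csv")
        for _, r in segs.iterrows():
            net.add_segment(int(r["node_a"]), int(r["node_b"]), float(r["diameter_mm"]),
                            int(r["order"]), generation=int(r["generation"]),
                            parent=bool(r["parent"]))
        ev_path = directory / "branch_events.csv"
        if ev_path.exists():
            ev = pd.read_csv(ev_path)
            for _, r in ev.iterrows():
                net.branch_events.append(BranchEvent(
                    int(r["parent_order"]), int(r["daughter_order"]),
                    float(r["angle_deg"]), int(r["node_id"]), bool(r["same_order"])))
        return net

    def to_graphml(self, path: str | Path) -> None:
        g = nx.MultiGraph()
        for nid in self.node_ids():
            d = self.g.nodes[nid]
            g.add_node(nid, x=d["x"], y=d["y"], kind=d["kind"], bc=d.get("bc") or "")
        for sid, a, b, d in self.segments():
            g.add_edge(a, b, key=sid, sid=sid, diameter=d["diameter"], length=d["length"],
                       order=d["order"], generation=d["generation"], parent=int(d["parent"]))
        nx.write_graphml(g, str(path))

    def edge_table_hash(self) -> str:
        """SHA-256 of the canonical node+segment tables (determinism checks)."""
        buf = io.StringIO()
        self.nodes_df().to_csv(buf, index=False)
        self.segments_df().to_csv(buf, index=False)
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()

    def bounds_check(self, bounds: tuple[float, float, float, float], tol: float = 1e-9) -> bool:
        xmin, ymin, xmax, ymax = bounds
        pos = self.node_positions()
        if pos.size == 0:
            return True
        return bool(
            (pos[:, 0] >= xmin - tol).all() and (pos[:, 0] <= xmax + tol).all()
            and (pos[:, 1] >= ymin - tol).all() and (pos[:, 1] <= ymax + tol).all()
        )
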