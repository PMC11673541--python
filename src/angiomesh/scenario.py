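"""Scenario definition, synthetic CAM-like generation and configuration I/O.

A :class:`Scenario` bundles everything one simulation needs: the domain
rectangle and meshless node spacing, parent-vessel polylines with their
diameters and artery/vein terminal tags, the hydrogel (VEGF source) disk,
initial tip-cell positions, and the parameter blocks of every stage, under
a single RNG seed.  :func:`generate_cam_like_scenario` emulates the CAM
assay's region of interest: a 5 x 5 mm window with an 8 mm-diameter
hydrogel centred on the lower-left corner and a parent vessel of diameter
~0.17–0.2 mm along the opposite edge carrying 3–6 initial sprout tips.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from angiomesh.adaptation import AdaptationParams
from angiomesh.hemodynamics import FlowParams
from angiomesh.rpim import DiffusionProblem, NodalDomain, RpimParams
from angiomesh.sprouting import SproutingParams
from angiomesh.units import substream

EDGE_NAMES = ("left", "right", "bottom", "top")


class ScenarioValidationError(ValueError):
    """Configuration value violates the schema; names the offending field."""


@dataclass
class ParentVessel:
    """Pre-existing vessel polyline with terminal pressure tags."""

    polyline: list[tuple[float, float]]
    diameter: float
    start_bc: Optional[str] = "artery"
    end_bc: Optional[str] = "vein"


@dataclass
class Scenario:
    bounds: tuple[float, float, float, float] = (0.0, 0.0, 5.0, 5.0)
    spacing: float = 0.125
    parent_vessels: list[ParentVessel] = field(default_factory=list)
    hydrogel: tuple[float, float, float] = (0.0, 0.0, 4.0)  # (cx, cy, radius) mm
    initial_tips: list[tuple[float, float, int]] = field(default_factory=list)
    vegf_diffusion: float = 1.16e-6     # mm^2 s^-1
    vegf_release: float = 500e-6        # g mm^-3 source density
    vegf_bc_edges: list[str] = field(default_factory=lambda: ["top"])
    vegf_bc_value: float = 0.0
    hydrogel_bc_value: Optional[float] = None  # optional fixed-concentration source BC
    rpim: RpimParams = field(default_factory=RpimParams)
    sprouting: SproutingParams = field(default_factory=SproutingParams)
    flow: FlowParams = field(default_factory=FlowParams)
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.bounds
        if not (xmax > xmin and ymax > ymin):
            raise ScenarioValidationError("bounds: degenerate rectangle")
        for edge in self.vegf_bc_edges:
            if edge not in EDGE_NAMES:
                raise ScenarioValidationError(f"vegf_bc_edges: unknown edge {edge!r}")
        for k, pv in enumerate(self.parent_vessels):
            for (x, y) in pv.polyline:
                if not (xmin <= x <= xmax and ymin <= y <= ymax):
                    raise ScenarioValidationError(
                        f"parent_vessels[{k}].polyline: point ({x}, {y}) outside bounds")
            if not pv.diameter > 0:
                raise ScenarioValidationError(f"parent_vessels[{k}].diameter: must be > 0")
        cx, cy, r = self.hydrogel
        if not r > 0:
            raise ScenarioValidationError("hydrogel: radius must be > 0")
        if not (xmin <= cx <= xmax and ymin <= cy <= ymax):
            raise ScenarioValidationError("hydrogel: centre outside bounds")
        for k, (x, y, order) in enumerate(self.initial_tips):
            if not (xmin <= x <= xmax and ymin <= y <= ymax):
                raise ScenarioValidationError(f"initial_tips[{k}]: outside bounds")
            if order < 1:
                raise ScenarioValidationError(f"initial_tips[{k}]: order must be >= 1")

    # -------------------------------------------------------- VEGF plumbing
    def hydrogel_region(self):
        cx, cy, r = self.hydrogel

        def predicate(points: np.ndarray) -> np.ndarray:
            p = np.atleast_2d(points)
            return (p[:, 0] - cx) ** 2 + (p[:, 1] - cy) ** 2 <= r ** 2

        return predicate

    def vegf_problem(self) -> DiffusionProblem:
        return DiffusionProblem(
            diff_x=self.vegf_diffusion, diff_y=self.vegf_diffusion,
            release_rate=self.vegf_release, source_region=self.hydrogel_region(),
        )

    def vegf_bc_node_ids(self, domain: NodalDomain) -> np.ndarray:
        """Lattice node indices on the configured essential-BC edges."""
        xmin, ymin, xmax, ymax = self.bounds
        coords = domain.node_coords
        tol = 1e-9
        mask = np.zeros(coords.shape[0], dtype=bool)
        for edge in self.vegf_bc_edges:
            if edge == "left":
                mask |= np.abs(coords[:, 0] - xmin) < tol
            elif edge == "right":
                mask |= np.abs(coords[:, 0] - xmax) < tol
            elif edge == "bottom":
                mask |= np.abs(coords[:, 1] - ymin) < tol
            elif edge == "top":
                mask |= np.abs(coords[:, 1] - ymax) < tol
        return np.nonzero(mask)[0]


def generate_cam_like_scenario(seed: int, n_tips: Optional[int] = None,
                               spacing: float = 0.125,
                               hydrogel_corner: str = "lower-left") -> Scenario:
    """Synthesize a CAM-like scenario (deterministic in ``seed``).

    The hydrogel disk (radius 4 mm, the assay's 8 mm internal diameter)
    sits on the requested ROI corner; a straight parent vessel spans the
    opposite edge with diameter drawn uniformly in [0.17, 0.2] mm, its
    left end tagged artery and right end vein.  3–6 tips (unless ``n_tips``
    is given) start on the parent vessel at jittered positions.
    """
    rng = substream(seed, "scenario")
    bounds = (0.0, 0.0, 5.0, 5.0)
    corners = {
        "lower-left": (0.0, 0.0), "lower-right": (5.0, 0.0),
        "upper-left": (0.0, 5.0), "upper-right": (5.0, 5.0),
    }
    if hydrogel_corner not in corners:
        raise ScenarioValidationError(f"hydrogel_corner: unknown {hydrogel_corner!r}")
    cx, cy = corners[hydrogel_corner]
    # parent vessel on the edge opposite the hydrogel corner (top for lower-*)
    if "lower" in hydrogel_corner:
        y_par, bc_edge = 5.0, "top"
    else:
        y_par, bc_edge = 0.0, "bottom"
    diameter = float(rng.uniform(0.17, 0.2))
    if n_tips is None:
        n_tips = int(rng.integers(3, 7))
    # sprouts emerge as a dense cluster on the stretch of parent vessel
    # facing the VEGF source (neighbour spacing ~0.1-0.3 mm, the scale seen
    # along sprouting CAM vessels), not spread over the whole vessel
    x0 = float(rng.uniform(0.8, 1.8))
    gaps = rng.uniform(0.1, 0.3, size=n_tips - 1) if n_tips > 1 else np.empty(0)
    xs = x0 + np.concatenate([[0.0], np.cumsum(gaps)])
    if hydrogel_corner.endswith("right"):
        xs = 5.0 - xs
    tips = [(float(x), y_par, 1) for x in np.sort(xs)]
    return Scenario(
        bounds=bounds, spacing=spacing,
        parent_vessels=[ParentVessel(
            polyline=[(0.0, y_par), (5.0, y_par)], diameter=diameter)],
        hydrogel=(cx, cy, 4.0),
        initial_tips=tips,
        vegf_bc_edges=[bc_edge],
        seed=int(seed),
    )


# ------------------------------------------------------------- config I/O
_PARAM_BLOCKS = {
    "rpim": RpimParams,
    "sprouting": SproutingParams,
    "flow": FlowParams,
    "adaptation": AdaptationParams,
}


def scenario_to_dict(sc: Scenario) -> dict:
    d = {
        "bounds": list(sc.bounds),
        "spacing": sc.spacing,
        "parent_vessels": [
            {"polyline": [list(p) for p in pv.polyline], "diameter": pv.diameter,
             "start_bc": pv.start_bc, "end_bc": pv.end_bc}
            for pv in sc.parent_vessels
        ],
        "hydrogel": list(sc.hydrogel),
        "initial_tips": [list(t) for t in sc.initial_tips],
        "vegf_diffusion": sc.vegf_diffusion,
        "vegf_release": sc.vegf_release,
        "vegf_bc_edges": list(sc.vegf_bc_edges),
        "vegf_bc_value": sc.vegf_bc_value,
        "hydrogel_bc_value": sc.hydrogel_bc_value,
        "seed": sc.seed,
    }
    for name, cls in _PARAM_BLOCKS.items():
        block = asdict(getattr(sc, name))
        block = {k: (list(v) if isinstance(v, tuple) else v) for k, v in block.items()}
        d[name] = block
    return d


def scenario_from_dict(d: dict) -> Scenario:
    kwargs: dict = {}
    simple = ("spacing", "vegf_diffusion", "vegf_release", "vegf_bc_value",
              "hydrogel_bc_value", "seed")
    for key in simple:
        if key in d:
            kwargs[key] = d[key]
    if "bounds" in d:
        kwargs["bounds"] = tuple(d["bounds"])
    if "hydrogel" in d:
        kwargs["hydrogel"] = tuple(d["hydrogel"])
    if "vegf_bc_edges" in d:
        kwargs["vegf_bc_edges"] = list(d["vegf_bc_edges"])
    if "initial_tips" in d:
        kwargs["initial_tips"] = [(float(t[0]), float(t[1]), int(t[2]))
                                  for t in d["initial_tips"]]
    if "parent_vessels" in d:
        pvs = []
        for k, pv in enumerate(d["parent_vessels"]):
            try:
                pvs.append(ParentVessel(
                    polyline=[tuple(p) for p in pv["polyline"]],
                    diameter=float(pv["diameter"]),
                    start_bc=pv.get("start_bc", "artery"),
                    end_bc=pv.get("end_bc", "vein")))
            except (KeyError, TypeError, ValueError) as exc:
                raise ScenarioValidationError(f"parent_vessels[{k}]: {exc}") from exc
        kwargs["parent_vessels"] = pvs
    for name, cls in _PARAM_BLOCKS.items():
        if name in d:
            block = dict(d[name])
            for k, v in block.items():
                if isinstance(v, list):
                    block[k] = tuple(v)
            try:
                kwargs[name] = cls(**block)
            except (TypeError, ValueError) as exc:
                raise ScenarioValidationError(f"{name}: {exc}") from exc
    unknown = set(d) - set(simple) - {"bounds", "hydrogel", "vegf_bc_edges",
                                      "initial_tips", "parent_vessels", *_PARAM_BLOCKS}
    if unknown:
        raise ScenarioValidationError(f"unknown config keys: {sorted(unknown)}")
    try:
        return Scenario(**kwargs)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ScenarioValidationError):
            raise
        raise ScenarioValidationError(str(exc)) from exc


def read_config(path: str | Path) -> Scenario:
    """Load a scenario from a YAML config; unset fields take defaults."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ScenarioValidationError(f"malformed YAML in {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ScenarioValidationError("config root must be a mapping")
    return scenario_from_dict(data)


def write_config(sc: Scenario, path: str | Path) -> None:
    """Write the canonical YAML form (write . read = identity)."""
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(sc), fh, sort_keys=True)


def write_manifest(directory: str | Path, sc: Scenario, seed: Optional[int] = None) -> None:
    """Record the run's seed, parameters and package version alongside outputs."""
    from angiomesh import __version__
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": int(seed if seed is not None else sc.seed),
        "angiomesh_version": __version__,
        "scenario": scenario_to_dict(sc),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
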