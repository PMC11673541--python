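"""Meshless RPIM solver for steady-state VEGF diffusion on a 2D rectangle.

The Radial Point Interpolation Method (RPIM) discretizes the domain with an
unstructured node cloud (here a regular lattice plus any nodes inserted by
growing sprouts) and integrates the weak form of the diffusion equation on a
fixed background mesh of quadrilateral cells carrying Gauss–Legendre points.
Shape functions are built per query point from the multiquadric radial basis

    r_i(x) = ((x_i - x)^2 + (y_i - y)^2 + c^2)^p

over the "influence domain" (the ``n_influence`` nodes nearest the query
point), augmented with a constant polynomial term so the interpolant
reproduces constants exactly (partition of unity) and passes through the
nodal values (delta property).

The boundary-value problem solved is the steady anisotropic diffusion /
Helmholtz equation

    Dx u_xx + Dy u_yy - g u + Q = 0

with a volumetric source Q over a geometric source region and essential
(Dirichlet) boundary conditions imposed by row/column elimination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numpy.polynomial.legendre import leggauss
from scipy.spatial import cKDTree


class InvalidDomainError(ValueError):
    """Raised for degenerate bounds or under-resolved discretizations."""


class ConditioningError(RuntimeError):
    """Raised when the RPIM moment matrix is singular at a query point."""


class OutOfDomainError(ValueError):
    """Raised when a query point lies outside the domain bounds."""


@dataclass(frozen=True)
class RpimParams:
    """Shape-function and quadrature parameters.

    ``c`` and ``p_exp`` are the multiquadric shape parameters; the defaults
    (c = 0.0001, p = 0.9999) are the values calibrated for this family of
    meshless diffusion solvers.  ``c`` is treated as an absolute length in
    mm.  ``n_influence`` is the number of nodes in each influence domain
    and ``gauss_order`` the quadrature order per cell axis.
    """

    c: float = 1.0e-4
    p_exp: float = 0.9999
    n_influence: int = 16
    gauss_order: int = 2

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError("RpimParams.c must be positive")
        if not 0 < self.p_exp < 2:
            raise ValueError("RpimParams.p_exp must lie in (0, 2)")
        if self.n_influence < 4:
            raise ValueError("RpimParams.n_influence must be >= 4")
        if self.gauss_order < 1:
            raise ValueError("RpimParams.gauss_order must be >= 1")


@dataclass
class NodalDomain:
    """Node cloud plus background Gauss–Legendre integration mesh.

    ``node_coords`` is an (N, 2) array in mm; ``bounds`` is
    (xmin, ymin, xmax, ymax).  ``integration_points`` / ``weights`` are
    filled by :func:`build_integration_mesh` and are independent of later
    node insertions (tip cells become nodes but the background mesh stays).
    """

    node_coords: np.ndarray
    bounds: tuple[float, float, float, float]
    integration_points: Optional[np.ndarray] = None
    weights: Optional[np.ndarray] = None
    cell_grid: Optional[tuple[int, int]] = None
    _tree: Optional[cKDTree] = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def area(self) -> float:
        xmin, ymin, xmax, ymax = self.bounds
        return (xmax - xmin) * (ymax - ymin)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.node_coords)
        return self._tree

    def contains(self, point: np.ndarray) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        x, y = float(point[0]), float(point[1])
        return xmin <= x <= xmax and ymin <= y <= ymax

    def with_extra_nodes(self, points: np.ndarray) -> "NodalDomain":
        """Return a new domain with ``points`` appended to the node cloud.

        Existing node indices are preserved; the background integration
        mesh is shared unchanged.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.size == 0:
            coords = self.node_coords
        else:
            coords = np.vstack([self.node_coords, pts])
        return NodalDomain(
            node_coords=coords,
            bounds=self.bounds,
            integration_points=self.integration_points,
            weights=self.weights,
            cell_grid=self.cell_grid,
        )


@dataclass(frozen=True)
class ShapeEval:
    """RPI shape-function values and derivatives at one query point."""

    node_ids: np.ndarray
    values: np.ndarray
    dx: np.ndarray
    dy: np.ndarray


def discretize_domain(bounds: Sequence[float], spacing: float) -> NodalDomain:
    """Lay a regular node lattice over a rectangular domain.

    ``bounds`` is (xmin, ymin, xmax, ymax) in mm.  The lattice has
    ``round(extent / spacing) + 1`` nodes per axis, ordered row-major from
    the lower-left corner; at least 3 nodes per axis are required.
    """
    xmin, ymin, xmax, ymax = (float(v) for v in bounds)
    if not (xmax > xmin and ymax > ymin):
        raise InvalidDomainError(f"degenerate bounds {bounds!r}")
    if not spacing > 0:
        raise InvalidDomainError("spacing must be positive")
    nx = int(round((xmax - xmin) / spacing)) + 1
    ny = int(round((ymax - ymin) / spacing)) + 1
    if nx < 3 or ny < 3:
        raise InvalidDomainError(
            f"spacing {spacing} gives only {nx}x{ny} nodes; need >= 3 per axis"
        )
    xs = np.linspace(xmin, xmax, nx)
    ys = np.linspace(ymin, ymax, ny)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    coords = np.column_stack([X.ravel(), Y.ravel()])
    return NodalDomain(node_coords=coords, bounds=(xmin, ymin, xmax, ymax))


def build_integration_mesh(
    domain: NodalDomain,
    cells: Optional[tuple[int, int]] = None,
    gauss_order: int = 2,
) -> NodalDomain:
    """Fill the background integration mesh of ``domain`` in place.

    The domain is tiled with ``cells`` = (nx, ny) equal quadrilateral cells
    (default: one cell per lattice gap, inferred from the node count when
    the cloud is a regular lattice); each cell carries a tensor-product
    Gauss–Legendre rule of ``gauss_order`` points per axis, with weights
    scaled by the cell Jacobian so that the weights sum to the domain area.
    """
    xmin, ymin, xmax, ymax = domain.bounds
    if cells is None:
        n_side = int(round(np.sqrt(domain.n_nodes)))
        cells = (max(n_side - 1, 1), max(n_side - 1, 1))
    cx, cy = cells
    if cx < 1 or cy < 1:
        raise InvalidDomainError("need at least 1 integration cell per axis")
    if gauss_order < 1:
        raise InvalidDomainError("gauss_order must be >= 1")
    gp, gw = leggauss(gauss_order)  # on [-1, 1]
    hx = (xmax - xmin) / cx
    hy = (ymax - ymin) / cy
    x_centres = xmin + hx * (np.arange(cx) + 0.5)
    y_centres = ymin + hy * (np.arange(cy) + 0.5)
    # per-cell points: centre + h/2 * gauss abscissae
    loc_x = 0.5 * hx * gp
    loc_y = 0.5 * hy * gp
    w2d = np.outer(gw, gw).ravel() * (0.25 * hx * hy)
    pts = []
    for yc in y_centres:
        for xc in x_centres:
            PX, PY = np.meshgrid(xc + loc_x, yc + loc_y, indexing="xy")
            pts.append(np.column_stack([PX.ravel(), PY.ravel()]))
    points = np.vstack(pts)
    weights = np.tile(w2d, cx * cy)
    domain.integration_points = points
    domain.weights = weights
    domain.cell_grid = (cx, cy)
    return domain


def influence_nodes(point: Sequence[float], domain: NodalDomain, n_influence: int) -> np.ndarray:
    """Indices of the ``n_influence`` nodes nearest ``point``.

    Distance ties are broken by the lower node index for determinism.
    """
    if domain.n_nodes < n_influence:
        raise InvalidDomainError(
            f"domain has {domain.n_nodes} nodes < n_influence={n_influence}"
        )
    return _influence_bulk(np.atleast_2d(np.asarray(point, float)), domain, n_influence)[0]


def _influence_bulk(points: np.ndarray, domain: NodalDomain, n: int) -> np.ndarray:
    """Vectorised nearest-node query, tie-broken by lowest node index."""
    k = min(2 * n, domain.n_nodes)
    dist, idx = domain.tree.query(points, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    # stable tie-break: sort each row by (distance, index)
    order = np.lexsort((idx, np.round(dist, 12)), axis=1)
    idx_sorted = np.take_along_axis(idx, order, axis=1)
    return idx_sorted[:, :n]


def _multiquadric(d2: np.ndarray, params: RpimParams) -> np.ndarray:
    return (d2 + params.c ** 2) ** params.p_exp


def rpi_shape(
    point: Sequence[float],
    domain: NodalDomain,
    params: RpimParams,
    node_ids: Optional[np.ndarray] = None,
) -> ShapeEval:
    """RPI shape functions and their Cartesian derivatives at ``point``.

    The moment system couples the multiquadric basis evaluated between the
    influence nodes with a single constant-augmentation row/column; solving
    it for the basis (and basis-derivative) vectors at the query point
    yields shape functions with the delta property and partition of unity.
    The Lagrange multiplier of the constant constraint is a by-product of
    the solve and is not returned.
    """
    pt = np.asarray(point, dtype=float)
    if node_ids is None:
        node_ids = influence_nodes(pt, domain, params.n_influence)
    nodes = domain.node_coords[node_ids]
    n = nodes.shape[0]
    diff = nodes[:, None, :] - nodes[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    G = np.empty((n + 1, n + 1))
    G[:n, :n] = _multiquadric(d2, params)
    G[n, :n] = 1.0
    G[:n, n] = 1.0
    G[n, n] = 0.0

    dq = nodes - pt[None, :]
    d2q = np.einsum("ij,ij->i", dq, dq)
    base = d2q + params.c ** 2
    r = base ** params.p_exp
    # d r_i / d x at the query point: 2 p (x - x_i) (d^2 + c^2)^(p-1)
    fac = 2.0 * params.p_exp * base ** (params.p_exp - 1.0)
    rhs = np.zeros((n + 1, 3))
    rhs[:n, 0] = r
    rhs[n, 0] = 1.0
    rhs[:n, 1] = fac * (pt[0] - nodes[:, 0])
    rhs[:n, 2] = fac * (pt[1] - nodes[:, 1])
    try:
        sol = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(
            f"singular RPIM moment matrix at point ({pt[0]:.6g}, {pt[1]:.6g})"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise ConditioningError(
            f"ill-conditioned RPIM moment matrix at point ({pt[0]:.6g}, {pt[1]:.6g})"
        )
    return ShapeEval(node_ids=node_ids, values=sol[:n, 0], dx=sol[:n, 1], dy=sol[:n, 2])


@dataclass
class DiffusionProblem:
    """Steady diffusion / Helmholtz problem with a volumetric source.

    ``source_region`` is a predicate mapping an (M, 2) array of points to a
    boolean mask; ``release_rate`` is applied as a volumetric source over
    that region.  ``essential_bcs`` is a list of (node index array, value)
    pairs.  ``reaction_g`` adds the Helmholtz reaction term (0 disables).
    """

    diff_x: float
    diff_y: float
    release_rate: float = 0.0
    source_region: Optional[Callable[[np.ndarray], np.ndarray]] = None
    reaction_g: float = 0.0
    essential_bcs: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.diff_x > 0 and self.diff_y > 0):
            raise ValueError("diffusion coefficients must be positive")
        if self.release_rate < 0:
            raise ValueError("release_rate must be non-negative")


@dataclass
class AssembledSystem:
    """Stiffness matrix and load vector before essential BCs."""

    K: sp.csr_matrix
    f: np.ndarray
    domain: NodalDomain
    params: RpimParams
    problem: DiffusionProblem


class ShapeCache:
    """Incremental cache of per-integration-point shape evaluations.

    During angiogenesis the node cloud only ever grows (sprout nodes are
    appended); an integration point's influence domain can change only if a
    new node lands closer than its current farthest influence node, so only
    those points are re-evaluated.
    """

    def __init__(self) -> None:
        self._n_nodes = 0
        self._evals: Optional[list[ShapeEval]] = None
        self._r_far: Optional[np.ndarray] = None

    def shape_evals(self, domain: NodalDomain, params: RpimParams) -> list[ShapeEval]:
        pts = domain.integration_points
        if pts is None:
            raise InvalidDomainError("integration mesh not built")
        if self._evals is None or domain.n_nodes < self._n_nodes:
            stale = np.arange(pts.shape[0])
            self._evals = [None] * pts.shape[0]  # type: ignore[list-item]
            self._r_far = np.empty(pts.shape[0])
        elif domain.n_nodes == self._n_nodes:
            stale = np.array([], dtype=int)
        else:
            new_nodes = domain.node_coords[self._n_nodes:]
            d_new, _ = cKDTree(new_nodes).query(pts, k=1)
            stale = np.nonzero(d_new <= self._r_far + 1e-12)[0]
        if stale.size:
            ids_all = _influence_bulk(pts[stale], domain, params.n_influence)
            for row, ip in enumerate(stale):
                se = rpi_shape(pts[ip], domain, params, node_ids=ids_all[row])
                self._evals[ip] = se
                d = domain.node_coords[se.node_ids] - pts[ip]
                self._r_far[ip] = np.sqrt(np.max(np.einsum("ij,ij->i", d, d)))
        self._n_nodes = domain.n_nodes
        return self._evals  # type: ignore[return-value]


def assemble_system(
    problem: DiffusionProblem,
    domain: NodalDomain,
    params: RpimParams,
    cache: Optional[ShapeCache] = None,
) -> AssembledSystem:
    """Assemble K = K_D + K_g and the source vector f_q by Gauss quadrature.

    Per integration point I with weight w_I and shape evaluation
    (phi, dphi/dx, dphi/dy):

        K_D += w_I * B^T diag(Dx, Dy) B        (diffusion)
        K_g += w_I * g * phi phi^T             (Helmholtz reaction)
        f_q += w_I * Q * phi                   (points inside source region)

    K is symmetric for this isotropic/orthotropic D.
    """
    pts = domain.integration_points
    if pts is None or pts.shape[0] == 0:
        raise InvalidDomainError("integration mesh is empty; call build_integration_mesh")
    if cache is None:
        cache = ShapeCache()
    evals = cache.shape_evals(domain, params)
    w = domain.weights
    if problem.source_region is not None and problem.release_rate > 0:
        in_src = np.asarray(problem.source_region(pts), dtype=bool)
    else:
        in_src = np.zeros(pts.shape[0], dtype=bool)

    n_inf = params.n_influence
    n_ip = pts.shape[0]
    block = n_inf * n_inf
    rows = np.empty(n_ip * block, dtype=np.int64)
    cols = np.empty(n_ip * block, dtype=np.int64)
    vals = np.empty(n_ip * block)
    f = np.zeros(domain.n_nodes)
    g = problem.reaction_g
    for ip in range(n_ip):
        se = evals[ip]
        local = w[ip] * (
            problem.diff_x * np.outer(se.dx, se.dx)
            + problem.diff_y * np.outer(se.dy, se.dy)
        )
        if g != 0.0:
            local = local + (w[ip] * g) * np.outer(se.values, se.values)
        sl = slice(ip * block, (ip + 1) * block)
        rows[sl] = np.repeat(se.node_ids, n_inf)
        cols[sl] = np.tile(se.node_ids, n_inf)
        vals[sl] = local.ravel()
        if in_src[ip]:
            f[se.node_ids] += w[ip] * problem.release_rate * se.values
    K = sp.coo_matrix((vals, (rows, cols)), shape=(domain.n_nodes, domain.n_nodes)).tocsr()
    return AssembledSystem(K=K, f=f, domain=domain, params=params, problem=problem)


@dataclass
class VegfField:
    """Nodal VEGF concentrations with RPI interpolation and gradients."""

    domain: NodalDomain
    nodal_values: np.ndarray
    params: RpimParams = field(default_factory=RpimParams)

    def interpolate(self, point: Sequence[float]) -> float:
        pt = np.asarray(point, dtype=float)
        if not self.domain.contains(pt):
            raise OutOfDomainError(f"point {pt.tolist()} outside domain bounds")
        se = rpi_shape(pt, self.domain, self.params)
        return float(se.values @ self.nodal_values[se.node_ids])

    def gradient(self, point: Sequence[float]) -> np.ndarray:
        pt = np.asarray(point, dtype=float)
        if not self.domain.contains(pt):
            raise OutOfDomainError(f"point {pt.tolist()} outside domain bounds")
        se = rpi_shape(pt, self.domain, self.params)
        v = self.nodal_values[se.node_ids]
        return np.array([se.dx @ v, se.dy @ v])


def interpolate(fld: VegfField, point: Sequence[float]) -> float:
    """RPI-interpolated field value at ``point`` (delta property at nodes)."""
    return fld.interpolate(point)


def gradient(fld: VegfField, point: Sequence[float]) -> np.ndarray:
    """RPI-interpolated field gradient at ``point`` (mm^-1 units of field)."""
    return fld.gradient(point)


def solve_vegf(
    system: AssembledSystem,
    essential_bcs: Optional[list[tuple[np.ndarray, float]]] = None,
) -> VegfField:
    """Impose essential BCs by row/column elimination and solve for the field.

    With the pure-diffusion problem (g = 0) at least one essential BC is
    required; an unconstrained or otherwise singular system raises with a
    hint to check the boundary conditions.
    """
    bcs = essential_bcs if essential_bcs is not None else system.problem.essential_bcs
    n = system.domain.n_nodes
    fixed_mask = np.zeros(n, dtype=bool)
    fixed_vals = np.zeros(n)
    for ids, value in bcs:
        ids = np.asarray(ids, dtype=int)
        fixed_mask[ids] = True
        fixed_vals[ids] = value
    if not fixed_mask.any() and system.problem.reaction_g == 0.0:
        raise ValueError(
            "no essential boundary conditions given; the pure-diffusion "
            "system is singular — check the BC specification"
        )
    free = ~fixed_mask
    K = system.K.tocsc()
    rhs = system.f[free] - K[free][:, fixed_mask] @ fixed_vals[fixed_mask]
    K_ff = K[free][:, free]
    try:
        u_free = spla.spsolve(K_ff.tocsc(), rhs)
    except RuntimeError as exc:  # umfpack/superlu singular matrix
        raise ValueError(
            "singular constrained diffusion system — check that the "
            "essential boundary conditions constrain every region"
        ) from exc
    if not np.all(np.isfinite(u_free)):
        raise ValueError(
            "diffusion solve produced non-finite values — check the "
            "essential boundary conditions"
        )
    u = np.empty(n)
    u[free] = u_free
    u[fixed_mask] = fixed_vals[fixed_mask]
    return VegfField(domain=system.domain, nodal_values=u, params=system.params)


def write_field_grid(fld: VegfField, path: str) -> None:
    """Export nodal values as a delimited (x, y, value) grid file.

    A JSON sidecar ``<path>.meta.json`` records the domain bounds, node
    count and coordinate convention (mm, lower-left origin).
    """
    data = np.column_stack([fld.domain.node_coords, fld.nodal_values])
    np.savetxt(path, data, delimiter=",", header="x_mm,y_mm,value", comments="")
    meta = {
        "bounds_mm": list(fld.domain.bounds),
        "n_nodes": int(fld.domain.n_nodes),
        "coordinates": "mm, lower-left origin",
    }
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
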