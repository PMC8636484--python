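"""Steady incompressible laminar Navier–Stokes solver on bifurcation meshes.

Solves

    div(v) = 0
    rho (v . grad) v = -grad(p) + mu Lap(v)

with a prescribed inlet velocity profile, no-slip walls and zero-pressure
("do-nothing") outlets, using Taylor–Hood P2/P1 finite elements and Newton
iteration from a Stokes starting guess.  The linearised saddle-point
systems are solved with a sparse direct factorisation.

The physical configuration is a vessel carrying a 3-D volumetric flow
rate Q through a semicircular section; the 2-D mid-plane problem is
driven so that the mid-plane *mean* inlet speed equals the 3-D mean
speed Q/A.  This preserves the velocity scale and the channel Reynolds
number of the 3-D duct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import CrossSection, Mesh, hydraulic_diameter

__all__ = [
    "FluidProperties",
    "BoundaryConditions",
    "SolverSettings",
    "FlowField",
    "FlowSolverError",
    "solve_steady_flow",
    "divergence_norm",
    "flux_through",
    "channel_reynolds",
    "NAMED_MEDIA",
]


class FlowSolverError(RuntimeError):
    """Solver non-convergence or invalid configuration."""


@dataclass(frozen=True)
class FluidProperties:
    """Carrier-medium properties (Newtonian)."""

    density: float            # kg/m^3
    dynamic_viscosity: float  # Pa s
    label: str = ""

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


#: The three perfusion media studied experimentally, at the shear rates of
#: interest (Newtonian approximation).  Densities are taken as water-like.
NAMED_MEDIA = {
    "non_conditioned": FluidProperties(1000.0, 1.46e-3, "non-conditioned medium"),
    "fbs": FluidProperties(1000.0, 1.935e-3, "foetal bovine serum"),
    "methylcellulose": FluidProperties(1000.0, 2.29e-3, "0.5% methylcellulose"),
}


@dataclass(frozen=True)
class BoundaryConditions:
    """Inlet flow rate (3-D, m^3/s), outlet pressure and inlet profile.

    Default flow rate is 3 mL/min; ``cross_section`` (default: the
    semicircular section of the geometry's calibre) converts it to the
    mean speed imposed on the 2-D mid-plane.
    """

    inlet_flow_rate: float = 3.0e-6 / 60.0
    outlet_pressure: float = 0.0
    inlet_profile: str = "parabolic"
    cross_section: Optional[CrossSection] = None

    def __post_init__(self):
        if self.inlet_flow_rate <= 0:
            raise ValueError("inlet flow rate must be positive")
        if self.inlet_profile not in ("parabolic", "uniform"):
            raise ValueError("inlet_profile must be 'parabolic' or 'uniform'")

    def section_for(self, geometry) -> CrossSection:
        if self.cross_section is not None:
            return self.cross_section
        return CrossSection("semicircle", (geometry.calibre,))

    def mean_speed(self, geometry) -> float:
        """3-D mean speed Q/A, imposed as the 2-D mean inlet speed."""
        return self.inlet_flow_rate / self.section_for(geometry).area


@dataclass
class SolverSettings:
    tolerance: float = 1.0e-5     # relative momentum/continuity residual
    max_newton: int = 30
    reynolds_guard: float = 500.0


# ---------------------------------------------------------------------------
# P2 space and reference-element tables
# ---------------------------------------------------------------------------

# 7-point degree-5 quadrature on the reference triangle
_QW = np.array([0.1125] + [0.0661970763942531] * 3 + [0.0629695902724136] * 3)
_a1, _b1 = 0.0597158717897698, 0.4701420641051151
_a2, _b2 = 0.7974269853530873, 0.1012865073234563
_QP = np.array([
    [1 / 3, 1 / 3],
    [_a1, _b1], [_b1, _a1], [_b1, _b1],
    [_a2, _b2], [_b2, _a2], [_b2, _b2],
])


def _p2_tables():
    xi, eta = _QP[:, 0], _QP[:, 1]
    lam = np.stack([1 - xi - eta, xi, eta], axis=1)         # (nq, 3)
    N = np.empty((len(_QP), 6))
    for k in range(3):
        N[:, k] = lam[:, k] * (2 * lam[:, k] - 1)
    N[:, 3] = 4 * lam[:, 0] * lam[:, 1]
    N[:, 4] = 4 * lam[:, 1] * lam[:, 2]
    N[:, 5] = 4 * lam[:, 2] * lam[:, 0]
    # gradients of barycentric coords wrt (xi, eta)
    dlam = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # (3, 2)
    dN = np.empty((len(_QP), 6, 2))
    for k in range(3):
        dN[:, k, :] = (4 * lam[:, k, None] - 1) * dlam[k]
    dN[:, 3, :] = 4 * (lam[:, 0, None] * dlam[1] + lam[:, 1, None] * dlam[0])
    dN[:, 4, :] = 4 * (lam[:, 1, None] * dlam[2] + lam[:, 2, None] * dlam[1])
    dN[:, 5, :] = 4 * (lam[:, 2, None] * dlam[0] + lam[:, 0, None] * dlam[2])
    return N, dN, lam


_N, _DN, _LAM = _p2_tables()


class P2Space:
    """Quadratic velocity space over a triangular mesh.

    Node ordering: mesh vertices first, then one node per unique edge
    (the edge midpoint).  ``elem_nodes`` lists, per triangle, local
    nodes [v0, v1, v2, m01, m12, m20].
    """

    def __init__(self, mesh: Mesh):
        tris = mesh.triangles
        pairs = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
        pairs_sorted = np.sort(pairs, axis=1)
        edges, inv = np.unique(pairs_sorted, axis=0, return_inverse=True)
        nv = len(mesh.points)
        ne = len(edges)
        self.mesh = mesh
        self.n_vertices = nv
        self.edges = edges
        self.n_nodes = nv + ne
        mid_ids = inv.reshape(3, -1).T + nv      # (nt, 3): m01, m12, m20
        self.elem_nodes = np.hstack([tris, mid_ids])
        self.node_coords = np.vstack([
            mesh.points,
            0.5 * (mesh.points[edges[:, 0]] + mesh.points[edges[:, 1]]),
        ])
        self.edge_index = {tuple(e): nv + i for i, e in enumerate(edges)}

        coords = mesh.points[tris]               # (nt, 3, 2)
        J = np.stack([coords[:, 1] - coords[:, 0],
                      coords[:, 2] - coords[:, 0]], axis=1)  # (nt,2,2) rows d x/d xi
        self.detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        if np.any(self.detJ <= 0):
            raise FlowSolverError("mesh contains inverted or degenerate cells")
        invJ = np.empty_like(J)
        invJ[:, 0, 0] = J[:, 1, 1]
        invJ[:, 0, 1] = -J[:, 0, 1]
        invJ[:, 1, 0] = -J[:, 1, 0]
        invJ[:, 1, 1] = J[:, 0, 0]
        invJ /= self.detJ[:, None, None]
        # physical gradients of P2 basis: (nt, nq, 6, 2); dN/dx_i = invJ[i,a] dN/dxi_a
        self.grad = np.einsum("qba,eia->eqbi", _DN, invJ)
        self.wdet = _QW[None, :] * np.abs(self.detJ)[:, None]   # (nt, nq)

    def interpolate_many(self, nodal: np.ndarray) -> np.ndarray:
        """Values of a P2 field at all quadrature points, (nt, nq)."""
        return np.einsum("qb,eb->eq", _N, nodal[self.elem_nodes])


def _scatter(space: P2Space, local: np.ndarray, rows_nodes, cols_nodes, shape):
    nt = len(space.elem_nodes)
    r = rows_nodes[:, :, None].repeat(local.shape[2], axis=2)
    c = cols_nodes[:, None, :].repeat(local.shape[1], axis=1)
    return sp.coo_matrix((local.ravel(), (r.ravel(), c.ravel())), shape=shape).tocsr()


# ---------------------------------------------------------------------------
# Flow field container
# ---------------------------------------------------------------------------

@dataclass
class FlowField:
    """Converged (or partially converged) discrete velocity/pressure field.

    ``velocity`` holds (n_p2_nodes, 2) values; the first ``n_vertices``
    rows are the mesh-vertex values used by interpolation, export and
    particle tracking.  ``pressure`` is vertex-based (P1).
    """

    mesh: Mesh
    space: P2Space
    velocity: np.ndarray
    pressure: np.ndarray
    residuals: list
    converged: bool
    fluid: FluidProperties
    bc: BoundaryConditions
    mean_inlet_speed: float

    @property
    def vertex_velocity(self) -> np.ndarray:
        return self.velocity[: self.space.n_vertices]

    @property
    def vertex_speed(self) -> np.ndarray:
        v = self.vertex_velocity
        return np.hypot(v[:, 0], v[:, 1])

    def max_speed(self) -> float:
        return float(np.hypot(self.velocity[:, 0], self.velocity[:, 1]).max())


# ---------------------------------------------------------------------------
# Dirichlet data
# ---------------------------------------------------------------------------

def _dirichlet_data(mesh: Mesh, space: P2Space, bc: BoundaryConditions):
    """Node indices and velocity values for inlet and wall boundaries."""
    geom = mesh.geometry
    w = geom.calibre
    vbar = bc.mean_speed(geom)

    def nodes_for(tag):
        nodes = set()
        for i, j in mesh.boundary_edges[mesh.boundary_tags == tag]:
            nodes.add(i)
            nodes.add(j)
            nodes.add(space.edge_index[(min(i, j), max(i, j))])
        return np.array(sorted(nodes), dtype=int)

    wall_nodes = nodes_for("wall")
    inlet_nodes = nodes_for("inlet")
    y = space.node_coords[inlet_nodes, 1]
    if bc.inlet_profile == "parabolic":
        ux = 1.5 * vbar * (1.0 - (2.0 * y / w) ** 2)
    else:
        ux = np.full_like(y, vbar)
    # wall takes precedence at shared corner nodes
    inlet_mask = ~np.isin(inlet_nodes, wall_nodes)
    idx = np.concatenate([wall_nodes, inlet_nodes[inlet_mask]])
    vals = np.zeros((len(idx), 2))
    vals[len(wall_nodes):, 0] = ux[inlet_mask]
    return idx, vals


# ---------------------------------------------------------------------------
# Main solver
# ---------------------------------------------------------------------------

def channel_reynolds(fluid: FluidProperties, bc: BoundaryConditions,
                     cross_section: CrossSection) -> float:
    """Channel Reynolds number Re = rho vbar D_h / mu of the 3-D duct."""
    area = cross_section.area
    if area <= 0:
        raise ValueError("cross-section area must be positive")
    vbar = bc.inlet_flow_rate / area
    return fluid.density * vbar * hydraulic_diameter(cross_section) / fluid.dynamic_viscosity


def solve_steady_flow(mesh: Mesh, fluid: FluidProperties, bc: BoundaryConditions,
                      settings: Optional[SolverSettings] = None) -> FlowField:
    """Solve the steady laminar flow problem on ``mesh``.

    Newton iteration on the convective term, starting from the Stokes
    solution; residuals (relative to the boundary-data load norm) are
    recorded per iteration and must drop below ``settings.tolerance``.

    Raises
    ------
    FlowSolverError
        If the configuration violates the laminar-regime guard or Newton
        fails to converge within ``max_newton`` iterations (the residual
        history is attached to the exception).
    """
    settings = settings or SolverSettings()
    geom = mesh.geometry
    re = channel_reynolds(fluid, bc, bc.section_for(geom))
    if re >= settings.reynolds_guard:
        raise FlowSolverError(
            f"channel Reynolds number {re:.1f} exceeds solver regime guard "
            f"{settings.reynolds_guard:.0f}")

    space = P2Space(mesh)
    n2 = space.n_nodes
    nv = space.n_vertices
    ndof = 2 * n2 + nv
    rho, mu = fluid.density, fluid.dynamic_viscosity

    en = space.elem_nodes
    ev = mesh.triangles
    wdet = space.wdet            # (nt, nq)
    grad = space.grad            # (nt, nq, 6, 2)

    # constant matrices: viscous K (n2 x n2) and divergence B_i (nv x n2)
    K_loc = mu * np.einsum("eq,eqai,eqbi->eab", wdet, grad, grad)
    K = _scatter(space, K_loc, en, en, (n2, n2))
    Bx_loc = np.einsum("eq,qa,eqb->eab", wdet, _LAM, grad[..., 0])
    By_loc = np.einsum("eq,qa,eqb->eab", wdet, _LAM, grad[..., 1])
    Bx = _scatter(space, Bx_loc, ev, en, (nv, n2))
    By = _scatter(space, By_loc, ev, en, (nv, n2))

    # Dirichlet handling
    dir_nodes, dir_vals = _dirichlet_data(mesh, space, bc)
    dir_dofs = np.concatenate([dir_nodes, n2 + dir_nodes])
    free = np.ones(ndof, dtype=bool)
    free[dir_dofs] = False
    keep = sp.diags(free.astype(float))
    pin = sp.diags((~free).astype(float))

    U = np.zeros(ndof)
    U[dir_nodes] = dir_vals[:, 0]
    U[n2 + dir_nodes] = dir_vals[:, 1]

    def residual_and_conv(U, need_matrix):
        ux, uy, p = U[:n2], U[n2:2 * n2], U[2 * n2:]
        uxe, uye = ux[en], uy[en]                       # (nt, 6)
        ux_q = np.einsum("qb,eb->eq", _N, uxe)
        uy_q = np.einsum("qb,eb->eq", _N, uye)
        gux = np.einsum("eqbi,eb->eqi", grad, uxe)      # grad ux at q
        guy = np.einsum("eqbi,eb->eqi", grad, uye)
        conv_x = ux_q * gux[..., 0] + uy_q * gux[..., 1]
        conv_y = ux_q * guy[..., 0] + uy_q * guy[..., 1]
        Fx_loc = rho * np.einsum("eq,qa,eq->ea", wdet, _N, conv_x)
        Fy_loc = rho * np.einsum("eq,qa,eq->ea", wdet, _N, conv_y)
        Fx = np.bincount(en.ravel(), (Fx_loc).ravel(), minlength=n2)
        Fy = np.bincount(en.ravel(), (Fy_loc).ravel(), minlength=n2)
        F = np.empty(ndof)
        F[:n2] = Fx + K @ ux - Bx.T @ p
        F[n2:2 * n2] = Fy + K @ uy - By.T @ p
        F[2 * n2:] = Bx @ ux + By @ uy
        if not need_matrix:
            return F, None
        # Newton matrix of the convective term
        adv = np.einsum("eq,qa,eq,eqb->eab", wdet, _N, ux_q, grad[..., 0]) \
            + np.einsum("eq,qa,eq,eqb->eab", wdet, _N, uy_q, grad[..., 1])
        Cxx = np.einsum("eq,qa,eq,qb->eab", wdet, _N, gux[..., 0], _N)
        Cxy = np.einsum("eq,qa,eq,qb->eab", wdet, _N, gux[..., 1], _N)
        Cyx = np.einsum("eq,qa,eq,qb->eab", wdet, _N, guy[..., 0], _N)
        Cyy = np.einsum("eq,qa,eq,qb->eab", wdet, _N, guy[..., 1], _N)
        A = _scatter(space, rho * (adv + Cxx), en, en, (n2, n2)) + K
        Axy = _scatter(space, rho * Cxy, en, en, (n2, n2))
        Ayx = _scatter(space, rho * Cyx, en, en, (n2, n2))
        Ayy = _scatter(space, rho * (adv + Cyy), en, en, (n2, n2)) + K
        Jmat = sp.bmat([[A, Axy, -Bx.T], [Ayx, Ayy, -By.T], [Bx, By, None]],
                       format="csr")
        return F, Jmat

    # residual scale: load norm of the boundary-driven Stokes problem
    F0, _ = residual_and_conv(U, False)
    scale = np.linalg.norm(F0[free.nonzero()[0]])
    if scale == 0.0:
        scale = 1.0

    def solve_linear(Jmat, F):
        A = keep @ Jmat @ keep + pin
        rhs = -F * free
        delta = spla.spsolve(A.tocsc(), rhs)
        return delta

    residuals = []
    # Stokes start: drop convection entirely
    Stokes = sp.bmat([[K, None, -Bx.T], [None, K, -By.T], [Bx, By, None]], format="csr")
    Fs = Stokes @ U
    U = U + solve_linear(Stokes, Fs)

    converged = False
    for _ in range(settings.max_newton):
        F, Jmat = residual_and_conv(U, True)
        rel = np.linalg.norm(F[free.nonzero()[0]]) / scale
        residuals.append(rel)
        if rel < settings.tolerance:
            converged = True
            break
        U = U + solve_linear(Jmat, F)
    if not converged:
        raise FlowSolverError(
            f"Newton iteration failed to reach {settings.tolerance:g} "
            f"(residual history: {residuals})")

    velocity = np.column_stack([U[:n2], U[n2:2 * n2]])
    return FlowField(mesh=mesh, space=space, velocity=velocity,
                     pressure=U[2 * n2:], residuals=residuals, converged=True,
                     fluid=fluid, bc=bc, mean_inlet_speed=bc.mean_speed(geom))


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def divergence_norm(flowfield: FlowField, mesh: Mesh) -> float:
    """Discrete L2 norm of div(v) over the domain, in 1/s."""
    space = flowfield.space
    if space.mesh is not mesh:
        raise ValueError("flow field was not computed on this mesh")
    en = space.elem_nodes
    ux = flowfield.velocity[:, 0][en]
    uy = flowfield.velocity[:, 1][en]
    div = np.einsum("eqb,eb->eq", space.grad[..., 0], ux) \
        + np.einsum("eqb,eb->eq", space.grad[..., 1], uy)
    return float(np.sqrt(np.sum(space.wdet * div ** 2)))


def flux_through(flowfield: FlowField, mesh: Mesh, boundary_tag: str) -> float:
    """Signed volumetric flux (m^2/s per unit depth), outward positive.

    Integrates the quadratic velocity trace with Simpson's rule, exact
    for P2.
    """
    edges = mesh.boundary_edges_for(boundary_tag)
    space = flowfield.space
    # owning triangle centroid fixes the outward normal orientation
    tri_of = {}
    for t, tri in enumerate(mesh.triangles):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            key = (min(tri[a], tri[b]), max(tri[a], tri[b]))
            tri_of.setdefault(key, t)
    total = 0.0
    for i, j in edges:
        key = (min(i, j), max(i, j))
        mid_node = space.edge_index[key]
        pi, pj = mesh.points[i], mesh.points[j]
        tvec = pj - pi
        L = np.hypot(*tvec)
        nrm = np.array([tvec[1], -tvec[0]]) / L
        c = mesh.points[mesh.triangles[tri_of[key]]].mean(axis=0)
        midpt = 0.5 * (pi + pj)
        if np.dot(nrm, midpt - c) < 0:
            nrm = -nrm
        un = (np.dot(flowfield.velocity[i], nrm),
              np.dot(flowfield.velocity[mid_node], nrm),
              np.dot(flowfield.velocity[j], nrm))
        total += L * (un[0] + 4.0 * un[1] + un[2]) / 6.0
    return float(total)
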