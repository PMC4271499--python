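"""Steady incompressible saline-film flow (axisymmetric Stokes).

The irrigation film moves at millimetres per second through sub-millimetre
thicknesses, so the Reynolds number is of order one or below and a creeping
(Stokes) linearization of the incompressible Navier-Stokes equations is used.
The discretization is the MINI element (P1 + cubic bubble velocity, P1
pressure) with the bubble statically condensed element by element, in the
full stress form so the open-boundary natural condition is zero traction.

Boundary conditions follow the irrigation setup: prescribed normal velocity
on the inflow band of the electrode wall, no slip on the saline-tissue
interface and the rest of the electrode wall, and an open (zero-traction)
boundary on the film surface and the outer rim.  With the open surface most
of the injected saline drains close to the electrode and the outer film is
nearly stagnant, which is what keeps the far tissue surface in contact with
slowly moving, conductively heated saline.  The discrete nodal inflow is
rescaled so the boundary flux equals the nominal volumetric rate exactly.

:func:`solve_stokes` also accepts an impermeable slip surface (penalty on
``u.n``) used by the contained annular-film fixture, whose
``Q/(2 pi r S)`` closed form assumes the film cannot drain through its
surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import TWO_PI, edge_normal_flux, outward_edge_normals
from .geometry import SALINE, Geometry
from .mesh import AxisymmetricMesh

# 7-point degree-5 triangle rule (barycentric coordinates, weights sum to 1)
_QW = np.array([0.225] + [0.13239415278850618] * 3 + [0.12593918054482715] * 3)
_a1, _b1 = 0.05971587178976982, 0.47014206410511505
_a2, _b2 = 0.7974269853530873, 0.10128650732345633
_QP = np.array([
    [1 / 3, 1 / 3, 1 / 3],
    [_a1, _b1, _b1], [_b1, _a1, _b1], [_b1, _b1, _a1],
    [_a2, _b2, _b2], [_b2, _a2, _b2], [_b2, _b2, _a2],
])


class FlowError(RuntimeError):
    pass


def inflow_velocity(drop_rate: float, drops_per_mL: float,
                    inflow_area: float) -> float:
    """Inflow speed (m/s) from a drip rate.

    ``drop_rate`` in drops/s, ``drops_per_mL`` drops per millilitre,
    ``inflow_area`` the wetted electrode area in m^2 through which the saline
    enters the film.
    """
    if min(drop_rate, drops_per_mL, inflow_area) <= 0:
        raise ValueError("all inflow parameters must be positive")
    Q = drop_rate / drops_per_mL * 1e-6  # m^3/s
    return Q / inflow_area


@dataclass
class VelocityField:
    """Steady film velocity on the full mesh (zero outside the saline)."""

    u: np.ndarray                   # (N, 2) nodal (u_r, u_z), m/s
    p: np.ndarray                   # pressure on the saline submesh nodes, Pa
    sub_nodes: np.ndarray           # full-mesh ids of the saline submesh nodes
    inflow_flux: float              # m^3/s through the inflow band
    outflow_flux: float             # m^3/s through the open boundaries
    density: float = 1004.0
    viscosity: float = 1.0e-3
    residual: float = 0.0


def _element_matrices(points, tris, mu):
    """Condensed MINI element blocks: Ann' (6x6), Bn' (3x6), C' (3x3)."""
    p = points[tris]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    area = 0.5 * det
    g = np.empty((len(tris), 3, 2))
    g[:, 1, 0] = d2[:, 1] / det
    g[:, 1, 1] = -d2[:, 0] / det
    g[:, 2, 0] = -d1[:, 1] / det
    g[:, 2, 1] = d1[:, 0] / det
    g[:, 0] = -g[:, 1] - g[:, 2]

    M = len(tris)
    A = np.zeros((M, 8, 8))     # dofs: [r: n1 n2 n3 b, z: n1 n2 n3 b]
    B = np.zeros((M, 3, 8))
    for lam, wq in zip(_QP, _QW):
        N = np.empty((M, 4))
        N[:, :3] = lam
        N[:, 3] = 27.0 * lam[0] * lam[1] * lam[2]
        GN = np.empty((M, 4, 2))
        GN[:, :3] = g
        GN[:, 3] = 27.0 * (lam[1] * lam[2] * g[:, 0]
                           + lam[2] * lam[0] * g[:, 1]
                           + lam[0] * lam[1] * g[:, 2])
        r = p[:, :, 0] @ lam
        if (r <= 0).any():
            raise FlowError("flow domain touches the axis r = 0")
        w = (wq * area * r * TWO_PI)
        Gr, Gz = GN[:, :, 0], GN[:, :, 1]
        Nr = N / r[:, None]
        arr = 2 * (Gr[:, :, None] * Gr[:, None, :]
                   + Nr[:, :, None] * Nr[:, None, :]) \
            + Gz[:, :, None] * Gz[:, None, :]
        azz = 2 * Gz[:, :, None] * Gz[:, None, :] \
            + Gr[:, :, None] * Gr[:, None, :]
        arz = Gz[:, :, None] * Gr[:, None, :]
        wmu = (w * mu)[:, None, None]
        A[:, :4, :4] += wmu * arr
        A[:, 4:, 4:] += wmu * azz
        A[:, :4, 4:] += wmu * arz
        A[:, 4:, :4] += wmu * arz.transpose(0, 2, 1)
        NL = N[:, :3]
        divr = Gr + Nr
        B[:, :, :4] -= w[:, None, None] * NL[:, :, None] * divr[:, None, :]
        B[:, :, 4:] -= w[:, None, None] * NL[:, :, None] * Gz[:, None, :]

    nidx = [0, 1, 2, 4, 5, 6]
    bidx = [3, 7]
    Ann = A[:, nidx][:, :, nidx]
    Anb = A[:, nidx][:, :, bidx]
    Abn = A[:, bidx][:, :, nidx]
    Abb = A[:, bidx][:, :, bidx]
    Bn = B[:, :, nidx]
    Bb = B[:, :, bidx]
    det_b = Abb[:, 0, 0] * Abb[:, 1, 1] - Abb[:, 0, 1] * Abb[:, 1, 0]
    inv = np.empty_like(Abb)
    inv[:, 0, 0] = Abb[:, 1, 1] / det_b
    inv[:, 1, 1] = Abb[:, 0, 0] / det_b
    inv[:, 0, 1] = -Abb[:, 0, 1] / det_b
    inv[:, 1, 0] = -Abb[:, 1, 0] / det_b
    AnnC = Ann - np.einsum('eib,ebc,ecj->eij', Anb, inv, Abn)
    BnC = Bn - np.einsum('epb,ebc,ecj->epj', Bb, inv, Abn)
    CC = -np.einsum('epb,ebc,eqc->epq', Bb, inv, Bb)
    return AnnC, BnC, CC


def slip_penalty(points: np.ndarray, edges: np.ndarray, normals: np.ndarray,
                 mu: float, n_nodes: int, factor: float = 1e10) -> sp.coo_matrix:
    """Penalty enforcing impermeability u.n = 0 on a free (slip) surface.

    Adds ``kappa int (u.n)(v.n) r ds`` with ``kappa = factor * mu / ell`` per
    edge; the tangential direction stays traction free.
    """
    p0, p1 = points[edges[:, 0]], points[edges[:, 1]]
    ell = np.hypot(*(p1 - p0).T)
    r0, r1 = p0[:, 0], p1[:, 0]
    kappa = factor * mu / ell
    # edge mass matrix entries, weighted 2 pi r
    m00 = TWO_PI * kappa * ell * (3 * r0 + r1) / 12.0
    m11 = TWO_PI * kappa * ell * (r0 + 3 * r1) / 12.0
    m01 = TWO_PI * kappa * ell * (r0 + r1) / 12.0
    rows, cols, vals = [], [], []
    for (ia, ib), m in (((0, 0), m00), ((0, 1), m01), ((1, 0), m01),
                        ((1, 1), m11)):
        na, nb = edges[:, ia], edges[:, ib]
        for ca in range(2):
            for cb in range(2):
                rows.append(na + ca * n_nodes)
                cols.append(nb + cb * n_nodes)
                vals.append(m * normals[:, ca] * normals[:, cb])
    return sp.coo_matrix((np.concatenate(vals),
                          (np.concatenate(rows), np.concatenate(cols))),
                         shape=(3 * n_nodes, 3 * n_nodes))


def solve_stokes(points: np.ndarray, tris: np.ndarray,
                 dirichlet: dict[int, tuple[float, float]],
                 mu: float = 1.0e-3,
                 slip: tuple[np.ndarray, np.ndarray] | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Stokes solve on a triangulation away from the axis.

    ``dirichlet`` maps node id -> (u_r, u_z); ``slip`` is an optional
    ``(edges, outward_normals)`` pair of impermeable free-surface edges.
    Returns nodal velocity (n,2) and nodal pressure (n,).
    """
    n = len(points)
    AnnC, BnC, CC = _element_matrices(points, tris, mu)

    def scatter(blocks, rows, cols, shape):
        r = np.broadcast_to(rows[:, :, None], blocks.shape).reshape(-1)
        c = np.broadcast_to(cols[:, None, :], blocks.shape).reshape(-1)
        return sp.coo_matrix((blocks.reshape(-1), (r, c)), shape=shape)

    vel = np.concatenate([tris, tris + n], axis=1)      # 6 velocity dofs
    pre = tris + 2 * n
    N = 3 * n
    K = (scatter(AnnC, vel, vel, (N, N))
         + scatter(BnC, pre, vel, (N, N))
         + scatter(BnC.transpose(0, 2, 1), vel, pre, (N, N))
         + scatter(CC, pre, pre, (N, N)))
    if slip is not None and len(slip[0]):
        K = K + slip_penalty(points, slip[0], slip[1], mu, n)
    K = K.tocsr()

    fixed = np.array(sorted(dirichlet), dtype=np.int64)
    vals_r = np.array([dirichlet[i][0] for i in fixed])
    vals_z = np.array([dirichlet[i][1] for i in fixed])
    fixed_dofs = np.concatenate([fixed, fixed + n])
    fixed_vals = np.concatenate([vals_r, vals_z])

    x = np.zeros(N)
    x[fixed_dofs] = fixed_vals
    free = np.ones(N, dtype=bool)
    free[fixed_dofs] = False
    fi = np.flatnonzero(free)
    Kc = K.tocsc()
    rhs = -Kc[fi][:, fixed_dofs] @ fixed_vals
    x[fi] = spla.spsolve(Kc[fi][:, fi], rhs)
    u = np.column_stack([x[:n], x[n:2 * n]])
    p = x[2 * n:]
    return u, p


def solve_saline_flow(mesh: AxisymmetricMesh, inflow_speed: float = 5.3e-3,
                      mu: float = 1.0e-3, rho: float = 1004.0) -> VelocityField:
    """Steady film velocity for the irrigated-electrode geometry.

    ``inflow_speed`` is the nominal normal velocity on the inflow band; the
    discrete nodal values are rescaled so the boundary flux equals
    ``inflow_speed * inflow_area`` exactly.
    """
    geom: Geometry = mesh.geom
    emask = mesh.material == SALINE
    if not emask.any():
        raise FlowError("mesh has no saline subdomain")
    sub_tris_full = mesh.triangles[emask]
    sub_nodes = np.unique(sub_tris_full)
    remap = -np.ones(mesh.n_points, dtype=np.int64)
    remap[sub_nodes] = np.arange(len(sub_nodes))
    tris = remap[sub_tris_full]
    pts = mesh.points[sub_nodes]

    tol = 1e-7 * geom.a
    z = pts[:, 1]
    r = pts[:, 0]
    on_tissue = np.abs(z) < tol
    # film inner boundary: electrode wall below the equator, void crevice above
    on_wall = (np.abs(r - geom.a) < tol) & ~on_tissue
    z_hi, z_lo = geom.inflow_band()
    # the node at the film-surface corner z = -L keeps the slip condition so
    # no prescribed inflow pierces the free surface
    in_band = on_wall & (z > z_hi + tol) & (z <= z_lo + tol)

    dirichlet: dict[int, tuple[float, float]] = {}
    for i in np.flatnonzero(on_tissue | on_wall):
        dirichlet[int(i)] = (0.0, 0.0)
    if inflow_speed != 0.0:
        for i in np.flatnonzero(in_band):
            dirichlet[int(i)] = (inflow_speed, 0.0)  # radial, off the wall

    # classify the submesh boundary: walls, inflow band, impermeable free
    # surface (slip) and the open outer rim where the film drains
    sub = AxisymmetricMesh(points=pts, triangles=tris,
                           material=np.zeros(len(tris), np.int8))
    bedges, bowners = sub.boundary_edges
    bc = sub.centroids[bowners]
    nrm = outward_edge_normals(pts, bedges, bc)
    mid = 0.5 * (pts[bedges[:, 0]] + pts[bedges[:, 1]])
    e_on_wall = np.abs(mid[:, 0] - geom.a) < tol
    e_on_tissue = np.abs(mid[:, 1]) < tol
    e_rim = np.abs(mid[:, 0] - geom.Rs) < tol
    e_free = ~(e_on_wall | e_on_tissue)  # open: film surface and outer rim
    e_in = e_on_wall & (mid[:, 1] >= z_hi - tol) & (mid[:, 1] <= z_lo + tol)

    u, p = solve_stokes(pts, tris, dirichlet, mu)

    if inflow_speed != 0.0:
        flux_in = -edge_normal_flux(pts, bedges[e_in], u, nrm[e_in])
        target = inflow_speed * geom.params.inflow_area
        if flux_in <= 0:
            raise FlowError("inflow band produced no influx")
        scale = target / flux_in
        for i in np.flatnonzero(in_band):
            ur, uz = dirichlet[int(i)]
            dirichlet[int(i)] = (ur * scale, uz * scale)
        u, p = solve_stokes(pts, tris, dirichlet, mu)
        flux_in = -edge_normal_flux(pts, bedges[e_in], u, nrm[e_in])
    else:
        flux_in = 0.0
    flux_out = edge_normal_flux(pts, bedges[e_free], u, nrm[e_free])

    u_full = np.zeros((mesh.n_points, 2))
    u_full[sub_nodes] = u
    return VelocityField(u=u_full, p=p, sub_nodes=sub_nodes,
                         inflow_flux=flux_in, outflow_flux=flux_out,
                         density=rho, viscosity=mu)
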