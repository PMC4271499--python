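"""Analytic-solution fixtures: small meshes with closed-form references.

Each fixture provides a mesh compatible with the solvers plus an evaluator of
the exact solution, so every solver can be verified against an independent
closed form without running the full device pipeline.  All fixtures are
deterministic and parameterized; nothing in the project uses randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .mesh import rectangle_mesh

FIXTURE_NAMES = ("concentric_spheres", "slab_conduction_1d",
                 "annular_film_flow", "gaussian_temperature_field")


@dataclass
class AnalyticFixture:
    name: str
    points: np.ndarray
    triangles: np.ndarray
    params: dict
    reference: Callable
    boundary_nodes: dict[str, np.ndarray] = field(default_factory=dict)
    reference_scalar: float | None = None


def concentric_spheres(a: float = 1e-3, b: float = 10e-3, sigma: float = 1.0,
                       n_rho: int = 40, n_theta: int = 32) -> AnalyticFixture:
    """Conduction between concentric spheres (axisymmetric half-annulus).

    The exact potential is ``V(rho) = V0 (1/rho - 1/b) / (1/a - 1/b)`` and the
    resistance ``R = (1/a - 1/b) / (4 pi sigma)``.
    """
    rho = np.geomspace(a, b, n_rho + 1)
    theta = np.linspace(0.0, math.pi, n_theta + 1)
    P, T = np.meshgrid(rho, theta, indexing="ij")
    pts = np.column_stack([(P * np.sin(T)).ravel(), (P * np.cos(T)).ravel()])
    tris = []
    for i in range(n_rho):
        for j in range(n_theta):
            n00 = i * (n_theta + 1) + j
            n01 = n00 + 1
            n10 = n00 + (n_theta + 1)
            n11 = n10 + 1
            tris.append((n00, n10, n11))
            tris.append((n00, n11, n01))
    tris = np.asarray(tris, np.int64)
    p = pts[tris]
    ar = 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    tris[ar < 0] = tris[ar < 0][:, [0, 2, 1]]
    pts[:, 0] = np.maximum(pts[:, 0], 0.0)  # clip sin(pi) roundoff

    rr = np.hypot(pts[:, 0], pts[:, 1])
    inner = np.flatnonzero(np.abs(rr - a) < 1e-9 * a)
    outer = np.flatnonzero(np.abs(rr - b) < 1e-9 * b)

    def V_exact(r, z, V0=1.0):
        rho = np.hypot(r, z)
        return V0 * (1.0 / rho - 1.0 / b) / (1.0 / a - 1.0 / b)

    return AnalyticFixture(
        name="concentric_spheres", points=pts, triangles=tris,
        params=dict(a=a, b=b, sigma=sigma), reference=V_exact,
        boundary_nodes=dict(inner=inner, outer=outer),
        reference_scalar=(1.0 / a - 1.0 / b) / (4.0 * math.pi * sigma))


def slab_conduction_1d(thickness: float = 10e-3, r_center: float = 1.0,
                       width: float = 2e-3, k: float = 0.5,
                       rho_c: float = 3.6e6, T0: float = 80.0,
                       T_face: float = 20.0, nz: int = 60,
                       nr: int = 2) -> AnalyticFixture:
    """Transient conduction in a slab with both faces clamped.

    Placed far from the axis (``r_center >> width``) so the axisymmetric
    weight is effectively constant and the classical Fourier-series solution
    applies: ``T = T_face + (T0-T_face) sum_odd 4/(n pi) sin(n pi z/d)
    exp(-n^2 pi^2 alpha t / d^2)``.
    """
    pts, tris = rectangle_mesh(r_center - width / 2, r_center + width / 2,
                               0.0, thickness, nr, nz)
    faces = np.flatnonzero((np.abs(pts[:, 1]) < 1e-12)
                           | (np.abs(pts[:, 1] - thickness) < 1e-12))
    alpha = k / rho_c

    def T_exact(z, t, n_terms=200):
        z = np.asarray(z, float)
        out = np.zeros_like(z)
        for n in range(1, n_terms, 2):
            out += 4.0 / (n * math.pi) * np.sin(n * math.pi * z / thickness) \
                * math.exp(-(n * math.pi / thickness) ** 2 * alpha * t)
        return T_face + (T0 - T_face) * out

    return AnalyticFixture(
        name="slab_conduction_1d", points=pts, triangles=tris,
        params=dict(thickness=thickness, k=k, rho_c=rho_c, T0=T0,
                    T_face=T_face, alpha=alpha),
        reference=T_exact, boundary_nodes=dict(faces=faces))


def annular_film_flow(r1: float = 2e-3, r2: float = 10e-3, S: float = 0.6e-3,
                      inflow_speed: float = 5.3e-3, nr: int = 60,
                      nz: int = 6) -> AnalyticFixture:
    """Uniform-thickness annular film fed radially at the inner rim.

    Mass conservation forces the thickness-averaged radial speed to
    ``Q / (2 pi r S)`` with ``Q = 2 pi r1 S v_in``, regardless of viscosity.
    No slip at the bottom (tissue), free surface on top, open outer rim.
    """
    pts, tris = rectangle_mesh(r1, r2, -S, 0.0, nr, nz)
    inner = np.flatnonzero(np.abs(pts[:, 0] - r1) < 1e-12)
    bottom = np.flatnonzero(np.abs(pts[:, 1]) < 1e-12)
    Q = 2.0 * math.pi * r1 * S * inflow_speed

    def mean_speed(r):
        return Q / (2.0 * math.pi * np.asarray(r, float) * S)

    return AnalyticFixture(
        name="annular_film_flow", points=pts, triangles=tris,
        params=dict(r1=r1, r2=r2, S=S, inflow_speed=inflow_speed, Q=Q),
        reference=mean_speed,
        boundary_nodes=dict(inflow=inner, no_slip=bottom))


def gaussian_temperature_field(w: float = 3e-3, extent: float = 12e-3,
                               peak: float = 100.0, n: int = 80) -> AnalyticFixture:
    """Radially symmetric synthetic temperature bump on a quarter plane.

    ``T(r, z) = peak exp(-(r^2+z^2)/w^2)``; the level-``c`` contour is the
    circle of radius ``w sqrt(ln(peak/c))``.
    """
    pts, tris = rectangle_mesh(0.0, extent, 0.0, extent, n, n)

    def T_field(r, z):
        return peak * np.exp(-(np.asarray(r) ** 2 + np.asarray(z) ** 2) / w ** 2)

    def contour_radius(level):
        return w * math.sqrt(math.log(peak / level))

    fx = AnalyticFixture(
        name="gaussian_temperature_field", points=pts, triangles=tris,
        params=dict(w=w, peak=peak), reference=T_field)
    fx.params["contour_radius"] = contour_radius
    return fx


def make_fixture(name: str, **params) -> AnalyticFixture:
    """Build a fixture by name; see :data:`FIXTURE_NAMES`."""
    table = {
        "concentric_spheres": concentric_spheres,
        "slab_conduction_1d": slab_conduction_1d,
        "annular_film_flow": annular_film_flow,
        "gaussian_temperature_field": gaussian_temperature_field,
    }
    if name not in table:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return table[name](**params)
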