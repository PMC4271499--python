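"""Saline-film Stokes solver: inflow law, mass conservation, film decay."""

import numpy as np
import pytest
from matplotlib.tri import LinearTriInterpolator, Triangulation

from salinerf import make_config
from salinerf.driver import build_model
from salinerf.fixtures import annular_film_flow
from salinerf.flow import inflow_velocity, solve_saline_flow, solve_stokes

Q_NOMINAL = 5e-8  # m^3/s, one drop per second at 20 drops/mL


@pytest.fixture(scope="module")
def device_mesh():
    _, mesh, _ = build_model(make_config("ex_vivo"))
    return mesh


@pytest.fixture(scope="module")
def film_field(device_mesh):
    return solve_saline_flow(device_mesh, inflow_speed=5.3e-3)


def _solve_annulus(nr=50, nz=6, mu=1e-3):
    fx = annular_film_flow(nr=nr, nz=nz)
    dirichlet = {int(i): (0.0, 0.0) for i in fx.boundary_nodes["no_slip"]}
    v = fx.params["inflow_speed"]
    for i in fx.boundary_nodes["inflow"]:
        dirichlet[int(i)] = (v, 0.0)
    # impermeable slip surface on top; the outer rim stays open
    S = fx.params["S"]
    top = np.flatnonzero(np.abs(fx.points[:, 1] + S) < 1e-12)
    top = top[np.argsort(fx.points[top, 0])]
    slip_edges = np.column_stack([top[:-1], top[1:]])
    normals = np.tile([0.0, -1.0], (len(slip_edges), 1))
    u, p = solve_stokes(fx.points, fx.triangles, dirichlet, mu=mu,
                        slip=(slip_edges, normals))
    return fx, u


def _mean_radial_speed(fx, u, r):
    tri = Triangulation(fx.points[:, 0], fx.points[:, 1], fx.triangles)
    interp = LinearTriInterpolator(tri, u[:, 0])
    S = fx.params["S"]
    zs = np.linspace(-S * 0.999, -S * 0.001, 50)
    vals = interp(np.full_like(zs, r), zs)
    return float(np.mean(vals))


class TestInflowVelocity:
    def test_drip_rate_conversion(self):
        # 1 drop/s at 20 drops/mL through 9.4e-6 m^2 -> Q = 3 mL/min, ~5.3 mm/s
        v = inflow_velocity(1.0, 20.0, 9.4e-6)
        assert v * 9.4e-6 == pytest.approx(Q_NOMINAL)
        assert v == pytest.approx(5.3e-3, rel=5e-3)

    def test_linear_in_drop_rate(self):
        assert inflow_velocity(2.0, 20.0, 9.4e-6) == \
            pytest.approx(2 * inflow_velocity(1.0, 20.0, 9.4e-6))

    def test_inverse_in_area(self):
        assert inflow_velocity(1.0, 20.0, 4.7e-6) == \
            pytest.approx(1.06e-2, rel=5e-3)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            inflow_velocity(0.0, 20.0, 9.4e-6)


class TestAnnularFilm:
    def test_mean_speed_follows_mass_conservation(self):
        # thickness-averaged radial speed = Q / (2 pi r S), the 1/r film decay
        fx, u = _solve_annulus()
        for r in (3e-3, 5e-3, 8e-3):
            assert _mean_radial_speed(fx, u, r) == \
                pytest.approx(float(fx.reference(r)), rel=5e-2)

    def test_refinement_stability(self):
        fx1, u1 = _solve_annulus(nr=40, nz=5)
        fx2, u2 = _solve_annulus(nr=80, nz=10)
        r = np.linspace(2.5e-3, 9.5e-3, 15)
        v1 = np.array([_mean_radial_speed(fx1, u1, ri) for ri in r])
        v2 = np.array([_mean_radial_speed(fx2, u2, ri) for ri in r])
        assert np.linalg.norm(v1 - v2) / np.linalg.norm(v2) < 0.03

    def test_viscosity_independent_flux(self):
        fx1, u1 = _solve_annulus(mu=1e-3)
        fx2, u2 = _solve_annulus(mu=1e-2)
        r = 6e-3
        assert _mean_radial_speed(fx1, u1, r) == \
            pytest.approx(_mean_radial_speed(fx2, u2, r), rel=1e-2)


class TestDeviceFilm:
    def test_global_mass_balance(self, film_field):
        assert film_field.inflow_flux == pytest.approx(Q_NOMINAL, rel=1e-2)
        assert film_field.outflow_flux == \
            pytest.approx(film_field.inflow_flux, rel=1e-2)

    def test_zero_inflow_gives_zero_velocity(self, device_mesh):
        vf = solve_saline_flow(device_mesh, inflow_speed=0.0)
        assert np.abs(vf.u).max() == 0.0
        assert vf.inflow_flux == 0.0

    def test_velocity_confined_to_saline(self, film_field, device_mesh):
        outside = np.setdiff1d(np.arange(device_mesh.n_points),
                               film_field.sub_nodes)
        assert np.abs(film_field.u[outside]).max() == 0.0

    def test_no_slip_at_tissue_interface(self, film_field, device_mesh):
        iface = np.unique(device_mesh.edge_labels["saline_tissue_interface"])
        assert np.abs(film_field.u[iface]).max() < 1e-12

    def test_speed_decays_with_radius(self, film_field, device_mesh):
        # volume conservation in the thin film forces ~1/r decay
        pts = device_mesh.points[film_field.sub_nodes]
        u = film_field.u[film_field.sub_nodes]
        speed = np.hypot(u[:, 0], u[:, 1])
        geom = device_mesh.geom

        def peak(r0, r1):
            sel = (pts[:, 0] > r0) & (pts[:, 0] < r1)
            return speed[sel].max()

        near = peak(geom.a, geom.a + 2e-3)
        mid = peak(10e-3, 15e-3)
        far = peak(30e-3, 45e-3)
        assert near > 3 * mid > 3 * far
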