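"""Quasi-static potential solver: closed forms, power balance, field laws."""

import numpy as np
import pytest

from salinerf import electrical, make_config
from salinerf.driver import _sigma_elements, build_model
from salinerf.fem import P1Fem
from salinerf.fixtures import concentric_spheres
from salinerf.geometry import ELECTRODE, SALINE, TISSUE
from salinerf.mesh import rectangle_mesh


@pytest.fixture(scope="module")
def spheres():
    fx = concentric_spheres(a=1.5e-3, b=50e-3, sigma=0.27, n_rho=60, n_theta=40)
    fem = P1Fem(fx.points, fx.triangles)
    sigma = np.full(len(fx.triangles), fx.params["sigma"])
    sol = electrical.solve_potential(fem, sigma, 47.0,
                                     fx.boundary_nodes["inner"],
                                     fx.boundary_nodes["outer"])
    return fx, sol


@pytest.fixture(scope="module")
def ex_vivo_static():
    cfg = make_config("ex_vivo")
    geom, mesh, fem = build_model(cfg)
    sigma = _sigma_elements(mesh, cfg.materials(),
                            np.full(mesh.n_elements, 24.0))
    sol = electrical.solve_potential(fem, sigma, cfg.V0,
                                     electrical.electrode_nodes(mesh),
                                     electrical.ground_nodes(mesh))
    return mesh, sol


class TestClosedForms:
    def test_concentric_spheres_resistance(self, spheres):
        fx, sol = spheres
        Z = electrical.compute_impedance(sol)
        assert Z == pytest.approx(fx.reference_scalar, rel=1e-2)

    def test_concentric_spheres_potential(self, spheres):
        fx, sol = spheres
        Vex = fx.reference(fx.points[:, 0], fx.points[:, 1], V0=47.0)
        assert np.max(np.abs(sol.V - Vex)) < 0.01 * 47.0

    def test_discrete_maximum_principle(self, spheres):
        _, sol = spheres
        assert sol.V.min() >= -1e-9
        assert sol.V.max() <= 47.0 + 1e-9

    def test_uniform_slab_field(self):
        # V0 across a slab of thickness d -> |E| = V0/d everywhere
        d = 5e-3
        pts, tris = rectangle_mesh(1.0, 1.01, 0.0, d, 4, 20)
        fem = P1Fem(pts, tris)
        top = np.flatnonzero(np.abs(pts[:, 1]) < 1e-12)
        bot = np.flatnonzero(np.abs(pts[:, 1] - d) < 1e-12)
        sol = electrical.solve_potential(fem, np.full(len(tris), 0.5), 10.0,
                                         top, bot)
        E, J, sar = electrical.derive_fields(sol)
        assert np.allclose(np.hypot(E[:, 0], E[:, 1]), 10.0 / d, rtol=1e-9)
        assert (sar >= 0).all()

    def test_zero_voltage_means_zero_fields(self, spheres):
        fx, _ = spheres
        fem = P1Fem(fx.points, fx.triangles)
        sigma = np.full(len(fx.triangles), 1.0)
        sol = electrical.solve_potential(fem, sigma, 0.0,
                                         fx.boundary_nodes["inner"],
                                         fx.boundary_nodes["outer"])
        _, _, sar = electrical.derive_fields(sol)
        assert np.allclose(sol.V, 0.0)
        assert np.allclose(sar, 0.0)


class TestPowerAndImpedance:
    def test_power_balance_volume_vs_boundary(self, ex_vivo_static):
        _, sol = ex_vivo_static
        P_vol = electrical.total_power(sol)
        P_bnd = sol.V0 * electrical.boundary_current(sol)
        assert P_vol == pytest.approx(P_bnd, rel=1e-2)

    def test_sigma_scaling_halves_impedance(self, spheres):
        fx, sol = spheres
        fem = sol.fem
        sol2 = electrical.solve_potential(fem, 2.0 * sol.sigma_elem, 47.0,
                                          fx.boundary_nodes["inner"],
                                          fx.boundary_nodes["outer"])
        assert electrical.compute_impedance(sol2) == pytest.approx(
            0.5 * electrical.compute_impedance(sol), rel=1e-12)

    def test_impedance_monotone_in_subdomain_sigma(self, ex_vivo_static):
        mesh, sol = ex_vivo_static
        Z = electrical.compute_impedance(sol)
        for mat in (SALINE, TISSUE):
            sigma = sol.sigma_elem.copy()
            sigma[mesh.material == mat] *= 1.2
            sol2 = electrical.solve_potential(sol.fem, sigma, sol.V0,
                                              sol.active_nodes, sol.ground_nodes)
            assert electrical.compute_impedance(sol2) < Z

    def test_missing_electrode_rejected(self, spheres):
        fx, sol = spheres
        with pytest.raises(electrical.ElectricalError):
            electrical.solve_potential(sol.fem, sol.sigma_elem, 47.0,
                                       np.array([], dtype=int),
                                       fx.boundary_nodes["outer"])


class TestDeviceFields:
    def test_sar_peaks_in_tissue_next_to_tip(self, ex_vivo_static):
        mesh, sol = ex_vivo_static
        _, _, sar = electrical.derive_fields(sol)
        tmask = mesh.material == TISSUE
        e = np.flatnonzero(tmask)[np.argmax(sar[tmask])]
        c = mesh.centroids[e]
        geom = mesh.geom
        dist_to_tip = abs(np.hypot(c[0], c[1] - geom.zc) - geom.a)
        assert dist_to_tip < 0.5e-3  # within half a millimetre of the tip

    def test_current_density_higher_in_saline(self, ex_vivo_static):
        mesh, sol = ex_vivo_static
        _, J, _ = electrical.derive_fields(sol)
        Jm = np.hypot(J[:, 0], J[:, 1])
        assert Jm[mesh.material == SALINE].mean() > \
            Jm[mesh.material == TISSUE].mean()

    def test_electrode_is_equipotential(self, ex_vivo_static):
        mesh, sol = ex_vivo_static
        nodes = np.unique(mesh.triangles[mesh.material == ELECTRODE])
        assert np.allclose(sol.V[nodes], sol.V0)
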