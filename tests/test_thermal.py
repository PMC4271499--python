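"""Bioheat solver: analytic conduction, energy conservation, perfusion."""

import numpy as np
import pytest

from salinerf.fem import P1Fem
from salinerf.fixtures import slab_conduction_1d
from salinerf.materials import MaterialModel, default_materials
from salinerf.mesh import AxisymmetricMesh, rectangle_mesh
from salinerf.thermal import (T_SHUTOFF, ThermalProblem, perfusion_term)


def _uniform_problem(pts, tris, k=0.5, rho_c=3.6e6, **kw):
    mesh = AxisymmetricMesh(points=pts, triangles=tris,
                            material=np.zeros(len(tris), np.int8))
    fem = P1Fem(pts, tris)
    mat = MaterialModel("tissue", k=k, c_liquid=rho_c, rho_liquid=1.0,
                        sigma37=1.0)
    mats = {n: mat for n in ("tissue", "saline", "electrode", "plastic")}
    return mesh, fem, ThermalProblem(mesh, fem, mats, T_ambient=kw.pop(
        "T_ambient", 0.0), cooled_labels=(), **kw)


class TestConduction:
    def test_equilibrium_is_preserved(self):
        pts, tris = rectangle_mesh(0.0, 0.02, 0.0, 0.02, 6, 6)
        _, _, tp = _uniform_problem(pts, tris, T_ambient=24.0)
        st = tp.initial_state(24.0)
        for _ in range(5):
            st = tp.step(st, 0.0, 0.5)
        assert np.allclose(st.T, 24.0, atol=1e-10)

    def test_slab_matches_fourier_series(self):
        fx = slab_conduction_1d(nz=120)
        faces = fx.boundary_nodes["faces"]
        _, _, tp = _uniform_problem(
            fx.points, fx.triangles, k=fx.params["k"],
            rho_c=fx.params["rho_c"],
            dirichlet=(faces, np.full(len(faces), fx.params["T_face"])))
        st = tp.initial_state(fx.params["T0"])
        while st.t < 30.0 - 1e-9:
            st = tp.step(st, 0.0, 0.5)
        Texact = fx.reference(fx.points[:, 1], st.t)
        scale = fx.params["T0"] - fx.params["T_face"]
        assert np.max(np.abs(st.T - Texact)) < 0.01 * scale

    def test_no_spurious_undershoot(self):
        fx = slab_conduction_1d(nz=60)
        faces = fx.boundary_nodes["faces"]
        _, _, tp = _uniform_problem(
            fx.points, fx.triangles, k=fx.params["k"], rho_c=fx.params["rho_c"],
            dirichlet=(faces, np.full(len(faces), fx.params["T_face"])))
        st = tp.initial_state(fx.params["T0"])
        for _ in range(10):
            st = tp.step(st, 0.0, 1.0)
            assert st.T.min() >= fx.params["T_face"] - 1e-9


class TestEnergyBalance:
    def test_insulated_heating_conserves_energy(self):
        # total enthalpy gain equals the integrated volumetric source
        pts, tris = rectangle_mesh(0.5, 0.52, 0.0, 0.02, 4, 20)
        mesh, fem, tp = _uniform_problem(pts, tris)
        st = tp.initial_state(20.0)
        q, dt, n = 5e6, 0.25, 40
        for _ in range(n):
            st = tp.step(st, q, dt)
        E_in = q * fem.integrate(np.ones(len(tris))) * dt * n
        gained = float(np.sum(fem.lumped(np.full(len(tris), 3.6e6))
                              * (st.T - 20.0)))
        assert gained == pytest.approx(E_in, rel=1e-2)

    def test_latent_heat_absorbed_across_vaporization(self):
        # stepping across 99-100 degC must account the transition enthalpy
        pts, tris = rectangle_mesh(0.5, 0.51, 0.0, 0.01, 2, 4)
        mesh = AxisymmetricMesh(points=pts, triangles=tris,
                                material=np.zeros(len(tris), np.int8))
        fem = P1Fem(pts, tris)
        mats = default_materials()
        tp = ThermalProblem(mesh, fem, mats, T_ambient=95.0, cooled_labels=())
        st = tp.initial_state(95.0)
        q, dt, n = 2e7, 0.5, 175
        for _ in range(n):
            st = tp.step(st, q, dt, n_corrections=2)
        E_in = q * fem.integrate(np.ones(len(tris))) * dt * n
        t = mats["tissue"]
        gained = float(np.sum(
            fem.lumped(np.ones(len(tris)))
            * (t.enthalpy(st.T) - t.enthalpy(95.0))))
        assert st.T.mean() > 100.0  # the band was actually crossed
        assert gained == pytest.approx(E_in, rel=2e-2)


class TestPerfusion:
    def test_closed_form_values(self):
        assert perfusion_term(37.0, 1.0) == 0.0
        assert perfusion_term(45.0, 1.0) == pytest.approx(
            1000.0 * 4180.0 * 6.4e-3 * (37.0 - 45.0))
        assert perfusion_term(55.0, 0.0) == 0.0

    def test_viability_switch_is_irreversible(self):
        pts, tris = rectangle_mesh(0.5, 0.52, 0.0, 0.02, 4, 8)
        mesh, fem, tp = _uniform_problem(pts, tris, perfusion=True)
        st = tp.initial_state(45.0)
        assert np.all(st.beta == 1.0)
        # heat above the 50 degC shutoff...
        for _ in range(20):
            st = tp.step(st, 2e7, 0.5)
        assert st.Tmax_seen.max() >= T_SHUTOFF
        assert np.all(st.beta[st.Tmax_seen >= T_SHUTOFF] == 0.0)
        dead = st.beta.copy()
        # ...then let it cool: beta must not recover
        for _ in range(20):
            st = tp.step(st, 0.0, 2.0)
        assert np.array_equal(st.beta <= dead, np.ones_like(dead, bool))

    def test_perfusion_cools_toward_blood_temperature(self):
        pts, tris = rectangle_mesh(0.5, 0.52, 0.0, 0.02, 4, 8)
        _, _, tp_on = _uniform_problem(pts, tris, perfusion=True)
        _, _, tp_off = _uniform_problem(pts, tris)
        s_on, s_off = tp_on.initial_state(45.0), tp_off.initial_state(45.0)
        for _ in range(10):
            s_on = tp_on.step(s_on, 0.0, 0.5)
            s_off = tp_off.step(s_off, 0.0, 0.5)
        assert s_on.T.max() < s_off.T.max()
        assert s_on.T.min() > 37.0 - 1e-9
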