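"""Transient bioheat solver in enthalpy form.

Advances ``rho dh/dt = div(k grad T) - rho_s c_s (u . grad T) + q + Q_p`` with
backward-Euler steps.  The enthalpy nonlinearity is handled with a secant
effective heat capacity: within each step the per-element capacity is
re-evaluated from the enthalpy difference between the predicted and previous
temperatures (one fixed-point correction by default), which conserves the
latent heat of the 99-100 degC vaporization band even when a step jumps
across it.

The convective term is active only in the saline subdomain and uses saline
density and specific heat; the perfusion sink ``Q_p = beta rho_b c_b omega_b
(T_b - T)`` acts in tissue with the viability switch ``beta`` dropping
irreversibly to zero once an element has reached 50 degC.  Boundaries carry
Newton cooling ``q_c = h_e (T - T_a)`` on the exposed outer surfaces and are
insulated elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .fem import P1Fem, solve_dirichlet
from .geometry import MATERIAL_NAMES, SALINE, TISSUE
from .materials import MaterialModel
from .mesh import AxisymmetricMesh

# blood properties of the perfusion term
RHO_BLOOD = 1000.0      # kg/m^3
C_BLOOD = 4180.0        # J/(kg K)
T_BLOOD = 37.0          # degC
OMEGA_BLOOD = 6.4e-3    # 1/s
T_SHUTOFF = 50.0        # degC: perfusion stops irreversibly above this

H_CONVECTION = 20.0     # W/(m^2 K), free convection coefficient

#: boundary labels that receive Newton cooling by default
COOLED_LABELS = ("plastic_outer", "electrode_active", "tissue_top",
                 "saline_free_surface")


def perfusion_term(T, beta):
    """Pennes perfusion heat source, W/m^3 (negative above blood temperature)."""
    return beta * RHO_BLOOD * C_BLOOD * OMEGA_BLOOD * (T_BLOOD - np.asarray(T))


@dataclass
class ThermalState:
    T: np.ndarray               # nodal temperature, degC
    t: float                    # time, s
    beta: np.ndarray            # per-element viability switch in {0, 1}
    Tmax_seen: np.ndarray       # per-element running maximum (mean) temperature


class ThermalProblem:
    """Assembled operators of the bioheat equation on one mesh.

    Parameters
    ----------
    velocity:
        Nodal saline velocity (N,2); ``None`` disables convection.
    perfusion:
        Enable the blood-perfusion sink in the tissue subdomain.
    cooled_labels:
        Boundary labels receiving Newton cooling (the saline free surface can
        be excluded to restrict cooling to the solid surfaces).
    dirichlet:
        Optional ``(nodes, values)`` fixed-temperature set (used by the
        analytic conduction fixtures; the device scenarios have none).
    """

    def __init__(self, mesh: AxisymmetricMesh, fem: P1Fem,
                 materials: dict[str, MaterialModel], *,
                 T_ambient: float,
                 velocity: np.ndarray | None = None,
                 perfusion: bool = False,
                 h_conv: float = H_CONVECTION,
                 cooled_labels: tuple[str, ...] = COOLED_LABELS,
                 dirichlet: tuple[np.ndarray, np.ndarray] | None = None,
                 stabilize: bool = True):
        self.mesh = mesh
        self.fem = fem
        self.materials = materials
        self.T_ambient = float(T_ambient)
        self.mat_elem = mesh.material
        self.k_elem = np.array([materials[MATERIAL_NAMES[m]].k
                                for m in self.mat_elem])
        self.K = fem.stiffness(self.k_elem)

        self.C = None
        if velocity is not None and np.abs(velocity).max() > 0:
            rho_c = np.where(self.mat_elem == SALINE,
                             materials["saline"].rho_liquid
                             * materials["saline"].c_liquid, 0.0)
            self.C = fem.convection(velocity, rho_c, self.k_elem,
                                    stabilize=stabilize)

        edges = [mesh.edge_labels[l] for l in cooled_labels
                 if l in mesh.edge_labels]
        if edges and h_conv > 0:
            self.R, self.r_w = fem.robin(np.concatenate(edges), h_conv)
        else:
            self.R, self.r_w = sp.csr_matrix((fem.n, fem.n)), np.zeros(fem.n)

        self.perfusion = perfusion
        if perfusion:
            coef = np.where(self.mat_elem == TISSUE,
                            RHO_BLOOD * C_BLOOD * OMEGA_BLOOD, 0.0)
            self._perf_coef = coef
        self.dirichlet = dirichlet

    # -- material laws, vectorized over elements -----------------------------

    def capacity(self, Tbar: np.ndarray) -> np.ndarray:
        out = np.empty(len(Tbar))
        for m, name in enumerate(MATERIAL_NAMES):
            sel = self.mat_elem == m
            if sel.any():
                out[sel] = self.materials[name].effective_volumetric_heat(Tbar[sel])
        return out

    def _enthalpy(self, Tbar: np.ndarray) -> np.ndarray:
        out = np.empty(len(Tbar))
        for m, name in enumerate(MATERIAL_NAMES):
            sel = self.mat_elem == m
            if sel.any():
                out[sel] = self.materials[name].enthalpy(Tbar[sel])
        return out

    def secant_capacity(self, T_old: np.ndarray, T_new: np.ndarray) -> np.ndarray:
        dT = T_new - T_old
        small = np.abs(dT) < 1e-9
        with np.errstate(divide='ignore', invalid='ignore'):
            c = (self._enthalpy(T_new) - self._enthalpy(T_old)) / dT
        c[small] = self.capacity(T_old)[small]
        return c

    # -- stepping -------------------------------------------------------------

    def initial_state(self, T_init: float) -> ThermalState:
        n_el = self.mesh.n_elements
        return ThermalState(T=np.full(self.fem.n, float(T_init)), t=0.0,
                            beta=np.ones(n_el), Tmax_seen=np.full(n_el, float(T_init)))

    def element_mean(self, T: np.ndarray) -> np.ndarray:
        return T[self.mesh.triangles].mean(axis=1)

    def _solve_once(self, T_old: np.ndarray, cap: np.ndarray, f_sar: np.ndarray,
                    beta: np.ndarray, dt: float) -> np.ndarray:
        M = self.fem.lumped(cap)
        A = sp.diags(M / dt) + self.K + self.R
        rhs = M / dt * T_old + f_sar + self.r_w * self.T_ambient
        if self.C is not None:
            A = A + self.C
        if self.perfusion:
            pv = self.fem.lumped(self._perf_coef * beta)
            A = A + sp.diags(pv)
            rhs = rhs + pv * T_BLOOD
        if self.dirichlet is not None:
            return solve_dirichlet(A.tocsr(), rhs, *self.dirichlet)
        return sp.linalg.spsolve(A.tocsr(), rhs)

    def _advance(self, T_old: np.ndarray, f_sar: np.ndarray, beta: np.ndarray,
                 dt: float, n_corrections: int, tol: float, max_iter: int,
                 depth: int) -> np.ndarray:
        """Damped secant capacity iteration; sub-steps in the transition band.

        If the iteration fails to settle (a step jumping across the sharp
        99-100 degC band makes the secant oscillate), the step is split into
        two half steps so the latent heat is absorbed consistently.
        """
        Tbar_old = self.element_mean(T_old)
        cap = self.capacity(Tbar_old)
        T_new, T_prev = T_old, None
        for it in range(max_iter):
            T_new = self._solve_once(T_old, cap, f_sar, beta, dt)
            if T_prev is not None and np.max(np.abs(T_new - T_prev)) < tol \
                    and it >= n_corrections:
                return T_new
            cap = 0.5 * (cap + self.secant_capacity(
                Tbar_old, self.element_mean(T_new)))
            T_prev = T_new
        if depth >= 8:
            raise RuntimeError(
                "enthalpy iteration failed to converge in the transition band "
                f"even at dt = {dt:.3g} s")
        half = self._advance(T_old, f_sar, beta, dt / 2, n_corrections,
                             tol, max_iter, depth + 1)
        return self._advance(half, f_sar, beta, dt / 2, n_corrections,
                             tol, max_iter, depth + 1)

    def step(self, state: ThermalState, sar_elem: np.ndarray | float,
             dt: float, n_corrections: int = 1, tol: float = 0.01,
             max_iter: int = 8) -> ThermalState:
        """One backward-Euler step of length ``dt``.

        In smooth regions the capacity loop exits after ``n_corrections``
        extra solves; crossing the vaporization band triggers additional
        damped iterations and, if needed, recursive ``dt`` halving.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        sar = np.broadcast_to(np.asarray(sar_elem, float), (self.mesh.n_elements,))
        f_sar = self.fem.load(sar)
        T_new = self._advance(state.T, f_sar, state.beta, dt,
                              n_corrections, tol, max_iter, 0)
        Tbar_new = self.element_mean(T_new)
        Tmax = np.maximum(state.Tmax_seen, Tbar_new)
        beta = np.where(Tmax >= T_SHUTOFF, 0.0, state.beta)
        return ThermalState(T=T_new, t=state.t + dt, beta=beta, Tmax_seen=Tmax)
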