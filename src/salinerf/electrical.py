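"""Quasi-static RF electrical problem: div(sigma grad V) = 0.

At ~500 kHz liver behaves almost purely resistively, so the potential obeys
the Laplace equation with the instantaneous conductivity field.  The metal
electrode (sigma = 1e8 S/m) is effectively equipotential: every node touching
a metal element carries the applied voltage; the dispersive (return) electrode
under the tissue is the grounded bottom boundary.  The volumetric heat source
is the specific absorption rate q = sigma |E|^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import P1Fem, solve_dirichlet
from .geometry import ELECTRODE
from .mesh import AxisymmetricMesh


class ElectricalError(RuntimeError):
    pass


@dataclass
class PotentialSolution:
    """Nodal potential with the conductivity field it was solved for."""

    V: np.ndarray               # nodal potential, volt
    sigma_elem: np.ndarray      # per-element conductivity, S/m
    V0: float                   # applied voltage
    fem: P1Fem
    active_nodes: np.ndarray
    ground_nodes: np.ndarray
    _K = None                   # cached stiffness (set by solve_potential)


def electrode_nodes(mesh: AxisymmetricMesh) -> np.ndarray:
    nodes = np.unique(mesh.triangles[mesh.material == ELECTRODE])
    if len(nodes) == 0:
        raise ElectricalError("mesh has no electrode elements")
    return nodes


def ground_nodes(mesh: AxisymmetricMesh) -> np.ndarray:
    """Dispersive-electrode nodes: the bottom boundary z = H."""
    H = mesh.geom.H
    nodes = np.flatnonzero(np.abs(mesh.points[:, 1] - H) < 1e-9 * H)
    if len(nodes) == 0:
        raise ElectricalError("no dispersive boundary nodes found")
    return nodes


def solve_potential(fem: P1Fem, sigma_elem: np.ndarray, V0: float,
                    active: np.ndarray, ground: np.ndarray) -> PotentialSolution:
    """Solve the axisymmetric Laplace problem with Dirichlet electrodes.

    ``active`` nodes are clamped to ``V0``, ``ground`` nodes to 0 V; all other
    boundaries are natural (insulating).
    """
    if (sigma_elem <= 0).any():
        raise ElectricalError("conductivity must be positive everywhere")
    if len(active) == 0 or len(ground) == 0:
        raise ElectricalError("both electrodes need at least one node")
    K = fem.stiffness(sigma_elem)
    fixed = np.concatenate([active, ground])
    vals = np.concatenate([np.full(len(active), float(V0)),
                           np.zeros(len(ground))])
    V = solve_dirichlet(K, np.zeros(fem.n), fixed, vals)
    sol = PotentialSolution(V=V, sigma_elem=sigma_elem, V0=float(V0), fem=fem,
                            active_nodes=active, ground_nodes=ground)
    sol._K = K
    return sol


def derive_fields(sol: PotentialSolution):
    """Element-wise E = -grad V (V/m), J = sigma E (A/m^2), SAR (W/m^3)."""
    E = -sol.fem.gradient(sol.V)
    J = sol.sigma_elem[:, None] * E
    sar = sol.sigma_elem * np.einsum('ek,ek->e', E, E)
    return E, J, sar


def total_power(sol: PotentialSolution) -> float:
    """Delivered RF power: volume integral of the SAR, watt."""
    _, _, sar = derive_fields(sol)
    return sol.fem.integrate(sar)


def boundary_current(sol: PotentialSolution) -> float:
    """Current through the circuit from the discrete flux residual.

    Measured at the dispersive (ground) boundary: the active-electrode rows
    involve the metal conductivity of 1e8 S/m and their residuals are
    dominated by floating-point cancellation, while the ground rows only see
    tissue-scale conductivities.
    """
    if sol._K is None:
        sol._K = sol.fem.stiffness(sol.sigma_elem)
    resid = sol._K @ sol.V
    return float(-resid[sol.ground_nodes].sum())


def compute_impedance(sol: PotentialSolution) -> float:
    """Z = V0^2 / P (power method), ohm."""
    if sol.V0 <= 0:
        raise ElectricalError("impedance needs V0 > 0")
    P = total_power(sol)
    if P <= 0:
        raise ElectricalError("zero delivered power")
    return sol.V0 ** 2 / P
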