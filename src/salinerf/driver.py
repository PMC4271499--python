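"""Scenario orchestration: the coupled electric-thermal-flow simulation.

A run builds the geometry and mesh, solves the steady saline flow once, and
then marches the coupled problem with a staggered scheme per time step:
evaluate sigma(T_n) element-wise, solve the quasi-static potential, deposit
the SAR, and advance the bioheat equation to T_{n+1}.  The applied voltage is
held constant (constant-voltage protocol); the impedance trace is sampled at
every step.  Everything is deterministic.

Scenario presets
----------------
``ex_vivo``          flow on, perfusion off, 24 degC (bench conditions)
``zero_flow``        as ex vivo but with the saline velocity set to zero
``in_vivo_perfused`` flow on, perfusion on, 37 degC body temperature
``in_vivo_clamped``  37 degC but perfusion removed (vascular clamping)
``no_saline_contact``    static contact geometry without the film
``fully_inserted``       calibration topology: conductive length in tissue
``submerged_in_saline``  calibration topology: electrode in a saline tank
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from . import electrical, flow, postprocess
from .fem import P1Fem
from .geometry import MATERIAL_NAMES, GeometryParams, build_geometry
from .materials import MaterialModel, default_materials
from .mesh import AxisymmetricMesh, generate_mesh
from .thermal import ThermalProblem

SCENARIOS = ("ex_vivo", "in_vivo_perfused", "in_vivo_clamped", "zero_flow",
             "no_saline_contact", "fully_inserted", "submerged_in_saline")

_PRESETS: dict[str, dict] = {
    "ex_vivo": dict(flow_on=True, perfusion_on=False, T_init=24.0),
    "zero_flow": dict(flow_on=False, perfusion_on=False, T_init=24.0),
    "in_vivo_perfused": dict(flow_on=True, perfusion_on=True, T_init=37.0),
    "in_vivo_clamped": dict(flow_on=True, perfusion_on=False, T_init=37.0),
    "no_saline_contact": dict(flow_on=False, perfusion_on=False, T_init=24.0,
                              with_saline=False),
    "fully_inserted": dict(flow_on=False, perfusion_on=False, T_init=24.0,
                           topology="fully_inserted", with_saline=False),
    "submerged_in_saline": dict(flow_on=False, perfusion_on=False, T_init=20.0,
                                topology="submerged_in_saline", with_saline=False),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one scenario run (deterministic, seedless)."""

    scenario: str = "ex_vivo"
    V0: float = 47.0                 # applied RMS voltage
    duration: float = 20.0           # s
    dt: float = 0.1                  # s
    alpha: float = 1.0               # sigma temperature coefficient, %/degC
    T_init: float = 24.0             # degC
    T_ambient: float | None = None   # degC; None -> T_init
    flow_on: bool = True
    perfusion_on: bool = False
    geometry: GeometryParams = field(default_factory=GeometryParams)
    h_interface: float = 0.085       # mm, finest element size
    grading: float = 1.35
    drop_rate: float = 1.0           # drops/s
    drops_per_mL: float = 20.0
    viscosity: float = 1.0e-3        # Pa s
    saline_model: str = "irrigated"  # or "tissue_like" above 99 degC
    cool_saline_surface: bool = True
    snapshot_interval: float = 5.0   # s
    n_corrections: int = 1           # enthalpy fixed-point corrections per step

    @property
    def ambient(self) -> float:
        return self.T_init if self.T_ambient is None else self.T_ambient

    def materials(self) -> dict[str, MaterialModel]:
        mats = default_materials(self.alpha)
        if self.saline_model == "tissue_like":
            t = mats["tissue"]
            mats["saline"] = replace(mats["saline"], rehydrated=False,
                                     c_gas=t.c_gas, rho_gas=t.rho_gas,
                                     water_fraction=t.water_fraction)
        elif self.saline_model != "irrigated":
            raise ValueError(f"unknown saline model {self.saline_model!r}")
        return mats


def make_config(scenario: str, **overrides) -> SimulationConfig:
    """Scenario preset with optional field overrides."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    preset = dict(_PRESETS[scenario])
    topology = preset.pop("topology", "surface_contact")
    with_saline = preset.pop("with_saline", True)
    geo = overrides.pop("geometry", GeometryParams())
    geo = dataclasses.replace(geo, scenario_topology=topology,
                              with_saline=with_saline)
    preset.update(overrides)
    return SimulationConfig(scenario=scenario, geometry=geo, **preset)


@dataclass
class SimulationResult:
    config: SimulationConfig
    mesh: AxisymmetricMesh
    times: np.ndarray                 # s, length n_steps + 1
    impedance: np.ndarray             # ohm, same length
    Tmax: dict[str, np.ndarray]       # per-subdomain max temperature traces
    snapshots: dict[float, np.ndarray]
    T_final: np.ndarray
    velocity: flow.VelocityField | None
    lesion: postprocess.LesionMetrics | None
    lesion50: postprocess.LesionMetrics | None
    power: np.ndarray | None = None   # delivered power trace, W

    @property
    def Z0(self) -> float:
        return float(self.impedance[0])


def _sigma_elements(mesh: AxisymmetricMesh, mats: dict[str, MaterialModel],
                    Tbar: np.ndarray) -> np.ndarray:
    sigma = np.empty(mesh.n_elements)
    for m, name in enumerate(MATERIAL_NAMES):
        sel = mesh.material == m
        if sel.any():
            sigma[sel] = mats[name].electrical_conductivity(Tbar[sel])
    return sigma


def build_model(config: SimulationConfig):
    """Geometry, mesh and FEM operators for a configuration."""
    geom = build_geometry(config.geometry)
    mesh = generate_mesh(geom, h_interface=config.h_interface,
                         grading=config.grading)
    fem = P1Fem(mesh.points, mesh.triangles)
    return geom, mesh, fem


def static_impedance(config: SimulationConfig, T: float | None = None,
                     mesh: AxisymmetricMesh | None = None,
                     fem: P1Fem | None = None) -> float:
    """Impedance of the configuration at a uniform temperature (no heating)."""
    if mesh is None or fem is None:
        _, mesh, fem = build_model(config)
    mats = config.materials()
    Tu = config.T_init if T is None else T
    sigma = _sigma_elements(mesh, mats, np.full(mesh.n_elements, float(Tu)))
    sol = electrical.solve_potential(fem, sigma, config.V0,
                                     electrical.electrode_nodes(mesh),
                                     electrical.ground_nodes(mesh))
    return electrical.compute_impedance(sol)


def run(config: SimulationConfig) -> SimulationResult:
    """Execute the coupled simulation for the configured duration."""
    geom, mesh, fem = build_model(config)
    mats = config.materials()

    velocity = None
    u_node = None
    if geom.has_saline and config.flow_on:
        v_in = flow.inflow_velocity(config.drop_rate, config.drops_per_mL,
                                    config.geometry.inflow_area)
        velocity = flow.solve_saline_flow(mesh, inflow_speed=v_in,
                                          mu=config.viscosity,
                                          rho=mats["saline"].rho_liquid)
        u_node = velocity.u

    labels = ("plastic_outer", "electrode_active", "tissue_top") + \
        (("saline_free_surface",) if config.cool_saline_surface else ())
    # fresh saline enters at the supply temperature: inflow nodes are clamped
    dirichlet = None
    if u_node is not None and "saline_inflow" in mesh.edge_labels:
        nodes = np.unique(mesh.edge_labels["saline_inflow"])
        dirichlet = (nodes, np.full(len(nodes), config.T_init))
    thermal = ThermalProblem(mesh, fem, mats, T_ambient=config.ambient,
                             velocity=u_node,
                             perfusion=config.perfusion_on,
                             cooled_labels=labels,
                             dirichlet=dirichlet)
    state = thermal.initial_state(config.T_init)

    active = electrical.electrode_nodes(mesh)
    ground = electrical.ground_nodes(mesh)
    subdomains = [n for n in MATERIAL_NAMES
                  if mesh.material_mask(n).any()]
    sub_nodes = {n: mesh.nodes_of(n) for n in subdomains}

    n_steps = int(round(config.duration / config.dt)) if config.duration > 0 else 0
    times = np.zeros(n_steps + 1)
    impedance = np.zeros(n_steps + 1)
    power = np.zeros(n_steps + 1)
    Tmax = {n: np.zeros(n_steps + 1) for n in subdomains}
    snapshots: dict[float, np.ndarray] = {0.0: state.T.copy()}

    def record(k, state, sol):
        times[k] = state.t
        impedance[k] = electrical.compute_impedance(sol)
        power[k] = config.V0 ** 2 / impedance[k]
        for n in subdomains:
            Tmax[n][k] = state.T[sub_nodes[n]].max()

    for k in range(n_steps + 1):
        Tbar = thermal.element_mean(state.T)
        sigma = _sigma_elements(mesh, mats, Tbar)
        sol = electrical.solve_potential(fem, sigma, config.V0, active, ground)
        record(k, state, sol)
        if k == n_steps:
            break
        _, _, sar = electrical.derive_fields(sol)
        state = thermal.step(state, sar, config.dt,
                             n_corrections=config.n_corrections)
        snap = config.snapshot_interval
        if snap > 0 and (state.t + 1e-9) % snap < config.dt * 0.5:
            snapshots[round(state.t, 6)] = state.T.copy()

    lesion = lesion50 = None
    if n_steps > 0:
        lesion = postprocess.lesion_dimensions(mesh, state.T, level=60.0)
        lesion50 = postprocess.lesion_dimensions(mesh, state.T, level=50.0)
    return SimulationResult(config=config, mesh=mesh, times=times,
                            impedance=impedance, Tmax=Tmax,
                            snapshots=snapshots, T_final=state.T,
                            velocity=velocity, lesion=lesion,
                            lesion50=lesion50, power=power)


# ---------------------------------------------------------------------------
# calibration-style operations


def estimate_insertion_depth(target_Z: float,
                             config: SimulationConfig | None = None,
                             tol: float = 1.0) -> float:
    """Insertion depth (mm) whose bare-contact impedance matches ``target_Z``.

    Uses the monotone decrease of impedance with insertion depth (more
    contact area, less constriction) in a bracketed root search; ``tol`` is
    the impedance tolerance in ohm.
    """
    if config is None:
        config = make_config("no_saline_contact")
    a = config.geometry.electrode_radius

    def Z_of(D_mm: float) -> float:
        geo = dataclasses.replace(config.geometry, insertion_depth=D_mm)
        return static_impedance(dataclasses.replace(config, geometry=geo))

    lo, hi = 0.08 * a, 0.92 * a
    Z_lo, Z_hi = Z_of(lo), Z_of(hi)
    if not (Z_hi <= target_Z <= Z_lo):
        raise ValueError(
            f"target impedance {target_Z:.1f} ohm outside the achievable "
            f"range [{Z_hi:.1f}, {Z_lo:.1f}] ohm for D in [{lo:.2f}, {hi:.2f}] mm")
    f = lambda D: Z_of(D) - target_Z
    # impedance varies by ~1 ohm per few microns near the solution
    D = brentq(f, lo, hi, xtol=2e-3, rtol=1e-4)
    if abs(Z_of(D) - target_Z) > tol:
        raise RuntimeError("root search did not reach the impedance tolerance")
    return float(D)


@dataclass
class ConvergenceReport:
    kind: str                         # "mesh" or "time_step"
    values: list[float]               # ladder of h_interface (mm) or dt (s)
    T_max: list[float]                # control values, degC
    converged_value: float
    tol: float


def convergence_study(config: SimulationConfig, *, kind: str = "mesh",
                      control_time: float = 10.0, tol: float = 0.002,
                      refine: float = math.sqrt(2.0),
                      max_levels: int = 5) -> ConvergenceReport:
    """Refinement ladder using max tissue temperature at 10 s as control.

    Refines the interface element size (or the time step) until successive
    control values differ by less than ``tol`` (relative); returns the
    coarsest converged setting per the standard convergence-test protocol.
    """
    if kind not in ("mesh", "time_step"):
        raise ValueError("kind must be 'mesh' or 'time_step'")
    base = replace(config, duration=control_time, snapshot_interval=0.0)
    values, controls = [], []
    h, dt = config.h_interface, config.dt
    for level in range(max_levels):
        cfg = replace(base, h_interface=h, dt=dt)
        res = run(cfg)
        controls.append(float(res.Tmax["tissue"][-1]))
        values.append(h if kind == "mesh" else dt)
        if level > 0:
            change = abs(controls[-1] - controls[-2]) / abs(controls[-2])
            if change < tol:
                return ConvergenceReport(kind=kind, values=values,
                                         T_max=controls,
                                         converged_value=values[-2], tol=tol)
        if kind == "mesh":
            h /= refine
        else:
            dt /= refine
    raise RuntimeError(
        f"no convergence after {max_levels} refinements; controls={controls}")
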