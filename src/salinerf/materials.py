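"""Material properties and their temperature dependence.

The four materials of the model (plastic sheath, metal electrode, saline,
hepatic tissue) carry constant thermal conductivity and a temperature law for
the electrical conductivity and for the effective volumetric heat capacity:

* ``sigma(T)``: linear rise of ``alpha`` %/degC from the 37 degC reference up to
  99 degC, a two-decade log-linear fall across the 99-100 degC vaporization
  band, constant beyond 100 degC.  The tissue and saline reference values
  (0.31 and 0.774 S/m) are the experimentally calibrated ones.
* effective volumetric heat ``rho * dh/dT``: the enthalpy method absorbs the
  latent heat of water vaporization into a large effective capacity over the
  99-100 degC band.  Tissue switches to gas-phase properties above 100 degC;
  saline, being continuously replenished, keeps the transition value for all
  T >= 99 degC (its gas phase is never reached).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

# phase-transition band, degC
T_VAP_LO = 99.0
T_VAP_HI = 100.0
DT_TRANSITION = T_VAP_HI - T_VAP_LO

#: latent heat of water vaporization, J/kg
LATENT_HEAT = 2.582e6
#: water density at 99 degC, kg/m^3
RHO_WATER_99 = 958.0
#: water mass fraction of hepatic tissue
TISSUE_WATER_FRACTION = 0.68

SIGMA_DECADES_DROP = 2.0  # conductivity falls 10^-2 across the band


@dataclass(frozen=True)
class MaterialModel:
    """Single-material property set (SI units, temperatures in degC)."""

    name: str
    k: float                    # thermal conductivity, W/(m K)
    c_liquid: float             # specific heat, J/(kg K)
    rho_liquid: float           # density, kg/m^3
    sigma37: float              # electrical conductivity at 37 degC, S/m
    alpha: float = 0.0          # sigma temperature coefficient, %/degC
    c_gas: float | None = None  # gas-phase specific heat (tissue)
    rho_gas: float | None = None
    water_fraction: float = 0.0
    has_transition: bool = False
    rehydrated: bool = False    # saline: transition capacity persists > 100 degC
    latent_heat: float = LATENT_HEAT

    def with_alpha(self, alpha: float) -> "MaterialModel":
        return replace(self, alpha=alpha)

    # -- electrical ---------------------------------------------------------

    def electrical_conductivity(self, T):
        """sigma(T) in S/m; piecewise-continuous in T."""
        T = np.asarray(T, dtype=float)
        if not np.isfinite(T).all():
            raise ValueError("temperature must be finite")
        s99 = self.sigma37 * (1.0 + self.alpha / 100.0 * (T_VAP_LO - 37.0))
        lin = self.sigma37 * (1.0 + self.alpha / 100.0 * (T - 37.0))
        if self.alpha == 0.0:
            return lin if lin.shape else float(lin)
        frac = np.clip((T - T_VAP_LO) / DT_TRANSITION, 0.0, 1.0)
        fall = s99 * 10.0 ** (-SIGMA_DECADES_DROP * frac)
        out = np.where(T <= T_VAP_LO, lin, fall)
        return out if out.shape else float(out)

    # -- thermal ------------------------------------------------------------

    @property
    def transition_capacity(self) -> float:
        """Effective volumetric heat in the 99-100 degC band, J/(m^3 K)."""
        wf = self.water_fraction if self.water_fraction > 0 else 1.0
        return self.latent_heat * wf * RHO_WATER_99 / DT_TRANSITION

    def effective_volumetric_heat(self, T):
        """rho * dh/dT in J/(m^3 K) at temperature T."""
        T = np.asarray(T, dtype=float)
        liquid = self.rho_liquid * self.c_liquid
        if not self.has_transition:
            out = np.full(T.shape, liquid)
            return out if out.shape else liquid
        trans = self.transition_capacity
        if self.rehydrated:
            out = np.where(T < T_VAP_LO, liquid, trans)
        else:
            gas = self.rho_gas * self.c_gas
            out = np.select([T < T_VAP_LO, T <= T_VAP_HI], [liquid, trans], gas)
        return out if out.shape else float(out)

    def enthalpy(self, T):
        """Volumetric enthalpy h(T) (J/m^3, zero at 0 degC); strictly increasing."""
        T = np.asarray(T, dtype=float)
        liquid = self.rho_liquid * self.c_liquid
        if not self.has_transition:
            return liquid * T
        trans = self.transition_capacity
        h99 = liquid * T_VAP_LO
        h100 = h99 + trans * DT_TRANSITION
        if self.rehydrated:
            return np.where(T < T_VAP_LO, liquid * T, h99 + trans * (T - T_VAP_LO))
        gas = self.rho_gas * self.c_gas
        return np.select(
            [T < T_VAP_LO, T <= T_VAP_HI],
            [liquid * T, h99 + trans * (T - T_VAP_LO)],
            h100 + gas * (T - T_VAP_HI))


#: temperatures (degC) of the impedance calibration experiments that anchor
#: the tissue and saline conductivities
CALIBRATION_T = {"tissue": 24.0, "saline": 20.0}
#: temperature coefficient (%/degC) under which the 37 degC values were derived
CALIBRATION_ALPHA = 1.0


def default_materials(alpha: float = 1.0) -> dict[str, MaterialModel]:
    """The packaged property table with the calibrated conductivities.

    ``alpha`` is the sigma temperature coefficient in %/degC applied to tissue
    and saline (+1 %/degC reproduces the measured impedance progress).  The
    conductivities were calibrated from room-temperature impedance
    measurements, so the experimentally anchored quantity is sigma at the
    calibration temperature: changing ``alpha`` rescales the 37 degC reference
    to keep sigma(T_calibration) fixed.
    """
    def s37(base: float, name: str) -> float:
        Tc = CALIBRATION_T[name]
        anchored = base * (1.0 + CALIBRATION_ALPHA / 100.0 * (Tc - 37.0))
        return anchored / (1.0 + alpha / 100.0 * (Tc - 37.0))

    return {
        "plastic": MaterialModel("plastic", k=0.026, c_liquid=1045.0,
                                 rho_liquid=70.0, sigma37=1e-5),
        "electrode": MaterialModel("electrode", k=70.0, c_liquid=840.0,
                                   rho_liquid=6450.0, sigma37=1e8),
        "saline": MaterialModel("saline", k=0.58, c_liquid=3200.0,
                                rho_liquid=1004.0, sigma37=s37(0.774, "saline"),
                                alpha=alpha,
                                has_transition=True, rehydrated=True),
        "tissue": MaterialModel("tissue", k=0.502, c_liquid=3455.0,
                                rho_liquid=1080.0, sigma37=s37(0.31, "tissue"),
                                alpha=alpha,
                                c_gas=2155.0, rho_gas=370.44,
                                water_fraction=TISSUE_WATER_FRACTION,
                                has_transition=True),
    }


def electrical_conductivity(material: MaterialModel | str, T,
                            alpha: float | None = None):
    """sigma(T) for a material instance or a default-table material name."""
    if isinstance(material, str):
        table = default_materials(alpha if alpha is not None else 1.0)
        if material not in table:
            raise KeyError(f"unknown material {material!r}")
        material = table[material]
    elif alpha is not None:
        material = material.with_alpha(alpha)
    return material.electrical_conductivity(T)


def effective_volumetric_heat(material: MaterialModel | str, T):
    if isinstance(material, str):
        table = default_materials()
        if material not in table:
            raise KeyError(f"unknown material {material!r}")
        material = table[material]
    return material.effective_volumetric_heat(T)


def calibrate_sigma37(measured_Z: float, forward_impedance, sigma37_guess: float,
                      T_measurement: float = 37.0, alpha: float = 1.0) -> float:
    """Reference conductivity that makes the model match a measured impedance.

    For an electrode surrounded by a single homogeneous conductor the
    impedance scales as ``Z ~ 1/sigma37`` (the temperature factor cancels), so
    one forward solve at ``sigma37_guess`` suffices:
    ``sigma37 = sigma37_guess * Z(sigma37_guess) / measured_Z``.

    Parameters
    ----------
    measured_Z:
        Measured impedance in ohm (> 0).
    forward_impedance:
        Callable ``f(sigma37) -> Z`` running the model at the measurement
        temperature.
    """
    if not measured_Z > 0:
        raise ValueError("measured impedance must be positive")
    z0 = forward_impedance(sigma37_guess)
    return sigma37_guess * z0 / measured_Z
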