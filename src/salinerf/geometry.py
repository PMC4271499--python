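"""Axisymmetric domain geometry for a saline-linked RF electrode on hepatic tissue.

Coordinate convention: ``(r, z)`` half-plane with the symmetry axis at ``r = 0``,
``z = 0`` at the undisturbed tissue surface and ``z`` positive *downward* into
the tissue.  The electrode is a right cylinder of radius ``a`` capped by a
hemisphere of the same radius; its tip indents the tissue to the insertion
depth ``D``.  A two-zone saline film sits on the tissue surface: Zone 1 decays
linearly from height ``L`` at the electrode wall to thickness ``S`` at a
horizontal distance ``r0`` from the electrode surface, Zone 2 keeps the
constant thickness ``S`` further out.

All ``GeometryParams`` fields are in millimetres (the unit used in the device
datasheets); the derived :class:`Geometry` object works in SI metres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

MM = 1e-3

TOPOLOGIES = ("surface_contact", "fully_inserted", "submerged_in_saline")

#: materials that can appear in a mesh, in label order
MATERIAL_NAMES = ("tissue", "saline", "electrode", "plastic")

TISSUE, SALINE, ELECTRODE, PLASTIC = range(4)


class GeometryError(ValueError):
    """Raised for inconsistent geometry parameters."""


@dataclass(frozen=True)
class GeometryParams:
    """User-facing geometry description (lengths in mm)."""

    tissue_radius: float = 50.0          # R
    tissue_height: float = 50.0          # H
    electrode_radius: float = 1.5        # a  (3 mm diameter device)
    electrode_length: float = 10.0       # E, conductive length incl. tip
    insertion_depth: float = 0.75        # D, tip indentation below surface
    saline_thickness: float = 0.6        # S, Zone 2 film thickness
    saline_height_on_electrode: float = 1.5   # L, film height on the wall
    saline_zone1_extent: float = 2.0     # r0, measured from electrode surface
    saline_extent: float | None = None   # film outer radius; None -> R
    shaft_model_length: float = 15.0     # modeled shaft above the surface
    inflow_area: float = 9.4e-6          # m^2, wetted area carrying the inflow
    scenario_topology: str = "surface_contact"
    with_saline: bool = True

    def validate(self) -> None:
        p = self
        lengths = dict(
            tissue_radius=p.tissue_radius, tissue_height=p.tissue_height,
            electrode_radius=p.electrode_radius, electrode_length=p.electrode_length,
            insertion_depth=p.insertion_depth, saline_thickness=p.saline_thickness,
            saline_height_on_electrode=p.saline_height_on_electrode,
            saline_zone1_extent=p.saline_zone1_extent,
            shaft_model_length=p.shaft_model_length,
        )
        for name, v in lengths.items():
            if not v > 0:
                raise GeometryError(f"{name} must be > 0, got {v}")
        if p.scenario_topology not in TOPOLOGIES:
            raise GeometryError(f"unknown topology {p.scenario_topology!r}")
        if p.insertion_depth >= p.electrode_radius + p.electrode_length:
            raise GeometryError("insertion depth exceeds the electrode extent")
        if p.scenario_topology == "surface_contact":
            if p.insertion_depth >= p.electrode_radius:
                raise GeometryError(
                    "surface-contact topology requires D < electrode radius "
                    "(the hemispherical tip only partially indents the surface)")
            if p.with_saline:
                if p.saline_height_on_electrode < p.saline_thickness:
                    raise GeometryError("saline profile needs L >= S")
                if p.insertion_depth >= p.saline_height_on_electrode:
                    raise GeometryError(
                        "inconsistent topology: D >= L (tip deeper than the film is tall)")
                if p.saline_height_on_electrode <= p.electrode_radius - p.insertion_depth:
                    raise GeometryError(
                        "film height L must exceed a - D so the film reaches "
                        "the cylindrical electrode wall")
        if p.electrode_length <= p.electrode_radius:
            raise GeometryError("conductive length must exceed the tip radius")

    def build(self) -> "Geometry":
        return build_geometry(self)

    def without_saline(self) -> "GeometryParams":
        return replace(self, with_saline=False)


class Geometry:
    """Labelled planar region set in SI units, consumed by the mesher.

    The domain is described column-wise: at every radius ``r`` the method
    :meth:`intervals` lists the (possibly disconnected) ``z`` spans occupied by
    material, :meth:`crossings` the material interfaces along that column, and
    :meth:`material_at` classifies a point.  Interface curves that are not
    vertical are additionally exposed through :attr:`interface_curves` so the
    mesher can fit element edges to them.
    """

    def __init__(self, params: GeometryParams):
        params.validate()
        self.params = params
        p = params
        self.R = p.tissue_radius * MM
        self.H = p.tissue_height * MM
        self.a = p.electrode_radius * MM
        self.E = p.electrode_length * MM
        self.S = p.saline_thickness * MM
        self.L = p.saline_height_on_electrode * MM
        self.r0 = p.saline_zone1_extent * MM
        self.Ztop = p.shaft_model_length * MM
        self.topology = p.scenario_topology
        self.has_saline = p.with_saline and self.topology == "surface_contact"
        if self.topology == "surface_contact":
            self.D = p.insertion_depth * MM
        else:
            # fully inserted / submerged: the whole conductive length is buried
            self.D = self.E
        self.z_tip = self.D                       # apex of the tip
        self.zc = self.z_tip - self.a             # hemisphere centre
        self.z_sheath = self.z_tip - self.E       # metal/plastic transition
        if self.z_sheath <= -self.Ztop:
            raise GeometryError("shaft_model_length too short for the conductive length")
        # contact radius where the tip pierces the surface (surface topology)
        if self.topology == "surface_contact":
            self.rcap = math.sqrt(self.a**2 - self.zc**2)
        else:
            self.rcap = self.a
        self.Rs = (p.saline_extent * MM) if p.saline_extent is not None else self.R
        if self.has_saline and not (self.a + self.r0 <= self.Rs <= self.R):
            raise GeometryError("saline extent must lie in [a + r0, R]")
        # medium filling z in [0, H] around the electrode
        self.medium = SALINE if self.topology == "submerged_in_saline" else TISSUE

    # -- interface profiles -------------------------------------------------

    def z_electrode_bottom(self, r):
        """Lower surface of the electrode body (cylinder + hemispherical cap)."""
        r = np.asarray(r, dtype=float)
        rr = np.minimum(np.abs(r), self.a)
        return self.zc + np.sqrt(np.maximum(self.a**2 - rr**2, 0.0))

    def film_height(self, r):
        """Saline film height h(r) for r > a (two-zone profile)."""
        r = np.asarray(r, dtype=float)
        d = r - self.a  # horizontal distance from the electrode surface
        h = np.where(d <= self.r0,
                     self.L - (self.L - self.S) * d / self.r0,
                     self.S)
        return np.where(r > self.Rs, 0.0, h)

    def saline_top(self, r):
        """Upper saline boundary -h(r); the film lives outside the wall r = a."""
        return -self.film_height(r)

    # -- column description --------------------------------------------------

    def intervals(self, r: float, side: int) -> list[tuple[float, float]]:
        """Occupied ``(z_top, z_bot)`` spans at radius ``r`` approached from
        ``side`` (+1: from larger r, -1: from smaller r)."""
        eps = 1e-9 * self.a
        rt = r + side * eps
        if rt < 0:
            rt = 0.0
        if rt > self.R:
            return []
        if rt < self.a:
            if self.topology != "surface_contact" or rt <= self.rcap:
                return [(-self.Ztop, self.H)]
            # surface contact: the crevice between the pressed tip and the
            # tissue (rcap < r < a) is void, with or without the film
            return [(-self.Ztop, float(self.z_electrode_bottom(rt))), (0.0, self.H)]
        if self.has_saline and rt <= self.Rs:
            return [(-float(self.film_height(rt)), self.H)]
        return [(0.0, self.H)]

    def crossings(self, r: float, side: int) -> list[float]:
        """Material-interface z values along the column at radius ``r``."""
        eps = 1e-9 * self.a
        rt = min(max(r + side * eps, 0.0), self.R)
        out: list[float] = []
        if rt < self.a:
            out += [self.z_sheath, float(self.z_electrode_bottom(rt))]
        else:
            out.append(0.0)
            if self.has_saline and rt <= self.Rs:
                out.append(-float(self.film_height(rt)))
        return out

    def material_at(self, r: float, z: float) -> int | None:
        if r < 0 or r > self.R or z > self.H or z < -self.Ztop:
            return None
        if r <= self.a and z <= self.z_electrode_bottom(r):
            return ELECTRODE if z >= self.z_sheath else PLASTIC
        if z >= 0.0:
            return self.medium
        if self.has_saline and self.a < r <= self.Rs and z >= -self.film_height(r):
            return SALINE
        return None

    def material_of_elements(self, centroids: np.ndarray) -> np.ndarray:
        out = np.empty(len(centroids), dtype=np.int8)
        for i, (r, z) in enumerate(centroids):
            m = self.material_at(r, z)
            out[i] = -1 if m is None else m
        return out

    @property
    def interface_curves(self) -> list[tuple[Callable, float, float]]:
        """Non-vertical interface curves as ``(f(r), r_lo, r_hi)``."""
        curves = [(self.z_electrode_bottom, 0.0, self.a)]
        if self.has_saline:
            curves.append(lambda r: -self.film_height(r))
            curves[-1] = (curves[-1], self.a, self.Rs)
        return curves

    def key_radii(self) -> list[float]:
        ks = [0.0, self.a, self.R]
        if self.topology == "surface_contact":
            ks.append(self.rcap)
        if self.has_saline:
            ks += [self.a + self.r0, self.Rs]
        return sorted(set(ks))

    def key_levels(self) -> list[float]:
        ks = [-self.Ztop, self.z_sheath, self.zc, 0.0, self.z_tip, self.H]
        if self.has_saline:
            ks += [-self.L, -self.S]
        return sorted(set(ks))

    # -- saline inflow band ---------------------------------------------------

    def inflow_band(self) -> tuple[float, float]:
        """z-range ``(z_hi, z_lo)`` of the inflow band on the electrode wall.

        The saline enters through the wetted part of the cylindrical wall,
        between the top of the film (z = -L) and the hemisphere equator
        (z = zc); the nominal inflow speed is rescaled by the flow solver so
        the volumetric rate is met exactly on this band.
        """
        if not self.has_saline:
            raise GeometryError("inflow band only exists with a saline layer")
        z_hi, z_lo = -self.L, self.zc
        if z_lo <= z_hi:
            raise GeometryError("film does not wet the cylindrical wall")
        return z_hi, z_lo

    def wetted_wall_area(self) -> float:
        z_hi, z_lo = self.inflow_band()
        return 2.0 * math.pi * self.a * (z_lo - z_hi)

    def on_electrode_surface(self, r, z, tol) -> np.ndarray:
        """Points lying on the wetted electrode wall (cylinder or tip)."""
        r = np.asarray(r, float); z = np.asarray(z, float)
        on_cyl = (np.abs(r - self.a) < tol) & (z <= self.zc + tol)
        rho = np.hypot(r, z - self.zc)
        on_cap = (np.abs(rho - self.a) < tol) & (z > self.zc - tol)
        return on_cyl | on_cap

    def electrode_outward_normal(self, r, z):
        """Outward unit normal of the electrode surface at wall points."""
        r = np.asarray(r, float); z = np.asarray(z, float)
        on_cyl = z <= self.zc
        nr = np.where(on_cyl, 1.0, r)
        nz = np.where(on_cyl, 0.0, z - self.zc)
        norm = np.hypot(nr, nz)
        return np.stack([nr / norm, nz / norm], axis=-1)

    # -- analytic areas/volumes (mesh validation oracles) ---------------------

    def _int_circle(self, r):
        """integral_0^r sqrt(a^2 - s^2) ds."""
        a = self.a
        r = min(r, a)
        return 0.5 * (r * math.sqrt(max(a * a - r * r, 0.0)) + a * a * math.asin(r / a))

    def planar_areas(self) -> dict[str, float]:
        """Exact planar (r,z) area of each material region, in m^2."""
        a, zc, Ztop = self.a, self.zc, self.Ztop
        body = a * Ztop + a * zc + math.pi * a * a / 4.0
        metal = a * (self.E - a) + math.pi * a * a / 4.0
        plastic = body - metal
        # part of the body below the tissue surface (z > 0)
        if self.topology == "surface_contact":
            below = self.rcap * zc + self._int_circle(self.rcap)
        else:
            below = a * zc + math.pi * a * a / 4.0
        medium = self.R * self.H - below
        out = {"electrode": metal, "plastic": plastic,
               MATERIAL_NAMES[self.medium]: medium}
        if self.has_saline:
            zone1 = self.r0 * (self.L + self.S) / 2.0
            zone2 = self.S * (self.Rs - self.a - self.r0)
            out["saline"] = zone1 + zone2
        return out

    def tissue_volume(self) -> float:
        """Axisymmetric tissue volume: full cylinder minus the indented cap."""
        if self.topology != "surface_contact":
            raise NotImplementedError("only the surface topology is supported")
        D = self.D
        cap = math.pi * D * D * (self.a - D / 3.0)
        return math.pi * self.R**2 * self.H - cap


def build_geometry(params: GeometryParams) -> Geometry:
    """Validate ``params`` and construct the labelled planar region set."""
    return Geometry(params)
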