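# Methods

## Geometry

The domain is the (r, z) half-plane with the axis on the electrode
centreline, z = 0 at the undisturbed tissue surface and z positive downward.
The tissue is a cylinder of radius R = 50 mm and height H = 50 mm (the
converged domain size; the 65 mm physical sample is available as an option).
The electrode is a 3 mm-diameter rod capped by a hemisphere of the same
radius — the tip shape is not tabulated for the device, and the hemisphere
matches the spherical tip section the field plots show; the conductive
length is E = 10 mm with an insulating plastic sheath above, and the tip
indents the tissue to the insertion depth D = 0.75 mm (the value that
reproduces the measured bare-contact impedance).

The irrigation film has two zones: the height decays linearly from
L = 1.5 mm on the electrode wall to S = 0.6 mm at a horizontal distance
r₀ = 2 mm from the wall, and stays S further out. Two readings of the film
profile are possible where it meets the pressed-in tip; we model the
crevice between the hemisphere below its equator and the tissue as void
(the electrode is pressed onto the tissue under controlled force, and the
film profile is anchored at the cylindrical wall). This reading was
selected by the same indirect validation the insertion depth uses: with the
crevice filled, the computed full-configuration impedances sit ~11 % below
the measured 310/265 Ω; with the void reading they sit within 7 %. The
film's radial extent is not documented; by default Zone 2 runs to the
domain rim (the bench experiment floods the whole sample surface), and the
computed impedance changes by < 5 % if it is truncated at 8 mm.

Calibration topologies: `fully_inserted` buries the entire conductive
length (tip apex 10 mm deep, metal/sheath transition at the surface);
`submerged_in_saline` is the same geometry with saline as the medium —
the tank dimensions are not documented and the tissue-cylinder dimensions
are reused.

## Mesh

A structured column/strip mesher triangulates the domain: graded radial
stations each carry a sorted node column (material-interface crossings plus
a global graded z-ladder), and adjacent columns are stitched by a sorted
merge. Interface crossings are forced onto nodes and ladder points between
the crossing heights of neighbouring stations are suppressed, so every
material interface is an exact polyline of element edges and the mesh is
conforming by construction. Validity (positive areas, manifold edges, exact
subdomain areas) is asserted in the test suite.

The finest element size defaults to h = 0.085 mm at the electrode–tissue
interface, growing geometrically (ratio 1.35) away from it: 7,196 elements
for the surface-contact scenario. The size was fixed by the standard
convergence protocol — refine until the maximum tissue temperature after
10 s of heating changes by < 0.2 % (here 0.13 % for the next √2
refinement). The control is intrinsically noisy at the ±0.3 % level
because the maximum sits at the current-crowding ring of the contact patch,
where the electric field is weakly singular. The same protocol applied to
the time step confirms Δt = 0.1 s (halving it changes the control by
< 0.1 %).

## Electrical problem

P1 axisymmetric finite elements (all integrals carry the 2πr weight, exact
for linear triangles). The metal (σ = 10⁸ S/m) and plastic (10⁻⁵ S/m) stay
inside the domain with their tabulated properties; every node touching a
metal element carries the applied 47 V (RMS), the bottom boundary is the
grounded dispersive plate, all other boundaries are natural (insulating).
Per element, σ is evaluated at the element-mean temperature of the previous
time step. Impedance uses the power method Z = V₀²/∫σ|E|² dV; the
boundary-current cross-check V₀/I is evaluated at the ground boundary
(the active-electrode residual rows are float64 cancellation noise at
σ = 10⁸). The solver reproduces the concentric-spheres closed form to
0.02 % and the discrete power balance to numerical precision.

The conductivity law is linear in T below 99 °C with slope α %/°C, falls
two decades log-linearly across 99–100 °C and is constant beyond. The
calibrated references (0.31 / 0.774 S/m at 37 °C) derive from
room-temperature impedance measurements under α = +1 %/°C, so the
experimentally anchored quantity is σ at the calibration temperature
(24 °C tissue, 20 °C saline): selecting a different α rescales the 37 °C
reference to keep σ(T_cal) fixed. Without this anchoring the α-sweep would
shift the initial impedance instead of only steepening the drop.

## Flow problem

Steady axisymmetric Stokes (MINI element: P1+bubble velocity, P1 pressure,
bubble statically condensed; full stress form). At film speeds of a few
mm/s and sub-millimetre thicknesses the Reynolds number is of order one, so
the creeping-flow linearization is appropriate and unconditionally robust.
The drip (1 drop/s, 20 drops/mL → Q = 5·10⁻⁸ m³/s) enters as a prescribed
normal velocity on the wetted electrode wall; the discrete nodal values are
rescaled so the boundary flux equals Q exactly. The saline–tissue interface
and the electrode wall are no-slip; the film surface and rim are open
(zero traction). With the open surface most of the injected saline drains
within ~2 mm of the electrode and the outer film is nearly stagnant — this
is what lets conduction from the tissue warm the outer film to ~80 °C and
widen the surface lesion, and it reproduces the measured full-configuration
impedance-temperature behaviour. An impermeable (slip) film surface is also
implemented (penalty on u·n) and is used by the annular-film test fixture,
whose Q/(2πrS) closed form assumes a contained film; applied to the device
it would sweep essentially all surface heat into the drain and suppress the
surface lesion entirely. The flow is solved once and held fixed during
heating (the model has no thermal feedback on the flow); viscosity is
10⁻³ Pa·s (water, configurable — the flux balance is set by the boundary
conditions and is insensitive to it).

## Thermal problem

Backward-Euler P1 steps of the enthalpy-form bioheat equation with lumped
(row-sum) capacity. The effective volumetric heat ρ∂h/∂T is ρc per phase
and H_lg·w·ρ_w(99 °C)/ΔT across the 99–100 °C band (ΔT = 1 °C; tissue
water fraction w = 0.68, saline w = 1). The printed latent heat carries a
unit typo ("2.582 kJ/kg·K"); it is taken as 2.582 MJ/kg, the magnitude of
water's vaporization enthalpy, and is configurable. Within each step the
capacity is iterated with a damped secant (enthalpy-difference) update;
a step that jumps across the sharp band triggers recursive Δt halving so
the latent heat is absorbed consistently (verified to 2 % in an insulated
band-crossing test; exact conservation in the single-phase regime).

The convective term −ρ_s c_s (u·∇T) acts only in saline elements and uses
exact r-weighted integrals with streamline (SU) artificial diffusion sized
by the element Péclet number. Nodes on the inflow band are clamped to the
supply temperature (T_init), which is how the fresh, cool drip enters the
energy balance; without it the film recirculates its own heat and boils.
Newton cooling (h_e = 20 W/m²·K, ambient = initial temperature) acts on the
plastic and electrode outer surfaces, exposed tissue top, and — by default,
switchable — the film surface; the tissue flank is insulated (the sample
sits in a plastic container) and the bottom plate is adiabatic (the lesion
never approaches it in 20 s). Metabolic heat is zero in all scenarios.
The solver matches the transient-slab Fourier series to 0.2 %.

The perfusion sink uses ρ_b = 1000 kg/m³, c_b = 4180 J/kg·K, T_b = 37 °C,
ω_b = 6.4·10⁻³ s⁻¹, with the per-element switch β set irreversibly to zero
once the element-mean temperature has reached 50 °C.

## Coupling and scenarios

Per step: σ(T_n) → potential → SAR → thermal step to T_{n+1} (staggered, no
outer iteration; Δt = 0.1 s is far below the thermal time constants).
The voltage is constant (no generator limits). Ex vivo runs start at 24 °C
— the stated room temperature; a 21 °C figure appears once elsewhere in the
source material and is treated as a typo (configurable). In vivo runs start
at 37 °C with 37 °C boundaries and supply.

## Lesion metrics

The 60 °C isotherm (whitening proxy; 50 °C also reported) is extracted by
marching triangles restricted to the tissue subdomain. Width is the full
diameter at which the surface plane z = 0 reaches the level — where lesion
width is measured on the bench photographs. Depth is measured at the
deepest contour point from the local tissue surface: at the centre the
lesion starts at the floor of the tip indentation (z = D), so this is the
white-zone thickness a cross-section photograph shows. Measured from the
undisturbed z = 0 plane instead, the ex vivo depth would read 3.2 mm
rather than 2.5 mm; the local-surface convention is the one that matches
both the stated metric definition ("below the tissue surface on/near the
axis") and the photographic measurement.

## Known limitations

* Two calibration impedances (fully inserted 164 Ω, submerged 65 Ω) are
  reproduced only to −18 % / −13 % (134.7 / 56.6 Ω). The electrical solver
  verifies against closed forms to 0.02 %, the values are converged in mesh
  and insensitive to the domain size, and the same solver reproduces the
  bare-contact 561 Ω within 1 % — the gap therefore reflects undocumented
  geometry of those calibration setups (the really exposed conductive
  length of the device; the saline-tank dimensions), not the solver.
* The model is 2-D axisymmetric: asymmetric saline spread, tilted
  electrodes and surface irregularities are out of scope, as are
  interstitial saline infusion into the tissue, modulated electrosurgical
  waveforms, and tissue deformation beyond the fixed spherical-cap
  indentation.
* The film geometry is static; pooling transients and free-surface motion
  are not modeled.
* The convergence control (max tissue temperature) sits on a weakly
  singular field feature, so mesh-convergence statements at the 0.1 % level
  are noisy; lesion metrics are stable to < 0.2 mm under refinement.
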