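"""Bench-condition RF heating: 47 V for 20 s on room-temperature liver.

Runs the full coupled simulation (saline film flow, RF conduction, bioheat)
and prints the impedance progress and the 60 degC-isotherm lesion size.
"""

from salinerf import make_config, run

res = run(make_config("ex_vivo"))

print("ex vivo heating, 47 V / 20 s, +1 %/degC conductivity coefficient")
print(f"  mesh: {res.mesh.n_elements} elements")
print(f"  impedance: {res.impedance[0]:.0f} ohm at start, "
      f"{res.impedance[-1]:.0f} ohm after 20 s "
      f"(drop {res.impedance[0] - res.impedance[-1]:.0f} ohm)")
les = res.lesion
print(f"  60 degC lesion: {les.depth:.1f} mm deep, {les.width:.1f} mm wide")
print(f"  max tissue temperature {res.Tmax['tissue'].max():.0f} degC, "
      f"max saline temperature {res.Tmax['saline'].max():.0f} degC")
print()
print("The impedance falls as the tissue warms (conductivity rises ~1 %/degC);")
print("the saline never boils because the moving film carries heat away, and")
print("the lesion is deepest under the electrode tip where the RF power is")
print("deposited, while the warm film widens it along the surface.")
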