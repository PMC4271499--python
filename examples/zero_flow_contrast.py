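"""What the irrigation is for: heating with and without saline motion.

Repeats the bench heating with the saline velocity set to zero and compares
where the temperature maximum sits and whether the film boils.
"""

from salinerf import make_config, run

for scenario in ("ex_vivo", "zero_flow"):
    res = run(make_config(scenario, snapshot_interval=0.0))
    Ts, Tt = res.Tmax["saline"].max(), res.Tmax["tissue"].max()
    where = "saline" if Ts > Tt else "tissue"
    print(f"{scenario:9s}: max tissue T {Tt:5.1f} degC, max saline T {Ts:5.1f} "
          f"degC -> hottest in the {where}")
    print(f"           60 degC lesion {res.lesion.depth:.1f} x "
          f"{res.lesion.width:.1f} mm, final impedance "
          f"{res.impedance[-1]:.0f} ohm")
print()
print("With the film in motion the saline stays well below boiling; with the")
print("velocity zeroed the maximum relocates into the saline and reaches")
print("~100 degC at the film surface, where the vaporization enthalpy clamps")
print("any further rise - the reason irrigated electrodes do not char.")
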