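"""Operating-point correlations for a shaken flask and a stirred tank.

Evaluates the closed-form criteria and correlations for the two cultivation
systems of interest: a 500 mL unbaffled shake flask (160 mL fill, 130 rpm,
50 mm orbit) and a 6 L stirred vessel (85 mm segment impeller, 4 L fill),
plus the oxygen-transfer ceiling on viable cell density.
"""

import hydrostress as hs

water = hs.WATER_310K
RPM = 1 / 60

# --- shaken flask -----------------------------------------------------
flask = hs.ShakenSpec(
    shaking_frequency=130 * RPM,
    shaking_amplitude=0.05,
    max_inner_diameter=0.101,   # not printed for the flask; typical 500 mL
    fill_volume=1.6e-4,
    fluid=water,
    nominal_volume=5e-4,
)
verdict = hs.in_phase(flask)
print("shaken flask, 130 rpm / 50 mm orbit:")
print(f"  phase number Ph  = {verdict['phase_number']:.2f}  (> 1.26 required)")
print(f"  axial Froude Fra = {verdict['axial_froude']:.2f}  (> 0.4 required)")
print(f"  in phase: {verdict['in_phase']}")
print(f"  empirical power input P/V = {hs.buchs_power_unbaffled(flask):.1f} W/m^3")

# --- stirred tank ------------------------------------------------------
print("\nstirred 6 L vessel, 4 L fill, ds = 85 mm:")
for rpm in (100, 180, 275, 350, 500):
    spec = hs.StirredSpec(rpm * RPM, 0.085, 4e-3, water)
    vtip = hs.tip_speed(spec.stirrer_speed, spec.stirrer_diameter)
    pv = hs.maschke_power(vtip)
    ne = hs.newton_number(pv * spec.fill_volume, spec)
    print(
        f"  {rpm:3d} rpm: Re_m = {hs.reynolds_stirred(spec):7.0f}  "
        f"v_tip = {vtip:5.2f} m/s  P/V = {pv:7.1f} W/m^3  Ne = {ne:5.2f}"
    )

# --- oxygen ceiling ----------------------------------------------------
c_star = hs.o2_solubility(310.15)  # dry air, 1 atm, 37 degC
vcd = hs.max_supported_vcd(hs.OxygenSpec(kla=16.0, qo2=1.85e-13, c_star=c_star))
print(
    f"\noxygen ceiling: c* = {c_star * 1e3:.3f} mmol/L, kLa = 16 1/h "
    f"-> max VCD = {vcd / 1e6:.1f} million cells/mL"
)
# The ceiling sits far above the ~5-6 million cells/mL a batch reaches, so
# growth differences between vessels are not an artefact of oxygen supply.
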