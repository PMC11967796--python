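"""Resolve the hydraulics of one emulsification condition.

A 20 um square channel on a rotor spinning at 5000 rpm, with the aqueous
surface 18 mm from the axis and a 6 mm liquid column above the nozzles.
"""

from spindrop import (
    ChannelGeometry,
    FluidSystem,
    RotorConfig,
    centrifugal_acceleration,
    flow_state,
)

channel = ChannelGeometry.from_lab(w_um=20, h_um=20, l_mm=5)
fluids = FluidSystem.from_lab(rho_kg_m3=1000, mu_mPa_s=1.0, gamma_mN_m=5.0, theta_deg=120)
rotor = RotorConfig.from_lab(omega_rpm=5000, r1_mm=18, r2_mm=6)

state = flow_state(channel, fluids, rotor)
print(f"centrifugal acceleration : {centrifugal_acceleration(rotor):9.1f} m/s^2")
print(f"driving pressure         : {state.driving_pressure:9.1f} Pa")
print(f"capillary pressure       : {state.capillary_pressure:9.1f} Pa")
print(f"hydraulic resistance     : {state.hydraulic_resistance:9.3e} Pa*s/m^3")
print(f"inlet velocity           : {state.inlet_velocity * 1e3:9.2f} mm/s")
print(f"Weber number             : {state.weber:9.4f}  ->  {state.regime}")
# The centrifugal head (~34.5 kPa) easily overcomes the -500 Pa hydrophobic
# capillary pressure; the low Weber number puts the nozzle in the
# monodisperse periodic-dripping regime.
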