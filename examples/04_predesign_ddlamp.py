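"""Pre-design droplets for a digital LAMP assay, then reverse-engineer the
generation conditions.

A 350 mm^2 observation reservoir with a quarter held back for tiling
headroom, a 20 uL sample, and at least 10 000 droplets for dynamic range
pin the admissible diameter window; a grid search over channels and rotor
speeds then finds conditions predicted to land inside it.
"""

import math

import numpy as np

from spindrop import (
    ChannelGeometry,
    PredictiveModel,
    TilingConstraints,
    area_budget,
    diameter_window,
    droplet_count,
    generate_condition_grid,
    generate_observations,
    reverse_engineer,
    units,
)
from spindrop.synth import DEFAULT_FLUIDS

MM2 = units.MM**2

constraints = TilingConstraints(
    reservoir_area=350 * MM2, sample_volume=20 * units.UL,
    min_count=10_000, reserve_fraction=0.25,
)
budget = area_budget(constraints.reservoir_area, constraints.reserve_fraction)
print(f"monolayer circle budget (full reservoir) : {area_budget(350 * MM2) / MM2:6.1f} mm^2")
print(f"budget with 1/4 tiling headroom          : {budget / MM2:6.1f} mm^2")

window = diameter_window(constraints)
print(f"admissible diameter window               : "
      f"{window.d_min / units.UM:.1f} - {window.d_max / units.UM:.1f} um")
print(f"droplets from 20 uL at 145 um            : "
      f"{droplet_count(20 * units.UL, 145 * units.UM):7.0f}")

# Train the predictor on synthetic observations, then search the catalogue
# over a dense speed grid spanning the trained accelerations (interpolating
# ln(alpha) and beta between the fitted laws).
model = PredictiveModel.fit(generate_observations(generate_condition_grid(), seed=1))
catalogue = [ChannelGeometry.from_lab(w, w, 5.0) for w in (20, 30, 40)]
accels = np.linspace(model.accelerations[0], model.accelerations[-1], 120)
omegas = [math.sqrt(a / 0.024) for a in accels]
result = reverse_engineer(model, window, catalogue, DEFAULT_FLUIDS, 0.018, 0.006,
                          omegas, interpolate=True)
print(f"{len(result.candidates)} candidate condition(s); best match:")
best = result.candidates[0]
print(f"  {best.condition.channel.width / units.UM:.0f} um channel @ "
      f"{units.rad_per_s_to_rpm(best.condition.rotor.omega):.0f} rpm "
      f"(a = {best.condition.acceleration:.1f} m/s^2) -> "
      f"D = {best.diameter / units.UM:.1f} um, f = {best.frequency:.1f} Hz")
# The window bounds trade observation area (lower bound) against count
# (upper bound); the search returns every condition whose predicted
# diameter fits, closest to the window centre first.
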