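"""Quantify a target by droplet digital assay on synthetic populations.

Builds droplet populations at known concentrations (12 500 droplets of
145 um each, with stitching-style baseline drift), classifies droplets
with the drift-robust local threshold, inverts the positive fraction
through Poisson statistics, and reads off dilution linearity, LOD and MIC.
"""

import numpy as np

from spindrop import (
    SusceptibilityCurve,
    dilution_linearity,
    generate_droplet_population,
    local_classify,
    lod,
    mic,
    poisson_concentration,
)

rng = np.random.default_rng(0)
controls = generate_droplet_population(0.0, 145e-6, 12_500, rng=rng)

theoretical, measured = [], []
for c_true in (28.5, 95.0, 285.0, 950.0, 2850.0):
    pop = generate_droplet_population(c_true, 145e-6, 12_500, rng=rng)
    calls = local_classify(pop, control_intensities=controls.intensities)
    estimate = poisson_concentration(calls.positive_fraction, pop.volume_uL)
    theoretical.append(c_true)
    measured.append(estimate.concentration_per_uL)
    print(f"true {c_true:8.1f} /uL   p = {calls.positive_fraction:7.4f}   "
          f"estimated {estimate.concentration_per_uL:8.1f} /uL")

fit = dilution_linearity(theoretical, measured)
print(f"dilution linearity (log10-log10): slope = {fit.slope:.3f}, "
      f"R^2 = {fit.r_squared:.4f}")

calls_by_conc = {10.0: [False, True, True], 28.5: [True, True, True],
                 285.0: [True, True, True]}
print(f"LOD (all replicates positive)   : {lod(calls_by_conc)} copies/uL")

curve = SusceptibilityCurve(
    concentrations=(0.0, 0.25, 0.5, 1.0, 2.0, 4.0),
    survival_pct=(100.0, 85.0, 55.0, 8.0, 2.0, 0.5),
)
print(f"MIC at 10% droplet survival     : {mic(curve)} ug/mL")
# The Poisson inversion C = -ln(1-p)/V turns a positive fraction into an
# absolute concentration without calibration; slope ~1 and R^2 ~1 confirm
# linearity across two decades.
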