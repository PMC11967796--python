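"""Seeded synthetic-data generators.

No public dataset accompanies the emulsification model, so every other
module is exercised on synthetic data generated here: a 60-condition grid
(three square channel sizes x five centrifugal accelerations x four rotor
geometries sharing each acceleration but splitting the liquid column
differently, hence different inlet velocities), droplet-size observations
drawn from a known ground-truth exponential law, and bimodal droplet
fluorescence populations with Poisson occupancy and a periodic baseline
drift emulating stitched-scan artefacts.

The ground-truth law coefficients are synthetic choices, not fitted values
from any experiment: ``ln alpha`` falls linearly and ``beta`` rises mildly
with acceleration, tuned once so the default grid spans mean droplet
diameters of roughly 80-400 um with the highest-acceleration large-channel
conditions tipping into the dripping-faucet regime (and being skipped),
mirroring the structure of real centrifugal step-emulsification datasets.

All randomness flows through ``numpy.random.default_rng`` seeded by the
caller: identical seed and spec give identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import units
from .assay import DropletPopulation
from .exceptions import NoFlowError, OutsideModelRangeError, ParameterError
from .physics import PERIODIC_DRIPPING, ChannelGeometry, FluidSystem
from .predictor import EmulsificationCondition, ExpLaw, _solve_diameter
from .physics import RotorConfig

__all__ = [
    "GridSpec",
    "SyntheticTruth",
    "DEFAULT_FLUIDS",
    "DEFAULT_TRUTH",
    "generate_condition_grid",
    "true_diameter",
    "generate_observations",
    "generate_droplet_population",
]

logger = logging.getLogger(__name__)

#: Synthetic aqueous phase: water-like density and viscosity, a
#: surfactant-laden oil interface (5 mN/m) and hydrophobic walls (120 deg).
DEFAULT_FLUIDS = FluidSystem.from_lab(
    rho_kg_m3=1000.0, mu_mPa_s=1.0, gamma_mN_m=5.0, theta_deg=120.0
)


@dataclass(frozen=True)
class GridSpec:
    """Layout of the synthetic condition grid (lab units)."""

    channel_widths_um: tuple[float, ...] = (20.0, 30.0, 40.0)
    channel_length_mm: float = 5.0
    accelerations: tuple[float, ...] = (1500.0, 2500.0, 3600.0, 4800.0, 6579.7)
    r2_mm: tuple[float, ...] = (4.0, 5.0, 6.0, 7.0)
    nozzle_radius_mm: float = 24.0
    fluids: FluidSystem = DEFAULT_FLUIDS
    weber_threshold: float = 1.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth exponential law family and noise model.

    ``ln alpha(a) = ln_alpha0 + ln_alpha_slope * a`` and
    ``beta(a) = beta0 + beta_slope * a``; ``diameter_cv_pct`` is the
    within-condition droplet polydispersity and ``condition_scatter_pct``
    the between-condition scatter of the mean diameter about the law
    (run-to-run reproducibility), both as lognormal CVs in percent.
    """

    ln_alpha0: float = 12.9
    ln_alpha_slope: float = -3.0e-4  # per (m/s^2)
    beta0: float = 9500.0  # 1/m
    beta_slope: float = 0.48  # 1/m per (m/s^2)
    diameter_cv_pct: float = 1.0
    condition_scatter_pct: float = 1.0

    def alpha(self, acceleration: float) -> float:
        return math.exp(self.ln_alpha0 + self.ln_alpha_slope * acceleration)

    def beta(self, acceleration: float) -> float:
        return self.beta0 + self.beta_slope * acceleration

    def law(self, acceleration: float) -> ExpLaw:
        return ExpLaw(acceleration, self.alpha(acceleration), self.beta(acceleration))


DEFAULT_TRUTH = SyntheticTruth()


def generate_condition_grid(spec: GridSpec = GridSpec()) -> list[EmulsificationCondition]:
    """Expand the spec into the full condition grid (60 conditions by default).

    Conditions in the dripping-faucet regime are kept in the grid (they are
    real settings one can run), but raise an error if *no* condition at all
    is in the periodic-dripping regime.
    """
    conditions: list[EmulsificationCondition] = []
    r_noz = spec.nozzle_radius_mm * units.MM
    for w_um in spec.channel_widths_um:
        channel = ChannelGeometry.from_lab(w_um, w_um, spec.channel_length_mm)
        for a in spec.accelerations:
            omega = math.sqrt(a / r_noz)
            for r2_mm in spec.r2_mm:
                r2 = r2_mm * units.MM
                rotor = RotorConfig(omega, r_noz - r2, r2)
                conditions.append(
                    EmulsificationCondition(channel, spec.fluids, rotor, spec.weber_threshold)
                )
    if not any(c.regime == PERIODIC_DRIPPING and not c.state.no_flow for c in conditions):
        raise ParameterError("grid spec yields no periodic-dripping conditions")
    return conditions


def true_diameter(condition: EmulsificationCondition, truth: SyntheticTruth) -> float:
    """Noise-free droplet diameter implied by the truth law for a condition.

    Solved tighter than the prediction default so that fits on noise-free
    synthetic data recover the truth coefficients to near machine precision.
    """
    return _solve_diameter(condition, truth.law(condition.acceleration), xtol=1e-13)


def generate_observations(
    conditions: Sequence[EmulsificationCondition],
    truth: SyntheticTruth = DEFAULT_TRUTH,
    n_droplets: int = 1000,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
):
    """Draw droplet-size observations for every model-eligible condition.

    Per condition the truth law is solved for the noise-free diameter, a
    condition-level lognormal factor (CV ``condition_scatter_pct``) shifts
    the population centre, and ``n_droplets`` individual diameters are
    drawn around it with CV ``diameter_cv_pct``; the sample mean, sample CV
    and count are emitted.  Conditions with no flow, in the dripping-faucet
    regime, or outside the law's support are skipped with a log entry.
    """
    from .predictor import DropletObservation

    if rng is None:
        rng = np.random.default_rng(seed)
    observations: list[DropletObservation] = []
    for idx, condition in enumerate(conditions):
        if condition.state.no_flow:
            logger.info("condition %d skipped: no flow", idx)
            continue
        if condition.regime != PERIODIC_DRIPPING:
            logger.info(
                "condition %d skipped: dripping faucet (We=%.3g)", idx, condition.state.weber
            )
            continue
        try:
            d_star = true_diameter(condition, truth)
        except (OutsideModelRangeError, NoFlowError) as exc:
            logger.info("condition %d skipped: %s", idx, exc)
            continue
        scatter_cv = truth.condition_scatter_pct / 100.0
        if scatter_cv > 0:
            sigma_c = math.sqrt(math.log1p(scatter_cv**2))
            centre = d_star * rng.lognormal(-0.5 * sigma_c**2, sigma_c)
        else:
            centre = d_star
        droplet_cv = truth.diameter_cv_pct / 100.0
        if droplet_cv > 0:
            sigma_d = math.sqrt(math.log1p(droplet_cv**2))
            draws = centre * rng.lognormal(-0.5 * sigma_d**2, sigma_d, size=n_droplets)
            mean_d = float(draws.mean())
            cv_pct = float(100.0 * draws.std(ddof=1) / mean_d)
        else:
            mean_d = centre
            cv_pct = 0.0
        observations.append(DropletObservation(condition, mean_d, cv_pct, n_droplets))
    return observations


def generate_droplet_population(
    concentration_per_uL: float,
    diameter: float,
    n_droplets: int,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    baseline: float = 100.0,
    separation: float = 100.0,
    noise_sd: float = 3.0,
    drift_amplitude: float = 10.0,
    drift_period: float = 500.0,
) -> DropletPopulation:
    """Synthetic fluorescence population at a known target concentration.

    Occupancy is Poisson with mean ``C * V`` (``V`` from ``diameter`` in
    metres); intensity is ``baseline + drift_amplitude *
    sin(2*pi*index/drift_period) + noise``, shifted up by ``separation``
    for occupied droplets.  True occupancy labels are retained.  The drift
    defaults (amplitude 10% of the positive-negative separation, period
    500 droplets) emulate stitched-scan baseline fluctuation.
    """
    if n_droplets < 1:
        raise ParameterError("need at least one droplet")
    if concentration_per_uL < 0:
        raise ParameterError("concentration must be non-negative")
    if diameter <= 0:
        raise ParameterError("diameter must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    volume_uL = units.m3_to_uL(math.pi * diameter**3 / 6.0)
    lam = concentration_per_uL * volume_uL
    occupancy = rng.poisson(lam, size=n_droplets)
    labels = occupancy >= 1
    index = np.arange(n_droplets)
    intensities = (
        baseline
        + drift_amplitude * np.sin(2.0 * math.pi * index / drift_period)
        + rng.normal(0.0, noise_sd, size=n_droplets)
        + separation * labels
    )
    return DropletPopulation(intensities, index, volume_uL, labels)
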