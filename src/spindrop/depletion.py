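"""Sample depletion: the decline of inlet velocity as a finite volume drains.

The nozzles sit at a fixed radius ``R_noz`` on the rotor.  As the aqueous
phase drains through ``n`` identical parallel channels, the free surface of
the reservoir recedes radially outward, so the column height ``R2``
shrinks, the driving pressure drops, and the inlet velocity declines.  The
reservoir is modelled as a column of constant free-surface cross-section
``A_res``: ``R2(V) = V / A_res`` and ``R1(V) = R_noz - R2(V)``.

The volume obeys ``dV/dt = -n * w * h * V_in(V)``, a smooth non-stiff 1-D
ODE integrated with a classical fixed-step 4th-order Runge-Kutta scheme,
with the step halved until the summary velocities change by less than 0.1%.
The run terminates when the volume falls below ``1e-4 * V0`` (to avoid
division noise at the empty limit), when the flow stalls (hydrophobic
capillary pressure exceeding the remaining centrifugal head), or at an
optional time cap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from . import units
from .exceptions import DoesNotEmulsifyError, ParameterError
from .physics import (
    ChannelGeometry,
    FluidSystem,
    RotorConfig,
    capillary_pressure,
    hydraulic_resistance,
)

__all__ = [
    "ReservoirGeometry",
    "DepletionTrace",
    "DeclineSummary",
    "simulate_depletion",
    "decline_summary",
]

#: Stop once the remaining volume drops below this fraction of the initial one.
VOLUME_FLOOR_FRACTION = 1e-4


@dataclass(frozen=True)
class ReservoirGeometry:
    """Sample reservoir feeding ``n_channels`` identical parallel channels.

    ``area`` is the free-surface cross-section (m^2), ``volume0`` the initial
    aqueous volume (m^3), ``nozzle_radius`` the fixed radial position of the
    nozzles (m).  The initial liquid column must fit between the rotation
    axis and the nozzles: ``volume0 / area <= nozzle_radius``.
    """

    area: float
    volume0: float
    n_channels: int
    nozzle_radius: float

    def __post_init__(self) -> None:
        if self.area <= 0 or self.volume0 <= 0 or self.nozzle_radius <= 0:
            raise ParameterError("reservoir area, volume and nozzle radius must be positive")
        if self.n_channels < 0:
            raise ParameterError("channel count must be non-negative")
        if self.volume0 / self.area > self.nozzle_radius:
            raise ParameterError("initial column height exceeds the nozzle radius")

    def rotor_at(self, volume: float, omega: float) -> RotorConfig:
        r2 = volume / self.area
        return RotorConfig(omega, self.nozzle_radius - r2, r2)


@dataclass
class DepletionTrace:
    """Time series of a depletion run (SI units)."""

    time: np.ndarray
    volume: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    v_in: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        if any(len(arr) != n for arr in (self.volume, self.r1, self.r2, self.v_in)):
            raise ParameterError("trace arrays must have equal length")

    @property
    def dispensed_volume(self) -> float:
        """Total volume pushed through the channels (m^3)."""
        return float(self.volume[0] - self.volume[-1]) if len(self.volume) else 0.0

    def to_csv(self, path: str | Path) -> None:
        """Write the trace as CSV with lab-unit columns."""
        import pandas as pd

        frame = pd.DataFrame(
            {
                "t_s": self.time,
                "V_uL": self.volume / units.UL,
                "R1_mm": self.r1 / units.MM,
                "R2_mm": self.r2 / units.MM,
                "Vin_mm_s": self.v_in / units.MM,
            }
        )
        frame.to_csv(path, index=False, float_format="%.10g")


class DeclineSummary(NamedTuple):
    v_begin: float
    v_end: float
    decline_pct: float


def decline_summary(trace: DepletionTrace) -> DeclineSummary:
    """Begin/end inlet velocities and the relative decline in percent."""
    if len(trace.time) == 0:
        raise ParameterError("empty depletion trace")
    v0 = float(trace.v_in[0])
    v1 = float(trace.v_in[-1])
    decline = 0.0 if v0 == 0.0 else 100.0 * (v0 - v1) / v0
    return DeclineSummary(v0, v1, decline)


def _integrate(
    reservoir: ReservoirGeometry,
    channel: ChannelGeometry,
    fluids: FluidSystem,
    omega: float,
    n_steps: int,
    t_max: float | None,
) -> DepletionTrace:
    # Only the centrifugal head varies with the remaining volume; the
    # capillary pressure and duct resistance are fixed by the geometry.
    p_cap = capillary_pressure(channel, fluids)
    r_hyd = hydraulic_resistance(channel, fluids)
    area = channel.cross_section
    half_rho_omega2 = 0.5 * fluids.density * omega**2
    r_noz = reservoir.nozzle_radius

    def velocity(volume: float) -> float:
        r1 = r_noz - volume / reservoir.area
        total = half_rho_omega2 * (r_noz**2 - r1**2) + p_cap
        return total / (r_hyd * area) if total > 0.0 else 0.0

    def dv_dt(volume: float) -> float:
        return -reservoir.n_channels * area * velocity(volume)

    v0 = velocity(reservoir.volume0)
    if v0 <= 0.0:
        raise DoesNotEmulsifyError("condition does not emulsify: no flow at the initial volume")

    floor = VOLUME_FLOOR_FRACTION * reservoir.volume0
    q0 = reservoir.n_channels * channel.cross_section * v0

    if q0 == 0.0:
        # Degenerate guard: no channels drain the reservoir.
        horizon = t_max if t_max is not None else 1.0
        t = np.array([0.0, horizon])
        vol = np.full(2, reservoir.volume0)
        r2 = vol / reservoir.area
        return DepletionTrace(t, vol, reservoir.nozzle_radius - r2, r2, np.full(2, v0))

    drain_estimate = reservoir.volume0 / q0
    dt = drain_estimate / n_steps
    max_steps = 60 * n_steps

    times = [0.0]
    volumes = [reservoir.volume0]
    vels = [v0]
    vol = reservoir.volume0
    t = 0.0
    for _ in range(max_steps):
        if t_max is not None and t >= t_max:
            break
        k1 = dv_dt(vol)
        k2 = dv_dt(max(vol + 0.5 * dt * k1, floor))
        k3 = dv_dt(max(vol + 0.5 * dt * k2, floor))
        k4 = dv_dt(max(vol + dt * k3, floor))
        vol_next = vol + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        t += dt
        if vol_next <= floor:
            vol = floor
            times.append(t)
            volumes.append(vol)
            vels.append(velocity(vol))
            break
        vol = vol_next
        v = velocity(vol)
        times.append(t)
        volumes.append(vol)
        vels.append(v)
        # A hydrophobic channel stalls asymptotically as the head decays
        # towards the capillary pressure; treat a velocity below 1e-6 of
        # the starting one as no flow.
        if v <= 1e-6 * v0:
            break
    vol_arr = np.array(volumes)
    r2 = vol_arr / reservoir.area
    return DepletionTrace(np.array(times), vol_arr, reservoir.nozzle_radius - r2, r2, np.array(vels))


def simulate_depletion(
    reservoir: ReservoirGeometry,
    channel: ChannelGeometry,
    fluids: FluidSystem,
    omega: float,
    n_steps: int = 2000,
    refine: bool = True,
    refine_rtol: float = 1e-3,
    t_max: float | None = None,
) -> DepletionTrace:
    """Integrate the draining reservoir and return the full trace.

    With ``refine=True`` the fixed step is halved (up to 5 times) until the
    end-of-run velocity changes by less than ``refine_rtol`` relative.
    """
    if n_steps < 2:
        raise ParameterError("need at least 2 integration steps")
    trace = _integrate(reservoir, channel, fluids, omega, n_steps, t_max)
    if not refine:
        return trace
    for _ in range(5):
        finer = _integrate(reservoir, channel, fluids, omega, 2 * n_steps, t_max)
        # Convergence judged against the begin velocity: the end velocity of
        # a stalled run is a near-zero asymptote with no meaningful relative
        # scale of its own.
        converged = abs(finer.v_in[-1] - trace.v_in[-1]) < refine_rtol * trace.v_in[0]
        trace = finer
        if converged:
            break
        n_steps *= 2
    return trace
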