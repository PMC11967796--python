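"""Closed-form centrifugal hydraulics for step emulsification.

In a centrifugal step emulsifier the aqueous phase sits in a reservoir on a
spinning rotor and is pushed through shallow rectangular microchannels whose
nozzles open into a deep oil-filled reservoir.  The mean inlet velocity in a
channel follows from three closed forms:

* the centrifugal driving pressure, obtained by integrating the centrifugal
  body force ``rho * omega**2 * r`` over the liquid column between the free
  surface (radius ``R1`` from the rotation axis) and the nozzle
  (radius ``R1 + R2``):  ``P_aqu = rho * omega**2 * ((R1+R2)**2 - R1**2) / 2``;
* the capillary pressure of a rectangular channel,
  ``P_cap = 2 * gamma * cos(theta) * (1/w + 1/h)``, negative for hydrophobic
  walls (contact angle above 90 degrees), which then oppose filling;
* the hydraulic resistance of a rectangular duct,
  ``R_hyd = 12 * mu * l / (w * h**3 * bracket(w, h))`` with the classical
  infinite-series bracket factor (0.4217 for a square duct).

The inlet velocity is ``V_in = (P_aqu + P_cap) / (R_hyd * w * h)``; a
non-positive pressure sum means the channel does not flow.  A Weber number
``We = rho * V_in**2 * D_h / gamma`` built on the hydraulic diameter
``D_h = 2*w*h/(w+h)`` separates the monodisperse periodic-dripping regime
(low ``We``) from the polydisperse dripping-faucet regime (high ``We``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import units
from .exceptions import ParameterError

__all__ = [
    "ChannelGeometry",
    "FluidSystem",
    "RotorConfig",
    "FlowState",
    "PERIODIC_DRIPPING",
    "DRIPPING_FAUCET",
    "DEFAULT_WEBER_THRESHOLD",
    "centrifugal_acceleration",
    "driving_pressure",
    "capillary_pressure",
    "rectangular_duct_factor",
    "hydraulic_resistance",
    "inlet_velocity",
    "flow_state",
    "weber_number",
    "classify_regime",
]

PERIODIC_DRIPPING = "periodic_dripping"
DRIPPING_FAUCET = "dripping_faucet"

#: Order-one inertia/capillarity crossover.  The regime boundary is a
#: heuristic: the underlying transition is not sharp, and no universal
#: numeric threshold exists for step emulsification.
DEFAULT_WEBER_THRESHOLD = 1.0

#: Maximum truncation tolerance accepted for the duct series.
_MAX_SERIES_RTOL = 1e-3


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular microchannel: cross-section ``width x height``, length ``length``.

    All lengths in metres.  ``max_cross_section`` is a sanity bound on the
    cross-section dimensions (default 1 mm: larger ducts are no longer
    microchannels and the lubrication-style closed forms degrade).
    """

    width: float
    height: float
    length: float
    max_cross_section: float = 1e-3

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0 and self.length > 0):
            raise ParameterError("channel dimensions must be strictly positive")
        if max(self.width, self.height) > self.max_cross_section:
            raise ParameterError(
                f"cross-section {max(self.width, self.height):g} m exceeds the "
                f"microchannel bound {self.max_cross_section:g} m"
            )
        if self.length <= max(self.width, self.height):
            raise ParameterError("channel length must exceed both cross-section dimensions")

    @classmethod
    def from_lab(
        cls, w_um: float, h_um: float, l_mm: float, max_cross_section: float = 1e-3
    ) -> "ChannelGeometry":
        """Build from lab units (width/height in um, length in mm)."""
        return cls(w_um * units.UM, h_um * units.UM, l_mm * units.MM, max_cross_section)

    @property
    def cross_section(self) -> float:
        """Cross-sectional area ``w*h`` (m^2)."""
        return self.width * self.height

    @property
    def hydraulic_diameter(self) -> float:
        """``2*w*h/(w+h)`` (m); also the zero of the resistance-factor bracket."""
        return 2.0 * self.width * self.height / (self.width + self.height)


@dataclass(frozen=True)
class FluidSystem:
    """Aqueous-phase properties and wetting against the channel walls.

    density kg/m^3, viscosity Pa*s, interfacial tension N/m against the oil
    phase, contact angle in radians (above pi/2 for hydrophobic walls).
    """

    density: float
    viscosity: float
    interfacial_tension: float
    contact_angle: float

    def __post_init__(self) -> None:
        if not (self.density > 0 and self.viscosity > 0 and self.interfacial_tension > 0):
            raise ParameterError("density, viscosity and interfacial tension must be positive")
        if not 0.0 <= self.contact_angle <= math.pi:
            raise ParameterError("contact angle must lie in [0, pi] radians")

    @classmethod
    def from_lab(
        cls,
        rho_kg_m3: float,
        mu_mPa_s: float,
        gamma_mN_m: float,
        theta_deg: float,
    ) -> "FluidSystem":
        return cls(
            rho_kg_m3,
            mu_mPa_s * units.MPA_S,
            gamma_mN_m * units.MN_PER_M,
            units.deg_to_rad(theta_deg),
        )


@dataclass(frozen=True)
class RotorConfig:
    """Rotor state: angular velocity (rad/s) and liquid-column radii (m).

    ``r1`` is the distance from the rotation axis to the free surface of the
    aqueous phase; ``r2`` is the distance from that surface to the nozzles,
    so the nozzles sit at radius ``r1 + r2``.
    """

    omega: float
    r1: float
    r2: float

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ParameterError("angular velocity must be non-negative")
        if self.r1 < 0 or self.r2 <= 0:
            raise ParameterError("rotor radii must satisfy r1 >= 0, r2 > 0")

    @classmethod
    def from_lab(cls, omega_rpm: float, r1_mm: float, r2_mm: float) -> "RotorConfig":
        return cls(units.rpm_to_rad_per_s(omega_rpm), r1_mm * units.MM, r2_mm * units.MM)

    @property
    def nozzle_radius(self) -> float:
        return self.r1 + self.r2


@dataclass(frozen=True)
class FlowState:
    """Resolved hydraulics of one emulsification condition (SI units)."""

    driving_pressure: float
    capillary_pressure: float
    hydraulic_resistance: float
    inlet_velocity: float
    weber: float
    regime: str
    no_flow: bool


def centrifugal_acceleration(rotor: RotorConfig) -> float:
    """Centrifugal acceleration at the nozzle, ``omega**2 * (r1 + r2)`` (m/s^2)."""
    return rotor.omega**2 * rotor.nozzle_radius


def driving_pressure(rotor: RotorConfig, fluids: FluidSystem) -> float:
    """Centrifugal driving pressure of the liquid column (Pa).

    Closed form of the body-force integral over [r1, r1+r2]:
    ``0.5 * rho * omega**2 * ((r1+r2)**2 - r1**2)``.  Non-negative.
    """
    return 0.5 * fluids.density * rotor.omega**2 * (rotor.nozzle_radius**2 - rotor.r1**2)


def capillary_pressure(channel: ChannelGeometry, fluids: FluidSystem) -> float:
    """Capillary pressure of a rectangular channel (Pa).

    ``2 * gamma * cos(theta) * (1/w + 1/h)``; negative for hydrophobic walls.
    """
    return (
        2.0
        * fluids.interfacial_tension
        * math.cos(fluids.contact_angle)
        * (1.0 / channel.width + 1.0 / channel.height)
    )


def rectangular_duct_factor(width: float, height: float, series_rtol: float = 1e-12) -> float:
    """Series bracket factor of the rectangular-duct resistance.

    ``1 - (192*h / (pi^5 * w)) * sum_{i odd} tanh(i*pi*w/(2*h)) / i^5``
    evaluated with the smaller dimension in the role of ``h`` (the series
    converges only in that convention, and the physical resistance is
    symmetric in ``w`` and ``h``).  Terms are added until a term's relative
    contribution drops below ``series_rtol``.  Equals 0.42173 for a square
    duct and tends to 1 in the parallel-plate limit ``w >> h``.
    """
    if width <= 0 or height <= 0:
        raise ParameterError("duct dimensions must be positive")
    if not 0.0 < series_rtol <= _MAX_SERIES_RTOL:
        raise ParameterError(f"series tolerance must lie in (0, {_MAX_SERIES_RTOL:g}]")
    wide = max(width, height)
    narrow = min(width, height)
    total = 0.0
    i = 1
    while i < 2000:
        term = math.tanh(i * math.pi * wide / (2.0 * narrow)) / i**5
        total += term
        if term < series_rtol * total:
            break
        i += 2
    return 1.0 - (192.0 * narrow / (math.pi**5 * wide)) * total


def hydraulic_resistance(
    channel: ChannelGeometry, fluids: FluidSystem, series_rtol: float = 1e-12
) -> float:
    """Hydraulic resistance of the rectangular channel (Pa*s/m^3).

    ``12 * mu * l / (w * h**3 * bracket)`` with ``h = min(w, h)`` and the
    series bracket factor in the denominator.
    """
    wide = max(channel.width, channel.height)
    narrow = min(channel.width, channel.height)
    factor = rectangular_duct_factor(wide, narrow, series_rtol)
    return 12.0 * fluids.viscosity * channel.length / (wide * narrow**3 * factor)


def weber_number(v_in: float, channel: ChannelGeometry, fluids: FluidSystem) -> float:
    """``We = rho * V_in**2 * D_h / gamma`` on the hydraulic diameter."""
    return fluids.density * v_in**2 * channel.hydraulic_diameter / fluids.interfacial_tension


def classify_regime(
    v_in: float,
    channel: ChannelGeometry,
    fluids: FluidSystem,
    threshold: float = DEFAULT_WEBER_THRESHOLD,
) -> str:
    """Label the generation regime from the Weber number.

    Returns ``periodic_dripping`` iff ``We < threshold``; the boundary value
    itself is assigned to ``dripping_faucet`` (tie-break by definition).
    """
    return PERIODIC_DRIPPING if weber_number(v_in, channel, fluids) < threshold else DRIPPING_FAUCET


def flow_state(
    channel: ChannelGeometry,
    fluids: FluidSystem,
    rotor: RotorConfig,
    weber_threshold: float = DEFAULT_WEBER_THRESHOLD,
    series_rtol: float = 1e-12,
) -> FlowState:
    """Resolve the full hydraulic state of one condition.

    A non-positive total pressure (hydrophobic capillary pressure exceeding
    the centrifugal head, as happens legitimately near the end of sample
    depletion) yields zero velocity with the ``no_flow`` flag set rather
    than an error.
    """
    p_aqu = driving_pressure(rotor, fluids)
    p_cap = capillary_pressure(channel, fluids)
    r_hyd = hydraulic_resistance(channel, fluids, series_rtol)
    total = p_aqu + p_cap
    if total <= 0.0:
        v_in = 0.0
        no_flow = True
    else:
        v_in = total / (r_hyd * channel.cross_section)
        no_flow = False
    we = weber_number(v_in, channel, fluids)
    regime = PERIODIC_DRIPPING if we < weber_threshold else DRIPPING_FAUCET
    return FlowState(p_aqu, p_cap, r_hyd, v_in, we, regime, no_flow)


def inlet_velocity(
    channel: ChannelGeometry,
    fluids: FluidSystem,
    rotor: RotorConfig,
    series_rtol: float = 1e-12,
) -> float:
    """Mean aqueous velocity in the channel (m/s); zero when there is no flow."""
    return flow_state(channel, fluids, rotor, series_rtol=series_rtol).inlet_velocity
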