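"""Droplet pre-design under tiling constraints.

Tiled droplets are observed as a monolayer in a reservoir of fixed area.
Each droplet of diameter ``D`` is given a square ``D x D`` footprint, the
square-minus-circle margin serving as inter-droplet spacing, so the circle
area available to droplets is ``pi/4`` of the (possibly reduced) reservoir
area.  With a sample volume ``V`` split into ``N = 6V/(pi D^3)`` droplets,
the accumulated circle area is ``N * pi D^2 / 4 = 1.5 V / D``: the area
budget caps the diameter from below, while a minimum droplet count (for
digital-assay dynamic range) caps it from above at
``D_max = (6V / (pi N_min))^(1/3)``.

Given an admissible window, generation conditions are reverse-engineered by
a grid search over a channel catalogue and a rotational-speed grid, keeping
conditions whose predicted diameter falls inside the window in the
periodic-dripping regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import units
from .exceptions import (
    NoFlowError,
    OutsideModelRangeError,
    ParameterError,
    UntrainedAccelerationError,
)
from .physics import PERIODIC_DRIPPING, ChannelGeometry, FluidSystem, RotorConfig
from .predictor import EmulsificationCondition, PredictiveModel, predict_diameter, predict_frequency

__all__ = [
    "TilingConstraints",
    "DiameterWindow",
    "DesignCandidate",
    "DesignResult",
    "area_budget",
    "droplet_count",
    "diameter_window",
    "mean_occupancy",
    "default_omega_grid",
    "reverse_engineer",
]

AREA_BUDGET_LABEL = "area_budget"
DROPLET_COUNT_LABEL = "droplet_count"


@dataclass(frozen=True)
class TilingConstraints:
    """Pre-design inputs: reservoir area (m^2), headroom fraction reserved for
    tiling, sample volume (m^3) and minimum droplet count."""

    reservoir_area: float
    sample_volume: float
    min_count: float
    reserve_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.reservoir_area <= 0 or self.sample_volume <= 0:
            raise ParameterError("reservoir area and sample volume must be positive")
        if self.min_count < 1:
            raise ParameterError("minimum droplet count must be at least 1")
        if not 0.0 <= self.reserve_fraction < 1.0:
            raise ParameterError("reserve fraction must lie in [0, 1)")


@dataclass(frozen=True)
class DiameterWindow:
    """Admissible diameter interval with the constraint binding each bound."""

    d_min: float
    d_max: float
    lower_constraint: str = AREA_BUDGET_LABEL
    upper_constraint: str = DROPLET_COUNT_LABEL

    @property
    def feasible(self) -> bool:
        return self.d_min <= self.d_max

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.d_min + self.d_max)


def area_budget(reservoir_area: float, reserve_fraction: float = 0.0) -> float:
    """Monolayer circle-area budget (m^2).

    ``A * (1 - reserve) * pi/4``: each droplet occupies the circle inscribed
    in its square footprint, and a fraction of the reservoir may be held
    back as tiling headroom.
    """
    if reservoir_area <= 0:
        raise ParameterError("reservoir area must be positive")
    if not 0.0 <= reserve_fraction < 1.0:
        raise ParameterError("reserve fraction must lie in [0, 1)")
    return reservoir_area * (1.0 - reserve_fraction) * math.pi / 4.0


def droplet_count(sample_volume: float, diameter: float) -> float:
    """Number of droplets of diameter ``D`` from volume ``V``: ``6V/(pi D^3)``.

    Real-valued (no dead volume); callers round for display.
    """
    if sample_volume <= 0 or diameter <= 0:
        raise ParameterError("sample volume and diameter must be positive")
    return 6.0 * sample_volume / (math.pi * diameter**3)


def diameter_window(
    constraints: TilingConstraints, budget: float | None = None
) -> DiameterWindow:
    """Admissible diameter window from an area budget and a count floor.

    ``D_min = 1.5 V / budget`` (the accumulated circle area ``1.5 V / D``
    must fit the budget) and ``D_max = (6V / (pi N_min))**(1/3)``.  The
    ``budget`` override lets a caller use an externally rounded budget
    verbatim instead of the rule-derived one.
    """
    if budget is None:
        budget = area_budget(constraints.reservoir_area, constraints.reserve_fraction)
    if budget <= 0:
        raise ParameterError("area budget must be positive")
    d_min = 1.5 * constraints.sample_volume / budget
    d_max = (6.0 * constraints.sample_volume / (math.pi * constraints.min_count)) ** (1.0 / 3.0)
    return DiameterWindow(d_min, d_max)


def mean_occupancy(concentration: float, diameter: float) -> float:
    """Expected entities per droplet: ``lambda = c * pi D^3 / 6``.

    ``concentration`` is a number concentration in 1/m^3 (see
    :func:`spindrop.units.per_mL_to_per_m3` for lab units).
    """
    if concentration < 0:
        raise ParameterError("concentration must be non-negative")
    if diameter <= 0:
        raise ParameterError("diameter must be positive")
    return concentration * math.pi * diameter**3 / 6.0


@dataclass(frozen=True)
class DesignCandidate:
    """A generation condition whose predicted diameter falls in the window."""

    condition: EmulsificationCondition
    diameter: float
    frequency: float
    regime: str


@dataclass(frozen=True)
class RejectedCondition:
    channel: ChannelGeometry
    omega: float
    reason: str


@dataclass
class DesignResult:
    candidates: list[DesignCandidate]
    rejections: list[RejectedCondition]


def default_omega_grid() -> np.ndarray:
    """Rotational speeds 500-6000 rpm in 100 rpm steps, in rad/s."""
    return np.array([units.rpm_to_rad_per_s(rpm) for rpm in range(500, 6001, 100)])


def reverse_engineer(
    model: PredictiveModel,
    window: DiameterWindow,
    channels: Sequence[ChannelGeometry],
    fluids: FluidSystem,
    r1: float,
    r2: float,
    omegas: Iterable[float] | None = None,
    interpolate: bool = False,
    d_max: float = 1e-3,
) -> DesignResult:
    """Grid-search generation conditions whose predicted diameter fits the window.

    For every channel and angular velocity, the inlet hydraulics are
    resolved, the regime checked, and the diameter predicted; candidates
    inside the window are returned sorted by distance to the window
    midpoint, everything else with a per-condition rejection reason.
    """
    if not window.feasible:
        raise ParameterError("infeasible diameter window (d_min > d_max)")
    if not channels:
        raise ParameterError("empty channel catalogue")
    omega_grid = default_omega_grid() if omegas is None else np.asarray(list(omegas), dtype=float)
    if omega_grid.size == 0:
        raise ParameterError("empty angular-velocity grid")

    candidates: list[DesignCandidate] = []
    rejections: list[RejectedCondition] = []
    for channel in channels:
        for omega in omega_grid:
            rotor = RotorConfig(float(omega), r1, r2)
            condition = EmulsificationCondition(channel, fluids, rotor)
            if window.d_max <= condition.diameter_floor:
                rejections.append(RejectedCondition(channel, float(omega), "below model support"))
                continue
            if condition.state.no_flow:
                rejections.append(RejectedCondition(channel, float(omega), "no flow"))
                continue
            if condition.regime != PERIODIC_DRIPPING:
                rejections.append(RejectedCondition(channel, float(omega), "dripping_faucet"))
                continue
            try:
                diameter = predict_diameter(
                    condition, model, d_max=d_max, interpolate=interpolate
                )
            except (UntrainedAccelerationError, OutsideModelRangeError, NoFlowError) as exc:
                rejections.append(RejectedCondition(channel, float(omega), str(exc)))
                continue
            if not window.d_min <= diameter <= window.d_max:
                rejections.append(
                    RejectedCondition(channel, float(omega), "diameter outside window")
                )
                continue
            candidates.append(
                DesignCandidate(
                    condition, diameter, predict_frequency(condition, diameter), condition.regime
                )
            )
    candidates.sort(key=lambda c: abs(c.diameter - window.midpoint))
    return DesignResult(candidates, rejections)
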