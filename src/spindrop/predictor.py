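"""Resistance-factor model: the droplet-size predictor.

In the periodic-dripping regime a droplet detaches when the liquid neck
("connection tube") between the channel exit and the growing droplet
collapses by Rayleigh-Plateau instability.  Lumping the neck's hydraulics
into a single resistance factor and balancing the Laplace pressure
difference between channel and droplet against the inlet flow rate gives

    R_f = 2 * gamma * (1/w + 1/h - 2/D) / V_in

which empirical/simulation data show follows an exponential law in the
droplet diameter at fixed centrifugal acceleration, irrespective of the
channel dimensions:

    R_f = alpha * exp(-beta * D)

with coefficients ``alpha`` (Pa*s/m) and ``beta`` (1/m) that vary only with
acceleration.  Equating the two expressions yields a single equation whose
unique root on ``(2*w*h/(w+h), D_max]`` is the predicted droplet diameter;
the generation frequency follows from volume conservation,
``f = 6 * w * h * V_in / (pi * D**3)``.

Fitting is done in log space (ordinary least squares of ``ln R_f`` on
``D``): the factors span orders of magnitude, and the log-linear fit has a
deterministic closed-form solution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .exceptions import (
    FitError,
    NoFlowError,
    OutsideModelRangeError,
    ParameterError,
    UntrainedAccelerationError,
)
from .physics import (
    DEFAULT_WEBER_THRESHOLD,
    PERIODIC_DRIPPING,
    ChannelGeometry,
    FlowState,
    FluidSystem,
    RotorConfig,
    centrifugal_acceleration,
    flow_state,
)

__all__ = [
    "EmulsificationCondition",
    "DropletObservation",
    "ExpLaw",
    "PredictiveModel",
    "EvaluationResult",
    "resistance_factor",
    "fit_exp_law",
    "predict_diameter",
    "predict_frequency",
    "evaluate_model",
]

#: Default relative tolerance when matching accelerations to fitted laws.
DEFAULT_ACCELERATION_RTOL = 0.01

#: Upper end of the diameter search bracket (m).
DEFAULT_D_MAX = 1e-3

#: Absolute diameter tolerance of the root finder (well inside the 1 nm
#: that matters physically; brentq reaches this at negligible extra cost).
DIAMETER_XTOL = 1e-12


@dataclass(frozen=True)
class EmulsificationCondition:
    """One generation condition: channel + fluids + rotor, with derived hydraulics."""

    channel: ChannelGeometry
    fluids: FluidSystem
    rotor: RotorConfig
    weber_threshold: float = DEFAULT_WEBER_THRESHOLD
    acceleration: float = field(init=False)
    state: FlowState = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "acceleration", centrifugal_acceleration(self.rotor))
        object.__setattr__(
            self, "state", flow_state(self.channel, self.fluids, self.rotor, self.weber_threshold)
        )

    @property
    def v_in(self) -> float:
        return self.state.inlet_velocity

    @property
    def regime(self) -> str:
        return self.state.regime

    @property
    def diameter_floor(self) -> float:
        """``2*w*h/(w+h)``: below this the resistance factor would be negative."""
        return self.channel.hydraulic_diameter


@dataclass(frozen=True)
class DropletObservation:
    """A measured droplet-size distribution under one condition.

    ``diameter`` is the mean droplet diameter (m), ``cv_pct`` the coefficient
    of variation of the distribution in percent, ``count`` the number of
    droplets measured.
    """

    condition: EmulsificationCondition
    diameter: float
    cv_pct: float = 0.0
    count: int = 1

    def __post_init__(self) -> None:
        if self.diameter <= self.condition.diameter_floor:
            raise ParameterError(
                "observed diameter must exceed the channel hydraulic diameter "
                f"({self.condition.diameter_floor:g} m)"
            )
        if self.cv_pct < 0:
            raise ParameterError("CV must be non-negative")
        if self.count < 1:
            raise ParameterError("droplet count must be at least 1")


@dataclass(frozen=True)
class ExpLaw:
    """Exponential law ``R_f = alpha * exp(-beta * D)`` at one acceleration."""

    acceleration: float
    alpha: float
    beta: float
    r_squared: float = 1.0
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError("exponential-law coefficients alpha, beta must be positive")

    def __call__(self, diameter: float) -> float:
        return self.alpha * math.exp(-self.beta * diameter)


def resistance_factor(condition: EmulsificationCondition, diameter: float) -> float:
    """Lumped neck resistance factor ``2*gamma*(1/w + 1/h - 2/D)/V_in`` (Pa*s/m).

    Zero at ``D = 2*w*h/(w+h)`` and strictly increasing in ``D``.
    """
    if diameter <= 0:
        raise ParameterError("diameter must be positive")
    if condition.v_in <= 0:
        raise NoFlowError("condition has no flow; resistance factor undefined")
    ch = condition.channel
    gamma = condition.fluids.interfacial_tension
    return 2.0 * gamma * (1.0 / ch.width + 1.0 / ch.height - 2.0 / diameter) / condition.v_in


def fit_exp_law(
    observations: Sequence[DropletObservation],
    acceleration_rtol: float = DEFAULT_ACCELERATION_RTOL,
) -> ExpLaw:
    """Fit ``ln R_f = ln alpha - beta * D`` over one acceleration group.

    Requires at least 3 observations, all at the same acceleration (within
    ``acceleration_rtol`` relative) and all with a positive resistance
    factor.  Returns the law with its log-space R-squared.
    """
    if len(observations) < 3:
        raise FitError(f"need >= 3 observations to fit, got {len(observations)}")
    accels = np.array([o.condition.acceleration for o in observations])
    a_ref = accels.mean()
    if np.any(np.abs(accels - a_ref) > acceleration_rtol * a_ref):
        raise FitError(
            "observations span more than one acceleration group: "
            f"range [{accels.min():.6g}, {accels.max():.6g}] m/s^2"
        )
    d = np.array([o.diameter for o in observations])
    rf = np.array([resistance_factor(o.condition, o.diameter) for o in observations])
    if np.any(rf <= 0):
        bad = int(np.sum(rf <= 0))
        raise FitError(f"{bad} observation(s) have non-positive resistance factor")
    y = np.log(rf)
    slope, intercept = np.polyfit(d, y, 1)
    beta = -slope
    if beta <= 0:
        raise FitError("fitted beta is non-positive: resistance factors do not decay with D")
    residuals = y - (intercept + slope * d)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return ExpLaw(float(a_ref), math.exp(intercept), float(beta), r2, len(observations))


def _group_by_acceleration(
    observations: Sequence[DropletObservation], rtol: float
) -> list[list[DropletObservation]]:
    """Cluster observations whose accelerations agree within ``rtol`` relative."""
    ordered = sorted(observations, key=lambda o: o.condition.acceleration)
    groups: list[list[DropletObservation]] = []
    for obs in ordered:
        a = obs.condition.acceleration
        if groups and abs(a - groups[-1][0].condition.acceleration) <= rtol * a:
            groups[-1].append(obs)
        else:
            groups.append([obs])
    return groups


@dataclass
class PredictiveModel:
    """A collection of per-acceleration exponential laws.

    Laws must be at accelerations distinct beyond ``acceleration_rtol``.
    Prediction at an unfitted acceleration raises by default; pass
    ``interpolate=True`` to :func:`predict_diameter` for piecewise-linear
    interpolation of ``ln alpha`` and ``beta`` in acceleration (an
    extension beyond the per-acceleration fits, flagged as such).
    """

    laws: list[ExpLaw]
    acceleration_rtol: float = DEFAULT_ACCELERATION_RTOL

    def __post_init__(self) -> None:
        self.laws = sorted(self.laws, key=lambda law: law.acceleration)
        for prev, cur in zip(self.laws, self.laws[1:]):
            if abs(cur.acceleration - prev.acceleration) <= self.acceleration_rtol * cur.acceleration:
                raise ParameterError(
                    "model laws must sit at accelerations distinct beyond the matching tolerance"
                )

    @property
    def accelerations(self) -> list[float]:
        return [law.acceleration for law in self.laws]

    def law_for(self, acceleration: float) -> ExpLaw:
        """Return the law matching ``acceleration`` within tolerance."""
        for law in self.laws:
            if abs(law.acceleration - acceleration) <= self.acceleration_rtol * acceleration:
                return law
        raise UntrainedAccelerationError(
            f"no fitted law at acceleration {acceleration:.6g} m/s^2 "
            f"(trained at {[f'{a:.5g}' for a in self.accelerations]})"
        )

    def interpolated_law(self, acceleration: float) -> ExpLaw:
        """Piecewise-linear interpolation of ``ln alpha`` and ``beta`` in acceleration.

        Only defined strictly inside the trained acceleration span.
        """
        try:
            return self.law_for(acceleration)
        except UntrainedAccelerationError:
            pass
        a = np.array(self.accelerations)
        if len(a) < 2 or not (a[0] <= acceleration <= a[-1]):
            raise UntrainedAccelerationError(
                f"acceleration {acceleration:.6g} m/s^2 outside the trained span "
                f"[{a[0] if len(a) else float('nan'):.6g}, {a[-1] if len(a) else float('nan'):.6g}]"
            )
        ln_alpha = float(np.interp(acceleration, a, np.log([law.alpha for law in self.laws])))
        beta = float(np.interp(acceleration, a, [law.beta for law in self.laws]))
        return ExpLaw(acceleration, math.exp(ln_alpha), beta, float("nan"), 0)

    @classmethod
    def fit(
        cls,
        observations: Sequence[DropletObservation],
        acceleration_rtol: float = DEFAULT_ACCELERATION_RTOL,
    ) -> "PredictiveModel":
        """Group observations by acceleration and fit one law per group."""
        groups = _group_by_acceleration(observations, acceleration_rtol)
        laws = [fit_exp_law(group, acceleration_rtol) for group in groups]
        return cls(laws, acceleration_rtol)

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize as a JSON list of law records."""
        payload = [
            {
                "a_m_s2": law.acceleration,
                "alpha": law.alpha,
                "beta": law.beta,
                "r2": law.r_squared,
                "n": law.n_points,
            }
            for law in self.laws
        ]
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PredictiveModel":
        if isinstance(source, Path) or not str(source).lstrip().startswith("["):
            text = Path(source).read_text()
        else:
            text = str(source)
        records = json.loads(text)
        laws = [
            ExpLaw(rec["a_m_s2"], rec["alpha"], rec["beta"], rec.get("r2", 1.0), rec.get("n", 0))
            for rec in records
        ]
        return cls(laws)


def _solve_diameter(
    condition: EmulsificationCondition,
    law: ExpLaw,
    d_max: float = DEFAULT_D_MAX,
    xtol: float = DIAMETER_XTOL,
) -> float:
    """Root of ``resistance_factor(D) = law(D)`` on ``(D_floor, d_max]``.

    The left side rises strictly from 0 and the right side is positive and
    strictly decreasing, so at most one root exists; the bracket is
    certified by sign change before solving.
    """
    if condition.v_in <= 0:
        raise NoFlowError("condition has no flow; cannot predict a diameter")
    lo = condition.diameter_floor * (1.0 + 1e-6)
    if d_max <= lo:
        raise OutsideModelRangeError("search bracket collapses: d_max below model support")

    def residual(d: float) -> float:
        return resistance_factor(condition, d) - law(d)

    f_lo = residual(lo)
    f_hi = residual(d_max)
    if f_lo >= 0.0 or f_hi <= 0.0:
        raise OutsideModelRangeError(
            f"no diameter in ({lo:.4g}, {d_max:.4g}] m satisfies the law at "
            f"a={law.acceleration:.5g} m/s^2 (residuals {f_lo:.3g}, {f_hi:.3g})"
        )
    return float(brentq(residual, lo, d_max, xtol=xtol))


def predict_diameter(
    condition: EmulsificationCondition,
    model: PredictiveModel,
    d_max: float = DEFAULT_D_MAX,
    interpolate: bool = False,
    require_dripping: bool = True,
) -> float:
    """Predict the droplet diameter (m) for a condition.

    The condition must be in the periodic-dripping regime (the law holds
    only there) and its acceleration must match a fitted law within the
    model tolerance, unless ``interpolate=True`` enables the flagged
    piecewise-linear extension.
    """
    if require_dripping and condition.regime != PERIODIC_DRIPPING:
        raise OutsideModelRangeError(
            f"condition is in the {condition.regime} regime (We={condition.state.weber:.3g}); "
            "the predictive law applies to periodic dripping only"
        )
    law = model.interpolated_law(condition.acceleration) if interpolate else model.law_for(
        condition.acceleration
    )
    return _solve_diameter(condition, law, d_max)


def predict_frequency(condition: EmulsificationCondition, diameter: float) -> float:
    """Generation frequency ``6*w*h*V_in/(pi*D**3)`` (1/s).

    Volumetric throughput divided by the volume of one droplet.
    """
    if diameter <= 0:
        raise ParameterError("diameter must be positive")
    if condition.v_in <= 0:
        raise NoFlowError("condition has no flow; frequency undefined")
    return 6.0 * condition.channel.cross_section * condition.v_in / (math.pi * diameter**3)


@dataclass
class EvaluationResult:
    """Train/validate outcome: mean absolute relative diameter error (%)."""

    mean_abs_rel_error_pct: float
    errors_pct: np.ndarray
    model: PredictiveModel
    n_train: int
    n_validation: int


def evaluate_model(
    observations: Sequence[DropletObservation],
    train_fraction: float = 2.0 / 3.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    acceleration_rtol: float = DEFAULT_ACCELERATION_RTOL,
) -> EvaluationResult:
    """Random train/validation split stratified by acceleration.

    Fits laws on the training split and reports the mean over validation
    points of ``100 * |D_pred - D_obs| / D_obs``.  Each acceleration
    stratum must contribute at least 3 training points.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError("train fraction must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    groups = _group_by_acceleration(observations, acceleration_rtol)
    if len(groups) < 2:
        raise FitError("dataset must span at least 2 accelerations")
    train: list[DropletObservation] = []
    validation: list[DropletObservation] = []
    deficient: list[str] = []
    for group in groups:
        m = len(group)
        n_train = int(round(train_fraction * m))
        n_train = min(max(n_train, 1), m - 1) if m > 1 else m
        if n_train < 3:
            deficient.append(
                f"a={group[0].condition.acceleration:.5g} m/s^2: {n_train} training point(s)"
            )
        order = rng.permutation(m)
        train.extend(group[i] for i in order[:n_train])
        validation.extend(group[i] for i in order[n_train:])
    if deficient:
        raise FitError("strata with fewer than 3 training points: " + "; ".join(deficient))
    model = PredictiveModel.fit(train, acceleration_rtol)
    errors = np.array(
        [
            100.0
            * abs(predict_diameter(obs.condition, model) - obs.diameter)
            / obs.diameter
            for obs in validation
        ]
    )
    return EvaluationResult(float(errors.mean()), errors, model, len(train), len(validation))
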