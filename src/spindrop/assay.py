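"""Digital-assay statistics downstream of droplet generation.

A tiled droplet array is scanned, per-droplet fluorescence intensities are
extracted, and droplets are called positive or negative.  The analyte
concentration then follows from Poisson statistics: if targets are
randomly discretized into droplets of volume ``V``, the fraction of empty
droplets is ``exp(-C*V)``, so

    C = -ln(1 - p) / V

with ``p`` the positive fraction.  This module also covers the
dilution-series linearity check (log10-log10 ordinary least squares), the
limit of detection (lowest concentration positive in all replicates), and
the minimum inhibitory concentration read off a droplet-survival curve at
a 10% survival cutoff.

Thresholding follows the two-pass scheme used with stitched scans:
a global threshold (mean of negative-control intensities plus three SD)
gives provisional labels, then each droplet is re-tested against the mean
plus five SD of its ten nearest provisionally-negative neighbours in scan
order, which tracks slow periodic baseline drift across stitched tiles.

Units: this module works in the units assay practitioners use — droplet
volumes in microlitres, concentrations per microlitre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import ParameterError, SaturatedAssayError

__all__ = [
    "DropletPopulation",
    "ClassificationResult",
    "ConcentrationEstimate",
    "SusceptibilityCurve",
    "LinearFit",
    "global_threshold",
    "local_classify",
    "poisson_concentration",
    "quantify",
    "dilution_linearity",
    "lod",
    "mic",
]


@dataclass
class DropletPopulation:
    """Per-droplet intensities with scan positions and a common droplet volume.

    ``volume_uL`` is the volume of one droplet in microlitres.
    ``true_labels`` is only ever set on synthetic populations.
    """

    intensities: np.ndarray
    positions: np.ndarray
    volume_uL: float
    true_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.positions = np.asarray(self.positions)
        if self.intensities.ndim != 1 or len(self.intensities) != len(self.positions):
            raise ParameterError("intensities and positions must be 1-D and equal length")
        if not np.all(np.isfinite(self.intensities)):
            raise ParameterError("intensities must be finite")
        if self.volume_uL <= 0:
            raise ParameterError("droplet volume must be positive")
        if len(np.unique(self.positions)) != len(self.positions):
            raise ParameterError("droplet positions must be unique")
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels, dtype=bool)
            if len(self.true_labels) != len(self.intensities):
                raise ParameterError("true labels must match the droplet count")

    def __len__(self) -> int:
        return len(self.intensities)


@dataclass
class ClassificationResult:
    """Per-droplet calls and the positive fraction ``p``."""

    labels: np.ndarray
    positive_fraction: float
    global_threshold: float
    method: str = "local"
    fallback_warning: bool = False


@dataclass
class ConcentrationEstimate:
    """Concentration (per uL) with the inputs it came from and an optional
    Wilson interval on ``p`` propagated through the Poisson inversion."""

    concentration_per_uL: float
    positive_fraction: float
    volume_uL: float
    interval_per_uL: tuple[float, float] | None = None


def global_threshold(control_intensities: Sequence[float], n_sd: float = 3.0) -> float:
    """Mean of negative-control intensities plus ``n_sd`` sample SDs."""
    values = np.asarray(control_intensities, dtype=float)
    if values.size < 2:
        raise ParameterError("need at least 2 control intensities")
    return float(values.mean() + n_sd * values.std(ddof=1))


def _iterated_global_threshold(intensities: np.ndarray, n_sd: float = 3.0) -> float:
    """Self-referential global threshold when no negative control is supplied.

    Starting from the droplets below the intensity mid-range (which isolates
    the negative mode of a bimodal population even near saturation), iterate
    mean+3SD over the droplets currently called negative until the labels
    stabilise; with a clear bimodal population this converges to the
    control-based threshold.
    """
    midrange = 0.5 * (intensities.min() + intensities.max())
    negatives = intensities <= midrange
    threshold = midrange
    for _ in range(100):
        subset = intensities[negatives]
        if subset.size < 2:
            break
        new_threshold = float(subset.mean() + n_sd * subset.std(ddof=1))
        new_negatives = intensities <= new_threshold
        threshold = new_threshold
        if np.array_equal(new_negatives, negatives):
            break
        negatives = new_negatives
    return threshold


def _k_nearest_negatives(
    positions: np.ndarray, neg_sorted_idx: np.ndarray, self_idx: int, k: int
) -> list[int]:
    """Indices of the k nearest provisional negatives by scan position."""
    neg_pos = positions[neg_sorted_idx]
    pos = positions[self_idx]
    j = int(np.searchsorted(neg_pos, pos))
    lo, hi = j - 1, j
    chosen: list[int] = []
    while len(chosen) < k and (lo >= 0 or hi < len(neg_pos)):
        take_lo = False
        if lo >= 0 and hi < len(neg_pos):
            take_lo = abs(pos - neg_pos[lo]) <= abs(neg_pos[hi] - pos)
        elif lo >= 0:
            take_lo = True
        if take_lo:
            idx = neg_sorted_idx[lo]
            lo -= 1
        else:
            idx = neg_sorted_idx[hi]
            hi += 1
        if idx != self_idx:
            chosen.append(int(idx))
    return chosen


def local_classify(
    population: DropletPopulation,
    k: int = 10,
    multiplier: float = 5.0,
    control_intensities: Sequence[float] | None = None,
    global_n_sd: float = 3.0,
) -> ClassificationResult:
    """Two-pass droplet classification robust to stitching baseline drift.

    Pass 1 labels droplets with the global threshold (from the negative
    control if given, else the iterated self-referential variant).  Pass 2
    re-tests every droplet against ``mean + multiplier * SD`` of its ``k``
    nearest provisionally-negative neighbours in scan order ("exceeds" is
    strict: a droplet exactly at threshold is negative).  Neighbourhoods
    with zero SD fall back to the global threshold for that droplet, and if
    fewer than ``k`` provisional negatives exist at all, the global labels
    are returned with a warning flag.
    """
    if k < 1:
        raise ParameterError("neighbourhood size k must be at least 1")
    x = population.intensities
    if control_intensities is not None:
        thr = global_threshold(control_intensities, global_n_sd)
    else:
        thr = _iterated_global_threshold(x, global_n_sd)
    provisional_positive = x > thr
    neg_idx = np.flatnonzero(~provisional_positive)
    if neg_idx.size < k:
        p = float(provisional_positive.mean())
        return ClassificationResult(provisional_positive, p, thr, "global_fallback", True)

    # Sort provisional negatives by scan position for nearest-neighbour lookup.
    order = np.argsort(population.positions[neg_idx], kind="stable")
    neg_sorted = neg_idx[order]
    labels = np.empty(len(x), dtype=bool)
    for i in range(len(x)):
        neighbours = _k_nearest_negatives(population.positions, neg_sorted, i, k)
        vals = x[neighbours]
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        local_thr = thr if sd == 0.0 else float(vals.mean() + multiplier * sd)
        labels[i] = x[i] > local_thr
    return ClassificationResult(labels, float(labels.mean()), thr, "local", False)


def poisson_concentration(
    positive_fraction: float,
    volume_uL: float,
    n_droplets: int | None = None,
    confidence: float | None = None,
) -> ConcentrationEstimate:
    """Invert the Poisson empty-droplet fraction: ``C = -ln(1-p)/V`` (per uL).

    With ``n_droplets`` and ``confidence`` given, attaches a Wilson score
    interval on ``p`` propagated through the inversion (an extension beyond
    the point estimate).
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ParameterError("positive fraction must lie in [0, 1]")
    if volume_uL <= 0:
        raise ParameterError("droplet volume must be positive")
    if positive_fraction == 1.0:
        raise SaturatedAssayError("all droplets positive: concentration unbounded")
    c = -math.log1p(-positive_fraction) / volume_uL
    interval = None
    if confidence is not None:
        if n_droplets is None or n_droplets < 1:
            raise ParameterError("a droplet count is required for a confidence interval")
        z = stats.norm.ppf(0.5 + confidence / 2.0)
        p, n = positive_fraction, n_droplets
        centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        p_lo, p_hi = max(centre - half, 0.0), min(centre + half, 1.0 - 1e-15)
        interval = (-math.log1p(-p_lo) / volume_uL, -math.log1p(-p_hi) / volume_uL)
    return ConcentrationEstimate(c, positive_fraction, volume_uL, interval)


def quantify(
    population: DropletPopulation,
    control_intensities: Sequence[float] | None = None,
    k: int = 10,
    multiplier: float = 5.0,
    confidence: float | None = None,
) -> tuple[ConcentrationEstimate, ClassificationResult]:
    """Classify a population and invert the positive fraction to a concentration."""
    result = local_classify(population, k, multiplier, control_intensities)
    estimate = poisson_concentration(
        result.positive_fraction, population.volume_uL, len(population), confidence
    )
    return estimate, result


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float


def dilution_linearity(
    theoretical: Sequence[float], measured: Sequence[float]
) -> LinearFit:
    """Ordinary least squares of ``log10(measured)`` on ``log10(theoretical)``."""
    x = np.asarray(theoretical, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ParameterError("need at least 3 matched concentration pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ParameterError("concentrations must be positive for a log-log fit")
    fit = stats.linregress(np.log10(x), np.log10(y))
    return LinearFit(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


def lod(replicate_calls: Mapping[float, Sequence[bool]]) -> float | None:
    """Limit of detection: lowest concentration positive in all replicates.

    Returns ``None`` when no concentration is consistently positive.
    """
    if not replicate_calls:
        raise ParameterError("empty replicate-call table")
    consistent = [
        conc
        for conc, calls in replicate_calls.items()
        if len(calls) > 0 and all(bool(c) for c in calls)
    ]
    return min(consistent) if consistent else None


@dataclass(frozen=True)
class SusceptibilityCurve:
    """Droplet survival (%) against antibiotic concentration (ug/mL)."""

    concentrations: tuple[float, ...]
    survival_pct: tuple[float, ...]
    replicates: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.concentrations) == 0:
            raise ParameterError("empty susceptibility curve")
        if len(self.concentrations) != len(self.survival_pct):
            raise ParameterError("concentrations and survival rates must match in length")
        if any(b <= a for a, b in zip(self.concentrations, self.concentrations[1:])):
            raise ParameterError("concentrations must be strictly increasing")
        if any(not 0.0 <= s <= 100.0 for s in self.survival_pct):
            raise ParameterError("survival rates must lie in [0, 100] %")


def mic(curve: SusceptibilityCurve, survival_cutoff_pct: float = 10.0) -> float | None:
    """Minimum inhibitory concentration: lowest tested concentration whose
    droplet survival is at or below the cutoff (default 10%).

    Returns ``None`` when no tested concentration suppresses survival.
    """
    for conc, surv in zip(curve.concentrations, curve.survival_pct):
        if surv <= survival_cutoff_pct:
            return conc
    return None
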