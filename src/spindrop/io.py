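"""Delimited-text ingest and export.

Condition tables use lab-unit header columns
``w_um, h_um, l_mm, rho_kg_m3, mu_mPa_s, gamma_mN_m, theta_deg, omega_rpm,
R1_mm, R2_mm``; observation tables append ``D_um, cv_pct, n_droplets``;
droplet-intensity tables use ``droplet_id, position_index, intensity`` with
an optional ``true_label`` column on synthetic data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import units
from .assay import DropletPopulation
from .exceptions import ParameterError
from .physics import ChannelGeometry, FluidSystem, RotorConfig
from .predictor import DropletObservation, EmulsificationCondition

CONDITION_COLUMNS = [
    "w_um",
    "h_um",
    "l_mm",
    "rho_kg_m3",
    "mu_mPa_s",
    "gamma_mN_m",
    "theta_deg",
    "omega_rpm",
    "R1_mm",
    "R2_mm",
]
OBSERVATION_COLUMNS = CONDITION_COLUMNS + ["D_um", "cv_pct", "n_droplets"]

_FLOAT_FORMAT = "%.17g"


def _condition_from_row(row: pd.Series) -> EmulsificationCondition:
    channel = ChannelGeometry.from_lab(row["w_um"], row["h_um"], row["l_mm"])
    fluids = FluidSystem.from_lab(
        row["rho_kg_m3"], row["mu_mPa_s"], row["gamma_mN_m"], row["theta_deg"]
    )
    rotor = RotorConfig.from_lab(row["omega_rpm"], row["R1_mm"], row["R2_mm"])
    return EmulsificationCondition(channel, fluids, rotor)


def _condition_to_row(condition: EmulsificationCondition) -> dict[str, float]:
    ch, fl, ro = condition.channel, condition.fluids, condition.rotor
    return {
        "w_um": ch.width / units.UM,
        "h_um": ch.height / units.UM,
        "l_mm": ch.length / units.MM,
        "rho_kg_m3": fl.density,
        "mu_mPa_s": fl.viscosity / units.MPA_S,
        "gamma_mN_m": fl.interfacial_tension / units.MN_PER_M,
        "theta_deg": np.degrees(fl.contact_angle),
        "omega_rpm": units.rad_per_s_to_rpm(ro.omega),
        "R1_mm": ro.r1 / units.MM,
        "R2_mm": ro.r2 / units.MM,
    }


def read_conditions(path: str | Path) -> list[EmulsificationCondition]:
    frame = pd.read_csv(path)
    missing = set(CONDITION_COLUMNS) - set(frame.columns)
    if missing:
        raise ParameterError(f"condition table missing columns: {sorted(missing)}")
    return [_condition_from_row(row) for _, row in frame.iterrows()]


def write_conditions(conditions: Sequence[EmulsificationCondition], path: str | Path) -> None:
    frame = pd.DataFrame([_condition_to_row(c) for c in conditions], columns=CONDITION_COLUMNS)
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_observations(path: str | Path) -> list[DropletObservation]:
    frame = pd.read_csv(path)
    missing = set(OBSERVATION_COLUMNS) - set(frame.columns)
    if missing:
        raise ParameterError(f"observation table missing columns: {sorted(missing)}")
    observations = []
    for _, row in frame.iterrows():
        condition = _condition_from_row(row)
        observations.append(
            DropletObservation(
                condition, row["D_um"] * units.UM, row["cv_pct"], int(row["n_droplets"])
            )
        )
    return observations


def write_observations(observations: Sequence[DropletObservation], path: str | Path) -> None:
    rows = []
    for obs in observations:
        row = _condition_to_row(obs.condition)
        row.update(
            D_um=obs.diameter / units.UM, cv_pct=obs.cv_pct, n_droplets=obs.count
        )
        rows.append(row)
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FORMAT
    )


def read_population(path: str | Path, volume_uL: float) -> DropletPopulation:
    frame = pd.read_csv(path)
    required = {"droplet_id", "position_index", "intensity"}
    missing = required - set(frame.columns)
    if missing:
        raise ParameterError(f"population table missing columns: {sorted(missing)}")
    labels = frame["true_label"].to_numpy(bool) if "true_label" in frame.columns else None
    return DropletPopulation(
        frame["intensity"].to_numpy(float),
        frame["position_index"].to_numpy(),
        volume_uL,
        labels,
    )


def write_population(population: DropletPopulation, path: str | Path) -> None:
    data = {
        "droplet_id": np.arange(len(population)),
        "position_index": population.positions,
        "intensity": population.intensities,
    }
    if population.true_labels is not None:
        data["true_label"] = population.true_labels.astype(int)
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FORMAT)
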