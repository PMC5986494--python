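"""From energy-density changes to intake, body-weight and BMI changes.

Each cohort's change in daily energy intake is the consumption-weighted
sum of category energy-density changes:

    delta_kJ/day = sum_c  delta_ED_c [kJ/g] * grams_c/day

assuming unchanged consumption quantities (no demand-side compensation).
A sustained intake change maps to an eventual steady-state body-weight
change through a linear energy-balance coefficient rho (kJ/day per kg),
and weight to BMI through the cohort's mean height:

    delta_kg  = delta_kJ/day / rho
    delta_BMI = delta_kg / height^2

The BMI change is applied downstream as a permanent location shift of the
cohort's lognormal BMI distribution (natural-scale SD preserved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EnergyWeightParams
from .errors import InvalidInputError
from .reformulation import ScenarioEffect


@dataclass(frozen=True)
class CohortChange:
    """Intake, weight and BMI change for one age-group x sex stratum."""

    age_lo: int
    age_hi: int
    sex: str
    delta_kj_per_day: float
    delta_kg: float
    delta_bmi: float


def weighted_intake_change(
    effect: ScenarioEffect, consumption: pd.DataFrame
) -> pd.DataFrame:
    """Per-cohort daily energy-intake change (kJ/day).

    Categories consumed but missing from the effect contribute zero.
    Returns columns ``age_lo, age_hi, sex, delta_kj_per_day``.
    """
    if (consumption["grams_per_day"] < 0).any():
        raise InvalidInputError("grams_per_day must be nonnegative")
    delta = consumption["category"].map(effect.kj_per_g).fillna(0.0)
    contrib = delta * consumption["grams_per_day"]
    out = (
        consumption.assign(_contrib=contrib)
        .groupby(["age_lo", "age_hi", "sex"], as_index=False)["_contrib"]
        .sum()
        .rename(columns={"_contrib": "delta_kj_per_day"})
    )
    return out


def energy_to_weight(
    delta_kj: float, age: float, params: EnergyWeightParams | None = None
) -> float:
    """Steady-state weight change (kg) from a sustained intake change."""
    params = params or EnergyWeightParams()
    if not np.isfinite(delta_kj):
        raise InvalidInputError("delta_kj must be finite")
    return delta_kj / params.rho(age)


def weight_to_bmi(delta_kg: float, height_m: float) -> float:
    """BMI change (kg/m^2) from a weight change at a given height."""
    if not height_m > 0:
        raise InvalidInputError("height must be positive")
    return delta_kg / height_m**2


def cohort_changes(
    effect: ScenarioEffect,
    consumption: pd.DataFrame,
    population: pd.DataFrame,
    params: EnergyWeightParams | None = None,
) -> pd.DataFrame:
    """Full intake -> weight -> BMI chain for every cohort.

    Joins the intake change with the population table's heights; the
    energy-balance coefficient is chosen by the age-group midpoint
    against the adult threshold.  Returns columns ``age_lo, age_hi, sex,
    delta_kj_per_day, delta_kg, delta_bmi``.
    """
    params = params or EnergyWeightParams()
    intake = weighted_intake_change(effect, consumption)
    merged = intake.merge(
        population[["age_lo", "age_hi", "sex", "height_m"]],
        on=["age_lo", "age_hi", "sex"],
        how="inner",
        validate="one_to_one",
    )
    mid = (merged["age_lo"] + merged["age_hi"]) / 2.0
    rho = np.where(mid >= params.adult_age_threshold, params.rho_adult, params.rho_child)
    merged["delta_kg"] = merged["delta_kj_per_day"] / rho
    merged["delta_bmi"] = merged["delta_kg"] / merged["height_m"] ** 2
    return merged.drop(columns="height_m")


def shift_lognormal(mu: float, sigma: float, delta_mean: float) -> tuple[float, float]:
    """Refit lognormal parameters after a location shift of the mean.

    The natural-scale mean moves by ``delta_mean`` while the natural-scale
    standard deviation is preserved; returns the new (mu, sigma).
    """
    mean = np.exp(mu + sigma**2 / 2.0)
    sd = mean * np.sqrt(np.expm1(sigma**2))
    new_mean = mean + delta_mean
    if new_mean <= 0:
        raise InvalidInputError("shift drives mean BMI nonpositive")
    new_sigma2 = np.log1p((sd / new_mean) ** 2)
    new_mu = np.log(new_mean) - new_sigma2 / 2.0
    return float(new_mu), float(np.sqrt(new_sigma2))


def population_mean_intake_change(
    intake: pd.DataFrame, population: pd.DataFrame
) -> float:
    """Population-size-weighted mean of cohort intake changes (kJ/day)."""
    merged = intake.merge(
        population[["age_lo", "age_hi", "sex", "size"]],
        on=["age_lo", "age_hi", "sex"],
        validate="one_to_one",
    )
    return float(
        np.average(merged["delta_kj_per_day"], weights=merged["size"])
    )
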