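"""Intervention costs, cost offsets, net costs and ICERs.

Intervention cost items follow schedules over the model horizon: annual
items recur every year (e.g., government administration and monitoring),
``per_cycle`` items recur every labelling cycle (industry re-labelling,
default 3 years), and ``one_off`` items occur at year 0 (legislation).
All occurrences are discounted to year 0 at the model rate.

Cost offsets are the treatment costs averted through prevented prevalent
case-years, discounted the same way; negative offsets are savings.  The
incremental cost-effectiveness ratio (ICER) is net incremental cost per
incremental HALY, with the usual dominance semantics: cheaper-and-better
interventions are "dominant", costlier-and-worse ones "dominated".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError, InvalidPairingError
from .pmslt import LifeTableRun

SCHEDULES = ("one_off", "per_cycle", "annual")


@dataclass(frozen=True)
class CostItem:
    name: str
    value: float  # 2010 A$ per occurrence
    schedule: str  # one_off | per_cycle | annual

    def __post_init__(self) -> None:
        if self.schedule not in SCHEDULES:
            raise InvalidConfigError(f"unknown schedule {self.schedule!r}")


@dataclass(frozen=True)
class CEOutcome:
    """Point cost-effectiveness outcome for one scenario (2010 A$)."""

    intervention_cost: float
    cost_offsets: float
    net_cost: float
    halys: float
    icer: float | None  # None when labelled dominant/dominated/undefined
    label: str  # "icer" | "dominant" | "dominated" | "undefined"
    cost_effective: bool


def occurrence_years(schedule: str, horizon: int, cycle_years: int) -> np.ndarray:
    """Years (0-based) at which a scheduled item occurs within the horizon."""
    if schedule == "one_off":
        return np.array([0])
    if schedule == "annual":
        return np.arange(horizon)
    if schedule == "per_cycle":
        return np.arange(0, horizon, cycle_years)
    raise InvalidConfigError(f"unknown schedule {schedule!r}")


def aggregate_intervention_costs(
    items: list[CostItem],
    horizon: int,
    discount_rate: float,
    labelling_cycle: int = 3,
) -> float:
    """Discounted total of all cost items over the horizon."""
    if horizon < 1:
        raise InvalidInputError("horizon must be >= 1")
    if labelling_cycle < 1:
        raise InvalidConfigError("labelling cycle must be >= 1")
    total = 0.0
    for item in items:
        years = occurrence_years(item.schedule, horizon, labelling_cycle)
        total += float(np.sum(item.value * (1.0 + discount_rate) ** -years))
    return total


def cost_items_from_table(costs: pd.DataFrame, scenario: str) -> list[CostItem]:
    """Cost items for one scenario from the cost input table."""
    sub = costs[costs["scenario"] == scenario]
    if sub.empty:
        raise InvalidInputError(f"no cost rows for scenario {scenario!r}")
    return [
        CostItem(name=row["item"], value=float(row["value"]), schedule=row["schedule"])
        for _, row in sub.iterrows()
    ]


def compute_cost_offsets(
    comparator: LifeTableRun,
    intervention: LifeTableRun,
    cost_per_case_year: np.ndarray,
) -> float:
    """Discounted averted-treatment-cost total (negative = savings).

    Sums ``cost x (prevalent cases intervention - comparator)`` over
    cohorts, cycles and diseases, discounted at the runs' rate.
    """
    if not comparator.same_cohorts(intervention):
        raise InvalidPairingError("runs do not share the same cohort structure")
    cost = np.asarray(cost_per_case_year, dtype=float)
    if cost.shape != (len(comparator.disease_names),):
        raise InvalidInputError("one cost per disease required")
    d_cases = intervention.prevalent_cases - comparator.prevalent_cases
    n_cyc = d_cases.shape[1]
    disc = (1.0 + comparator.discount_rate) ** -np.arange(n_cyc)
    return float(np.einsum("ctd,t,d->", d_cases, disc, cost))


def net_and_icer(
    intervention_cost: float,
    cost_offsets: float,
    halys: float,
    wtp: float = 50_000.0,
) -> CEOutcome:
    """Net incremental cost and ICER with dominance semantics.

    ``halys == 0`` is reported as an undefined ICER rather than raised.
    """
    for v in (intervention_cost, cost_offsets, halys):
        if not math.isfinite(v):
            raise InvalidInputError("inputs must be finite")
    net = intervention_cost + cost_offsets
    if halys == 0.0:
        return CEOutcome(intervention_cost, cost_offsets, net, halys,
                         icer=None, label="undefined", cost_effective=False)
    if halys > 0 and net < 0:
        return CEOutcome(intervention_cost, cost_offsets, net, halys,
                         icer=None, label="dominant", cost_effective=True)
    if halys < 0 and net > 0:
        return CEOutcome(intervention_cost, cost_offsets, net, halys,
                         icer=None, label="dominated", cost_effective=False)
    icer = net / halys
    return CEOutcome(intervention_cost, cost_offsets, net, halys,
                     icer=icer, label="icer",
                     cost_effective=bool(halys > 0 and icer < wtp))


def iteration_icer(net_cost: float, halys: float) -> float | None:
    """Per-iteration ICER used for Monte Carlo summaries.

    Defined only for iterations with positive incremental HALYs;
    cost-saving (dominant) iterations contribute their negative ratio.
    """
    if halys <= 0:
        return None
    return net_cost / halys
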