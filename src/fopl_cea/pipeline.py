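"""End-to-end orchestration: data -> effects -> anthropometry -> life table
-> costing -> PSA -> report.

A scenario run is a pure function of the five input tables and a
:class:`~fopl_cea.config.RunConfig`; all randomness flows from the
config seed.  The report bundle records the full config alongside the
results so any archived run can be reproduced exactly.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .costing import (
    aggregate_intervention_costs,
    compute_cost_offsets,
    cost_items_from_table,
    net_and_icer,
)
from .errors import ValidationError
from .intake import cohort_changes, population_mean_intake_change
from .pmslt import Model, incremental_halys
from .reformulation import (
    compute_category_effects,
    effects_table,
    estimate_uptake,
    scale_to_mandatory,
    uptake_by_category,
    voluntary_effect,
)
from .uncertainty import PSAInputs, run_psa

TABLE_NAMES = ("products", "consumption", "population", "diseases", "costs")

_REQUIRED_COLUMNS = {
    "products": {"product_id", "category", "ed_y0", "ed_y1", "labelled"},
    "consumption": {"age_lo", "age_hi", "sex", "category", "grams_per_day"},
    "population": {"age_lo", "age_hi", "sex", "size", "bmi_mu", "bmi_sigma",
                   "height_m", "mortality", "yld"},
    "diseases": {"disease", "age_lo", "age_hi", "sex", "incidence",
                 "case_fatality", "remission", "disability_weight",
                 "rr_per_5bmi", "rr_log_se", "cost_per_case_year", "min_age"},
    "costs": {"item", "scenario", "value", "min", "max", "schedule"},
}


def _check_partition(df: pd.DataFrame, table: str, violations: list[str]) -> None:
    for sex, grp in df.groupby("sex"):
        groups = sorted({(int(a), int(b)) for a, b in zip(grp["age_lo"], grp["age_hi"])})
        if not groups:
            continue
        if groups[0][0] != 0 or groups[-1][1] != 100:
            violations.append(f"{table}: age groups for sex={sex} do not cover [0, 100)")
            continue
        for (lo, hi), (lo2, _) in zip(groups, groups[1:]):
            if hi != lo2:
                violations.append(
                    f"{table}: age groups for sex={sex} have a gap/overlap at {hi}"
                )


def validate_inputs(dataset: dict[str, pd.DataFrame]) -> list[str]:
    """Schema, unit and invariant checks for all five tables.

    Returns the full list of violations (empty when valid); each entry
    names the table, the rule and, where applicable, the offending rows.
    """
    violations: list[str] = []
    for name in TABLE_NAMES:
        if name not in dataset:
            violations.append(f"missing table {name!r}")
            continue
        missing = _REQUIRED_COLUMNS[name] - set(dataset[name].columns)
        if missing:
            violations.append(f"{name}: missing column(s) {sorted(missing)}")
    if violations:
        return violations

    def flag(table: str, mask: pd.Series, rule: str) -> None:
        if mask.any():
            rows = list(mask[mask].index[:5])
            violations.append(f"{table}: {rule} (rows {rows})")

    prod = dataset["products"]
    flag("products", prod["ed_y0"] <= 0, "ed_y0 must be positive")
    flag("products", prod["ed_y1"] <= 0, "ed_y1 must be positive")

    cons = dataset["consumption"]
    flag("consumption", cons["grams_per_day"] < 0, "grams_per_day must be >= 0")
    _check_partition(cons.drop_duplicates(["age_lo", "age_hi", "sex"]),
                     "consumption", violations)

    pop = dataset["population"]
    flag("population", pop["size"] < 0, "size must be >= 0")
    flag("population", pop["bmi_sigma"] <= 0, "bmi_sigma must be > 0")
    flag("population", ~pop["height_m"].between(0.5, 2.1), "height_m outside [0.5, 2.1]")
    flag("population", ~((pop["mortality"] > 0) & (pop["mortality"] <= 1)),
         "mortality outside (0, 1]")
    flag("population", ~((pop["yld"] >= 0) & (pop["yld"] < 1)), "yld outside [0, 1)")
    _check_partition(pop, "population", violations)

    dis = dataset["diseases"]
    for col in ("incidence", "case_fatality", "remission"):
        flag("diseases", ~((dis[col] >= 0) & (dis[col] < 1)), f"{col} outside [0, 1)")
    flag("diseases", ~((dis["disability_weight"] >= 0) & (dis["disability_weight"] < 1)),
         "disability_weight outside [0, 1)")
    flag("diseases", dis["rr_per_5bmi"] < 0, "rr_per_5bmi must be >= 0")
    flag("diseases", dis["cost_per_case_year"] <= 0, "cost_per_case_year must be > 0")

    costs = dataset["costs"]
    flag("costs", ~((costs["min"] <= costs["value"]) & (costs["value"] <= costs["max"])),
         "min <= value <= max violated")
    flag("costs", ~costs["schedule"].isin(["one_off", "per_cycle", "annual"]),
         "unknown schedule")
    return violations


def scenario_effect(dataset: dict[str, pd.DataFrame], config: RunConfig):
    """Per-category kJ/g scenario effect implied by the product table."""
    effects = compute_category_effects(
        dataset["products"], list(config.excluded_categories)
    )
    uptake_cat = uptake_by_category(dataset["products"])
    eff = voluntary_effect(effects, uptake_cat, config.attributable_fraction)
    if config.scenario == "mandatory":
        eff = scale_to_mandatory(eff, uptake_cat)
    return effects, uptake_cat, eff


def run_scenario(
    dataset: dict[str, pd.DataFrame],
    config: RunConfig | None = None,
    run_uncertainty: bool = True,
) -> dict:
    """Full deterministic run plus (optionally) the Monte Carlo PSA.

    Returns a bundle dict with the validated config, effect-size tables,
    intake/anthropometry summaries, point cost-effectiveness outcome and
    PSA summaries.
    """
    config = config or RunConfig()
    violations = validate_inputs(dataset)
    if violations:
        raise ValidationError(violations)

    effects, uptake_cat, eff = scenario_effect(dataset, config)
    uptake = estimate_uptake(dataset["products"])

    changes = cohort_changes(
        eff, dataset["consumption"], dataset["population"], config.energy_weight
    )
    pop = dataset["population"]
    mean_kj = population_mean_intake_change(
        changes[["age_lo", "age_hi", "sex", "delta_kj_per_day"]], pop
    )
    sizes = changes.merge(pop[["age_lo", "sex", "size", "height_m"]],
                          on=["age_lo", "sex"], validate="one_to_one")
    mean_kg = float(np.average(sizes["delta_kg"], weights=sizes["size"]))
    mean_bmi = float(np.average(sizes["delta_bmi"], weights=sizes["size"]))

    model = Model.from_tables(pop, dataset["diseases"], config)
    key = {(int(r.age_lo), r.sex): (r.delta_kg, r.delta_bmi)
           for r in changes.itertuples()}
    delta_kg = np.zeros(len(model.cohorts))
    delta_bmi = np.zeros(len(model.cohorts))
    heights = np.zeros(len(model.cohorts))
    pop_idx = pop.set_index(["age_lo", "sex"])
    for j, row in model.cohorts.iterrows():
        k = (int(row["age_lo"]), row["sex"])
        delta_kg[j], delta_bmi[j] = key.get(k, (0.0, 0.0))
        heights[j] = pop_idx.loc[k, "height_m"]

    comp, interv = model.run(delta_bmi)
    halys = incremental_halys(comp, interv)
    offsets = compute_cost_offsets(comp, interv, model.cost_per_case_year)
    items = cost_items_from_table(dataset["costs"], config.scenario)
    cost = aggregate_intervention_costs(
        items, config.horizon_age, config.discount_rate, config.labelling_cycle_years
    )
    point = net_and_icer(cost, offsets, halys, config.wtp)

    bundle = {
        "config": config.to_dict(),
        "versions": {"fopl_cea": __version__, "python": platform.python_version()},
        "uptake": asdict(uptake),
        "effects": effects_table(effects).to_dict(orient="records"),
        "effect_kj_per_g": eff.kj_per_g,
        "intake": {
            "mean_delta_kj_per_day": mean_kj,
            "mean_delta_kg": mean_kg,
            "mean_delta_bmi": mean_bmi,
        },
        "point": asdict(point),
        "cohort_changes": changes.to_dict(orient="records"),
    }

    if run_uncertainty:
        psa_inputs = PSAInputs(
            model=model,
            delta_kg=delta_kg,
            heights=heights,
            mean_delta_kg=mean_kg,
            costs=dataset["costs"],
            scenario=config.scenario,
            config=config,
        )
        result = run_psa(psa_inputs)
        bundle["psa"] = {
            "n": result.n,
            "n_failed": result.n_failed,
            "seed": result.seed,
            "summaries": result.summaries,
            "quadrant_shares": result.quadrant_shares,
        }
        bundle["_psa_result"] = result  # in-memory only; not serialised
    return bundle


def run_sensitivity(
    dataset: dict[str, pd.DataFrame],
    config: RunConfig,
    fractions: list[float],
    run_uncertainty: bool = False,
) -> dict[float, dict]:
    """Rerun the scenario at several attributable fractions."""
    out = {}
    for f in fractions:
        cfg = RunConfig(**{**config.to_dict(), "attributable_fraction": f})
        out[f] = run_scenario(dataset, cfg, run_uncertainty=run_uncertainty)
    return out


def format_report(bundle: dict) -> str:
    """Human-readable summary: money in A$ millions (1 dp), HALYs as
    integers, mirroring the published table layout."""
    cfg = bundle["config"]
    point = bundle["point"]
    lines = [
        f"Scenario: {cfg['scenario']} "
        f"(attributable fraction {cfg['attributable_fraction']:.0%})",
        f"Label uptake: {bundle['uptake']['proportion']:.1%} "
        f"({bundle['uptake']['ci_low']:.1%} to {bundle['uptake']['ci_high']:.1%})",
        f"Mean intake change: {bundle['intake']['mean_delta_kj_per_day']:.2f} kJ/day; "
        f"weight {bundle['intake']['mean_delta_kg']:.3f} kg; "
        f"BMI {bundle['intake']['mean_delta_bmi']:.4f} kg/m^2",
        "",
        f"Intervention costs: A${point['intervention_cost'] / 1e6:.1f} m",
        f"Cost offsets:       A${point['cost_offsets'] / 1e6:.1f} m",
        f"Net costs:          A${point['net_cost'] / 1e6:.1f} m",
        f"Incremental HALYs:  {point['halys']:.0f}",
    ]
    if point["icer"] is not None:
        lines.append(f"ICER:               A${point['icer']:.0f} per HALY")
    else:
        lines.append(f"ICER:               {point['label']}")
    if "psa" in bundle:
        s = bundle["psa"]["summaries"]
        q = bundle["psa"]["quadrant_shares"]
        icer = s["icer"]
        icer_mean = "n/a" if icer["mean"] is None else f"A${icer['mean']:.0f}"
        lines += [
            "",
            f"PSA ({bundle['psa']['n']} iterations, seed {bundle['psa']['seed']}):",
            f"  HALYs:     {s['halys']['mean']:.0f} "
            f"({s['halys']['ui_low']:.0f} to {s['halys']['ui_high']:.0f})",
            f"  Net costs: A${s['net_cost']['mean'] / 1e6:.1f} m "
            f"(A${s['net_cost']['ui_low'] / 1e6:.1f} m to "
            f"A${s['net_cost']['ui_high'] / 1e6:.1f} m)",
            f"  Mean ICER: {icer_mean} per HALY "
            f"({icer['ui_low_label']} to {icer['ui_high']:.0f})"
            if icer["mean"] is not None
            else f"  Mean ICER: {icer_mean}",
            f"  CE plane:  NE {q['NE']:.0%}, SE {q['SE']:.0%}, "
            f"NW {q['NW']:.0%}, SW {q['SW']:.0%}",
        ]
    return "\n".join(lines)


def write_bundle(bundle: dict, outdir: str | Path) -> Path:
    """Serialise the bundle (minus in-memory objects) as JSON + report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    serialisable = {k: v for k, v in bundle.items() if not k.startswith("_")}
    path = outdir / "run_bundle.json"
    with open(path, "w") as fh:
        json.dump(serialisable, fh, indent=2, default=float)
    (outdir / "report.txt").write_text(format_report(bundle) + "\n")
    return path
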