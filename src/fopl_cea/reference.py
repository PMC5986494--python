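"""Published summary values for the Australian Health Star Rating (HSR)
reformulation evaluation.

These are printed, category-level summaries of proprietary data sources
(the FoodSwitch product database, the 2011-2012 Australian Health Survey)
and the government costing report for the HSR scheme.  The underlying
product- and person-level data are not public, so the printed summaries
serve as *inputs*: the arithmetic that turns them into difference-in-
difference effect sizes, uptake intervals and net costs is recomputed by
this package and checked in the test suite.

All monetary values are 2010 Australian dollars.
"""

from __future__ import annotations

import pandas as pd

#: Products present in the database in both 2013 and 2016, and the number
#: that displayed an HSR label in 2016.
UPTAKE_N_LABELLED = 1004
UPTAKE_N_TOTAL = 14986

#: Overall paired change in energy density among labelled products,
#: kJ/100 g (mean, 95% CI, p).
LABELLED_MEAN_CHANGE_KJ100G = -7.11

#: Category-level energy-density comparison, 2013 vs 2016, kJ/100 g.
#: Columns: baseline (2013) mean energy density and absolute 2013->2016
#: change, separately for products with and without the HSR label, plus
#: the published percentage-point change attributable to HSR (DiD at 1 dp).
CATEGORY_TABLE = pd.DataFrame(
    [
        ("Bread and bakery products", 1585, 1588, -3.3, -2.2, -0.1),
        ("Cereal and grain products", 1521, 1370, -7.9, -10.4, 0.2),
        ("Confectionery", 2070, 1720, 19.7, 4.0, 0.7),
        ("Convenience foods", 444, 512, -10.9, -3.2, -1.8),
        ("Dairy", 608, 933, -13.4, -0.9, -2.1),
        ("Edible oils and oil emulsions", 2724, 3066, -18.1, 5.0, -0.8),
        ("Fish and fish products", 721, 693, -1.0, 0.0, -0.1),
        ("Fruit and vegetables", 881, 998, -0.6, 0.6, -0.1),
        ("Meat and meat products", 828, 878, -4.1, 3.9, -0.9),
        ("Non-alcoholic beverages", 213, 197, -4.6, -2.1, -1.1),
        ("Sauces, dressings, spreads and dips", 1046, 816, -64.7, -5.5, -5.5),
        ("Snack foods", 2013, 1883, 65.8, -0.8, 3.3),
        ("Sugars, honey and related products", 1454, 1404, -19.7, 1.6, -1.5),
    ],
    columns=[
        "category",
        "ed_labelled_y0",
        "ed_unlabelled_y0",
        "change_labelled",
        "change_unlabelled",
        "published_pct_attributable",
    ],
)

#: The 13 included food categories, in published order.
CATEGORIES = list(CATEGORY_TABLE["category"])

#: Intervention cost inputs (2010 A$, point and expert min/max) per scenario,
#: with the schedule each item follows over the model horizon.
COST_TABLE = pd.DataFrame(
    [
        ("industry", "voluntary", 2.5e6, 1.2e6, 3.7e6, "per_cycle", "pert"),
        ("government", "voluntary", 1.2e6, 0.6e6, 1.8e6, "annual", "pert"),
        ("industry", "mandatory", 37.0e6, 18.5e6, 55.4e6, "per_cycle", "pert"),
        ("government", "mandatory", 17.8e6, 8.9e6, 26.7e6, "annual", "pert"),
        ("legislation", "mandatory", 1.1e6, 1.0e6, 1.2e6, "one_off", "gamma"),
    ],
    columns=["item", "scenario", "value", "min", "max", "schedule", "distribution"],
)

#: Published lifetime cost-effectiveness components (2010 A$ millions for
#: money, HALYs for health), used for net-cost identity checks.
BASELINE_RESULTS = {
    "voluntary": {
        "intervention_cost_m": 46.1,
        "cost_offsets_m": -41.6,
        "net_cost_m": 4.5,
        "halys": 4207,
        "mean_icer": 1728,
    },
    "mandatory": {
        "intervention_cost_m": 686.4,
        "cost_offsets_m": -488.7,
        "net_cost_m": 197.7,
        "halys": 49949,
        "mean_icer": 4752,
    },
}

#: Published sensitivity analyses on the HSR-attributable fraction
#: (voluntary scenario).  Keys are the attributable fraction.
SENSITIVITY_RESULTS = {
    0.5: {
        "intervention_cost_m": 46.1,
        "cost_offsets_m": -20.9,
        "net_cost_m": 25.3,
        "halys": 2101,
        "mean_icer": 13374,
    },
    0.3: {
        "intervention_cost_m": 46.0,
        "cost_offsets_m": -12.5,
        "net_cost_m": 33.5,
        "halys": 1253,
        "mean_icer": 29006,
    },
    0.1: {
        "intervention_cost_m": 46.0,
        "cost_offsets_m": -4.2,
        "net_cost_m": 41.8,
        "halys": 424,
        "mean_icer": 106368,
    },
}
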