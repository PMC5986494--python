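"""Synthetic input tables with the statistical structure the analysis assumes.

The real evaluation drew on proprietary sources: a national packaged-food
database (product energy densities and label uptake), a national nutrition
survey (grams/day consumed by food category, age and sex), national life
tables and burden-of-disease outputs, and a disease costing study.  None
are redistributable, so this module generates all five input tables with
the features the downstream stages rely on:

* category-specific energy-density baselines spanning roughly 200-3100
  kJ/100 g, with a small extra mean reduction among HSR-labelled products
  on top of a common secular drift;
* label uptake drawn Bernoulli at the observed ~6.7% rate;
* positively skewed (lognormal) population BMI by age and sex;
* nine adult-onset obesity-related diseases with relative risks > 1 per
  5 BMI units.

Every table is a tidy :class:`pandas.DataFrame`, reproducible bit-for-bit
from ``SyntheticConfig.seed``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .config import SEXES, SyntheticConfig

#: Seed of the reference fixture used throughout the test suite.
REFERENCE_SEED = 20100614

_TABLE_STREAMS = {"products": 1, "consumption": 2, "population": 3, "diseases": 4}


def _rng(cfg: SyntheticConfig, table: str) -> np.random.Generator:
    # Independent, deterministic substream per table.
    return np.random.default_rng([cfg.seed, _TABLE_STREAMS[table]])


def category_names(n: int) -> list[str]:
    """The published 13 category names when they fit, else generic slots."""
    if n == len(reference.CATEGORIES):
        return list(reference.CATEGORIES)
    return [f"category_{i + 1:02d}" for i in range(n)]


def generate_products(cfg: SyntheticConfig) -> pd.DataFrame:
    """Product table: category, energy density in both years, label flag.

    Year-1 energy density is year-0 plus a common secular drift plus
    product-level noise; labelled products (Bernoulli ``uptake_target``)
    additionally receive a mean shift of ``labelled_reform_mean`` kJ/100 g.
    """
    rng = _rng(cfg, "products")
    cats = category_names(cfg.n_categories)

    # Category baselines spread across the realistic energy-density range.
    base = np.exp(np.linspace(np.log(220.0), np.log(3000.0), cfg.n_categories))
    base = base * np.exp(rng.normal(0.0, 0.05, cfg.n_categories))

    cat_idx = rng.integers(0, cfg.n_categories, cfg.n_products)
    ed_y0 = base[cat_idx] * np.exp(rng.normal(0.0, 0.30, cfg.n_products))
    labelled = rng.random(cfg.n_products) < cfg.uptake_target
    change = (
        cfg.unlabelled_drift_mean
        + rng.normal(0.0, cfg.product_noise_sd, cfg.n_products)
        + np.where(labelled, cfg.labelled_reform_mean, 0.0)
    )
    ed_y1 = np.maximum(ed_y0 + change, 1.0)  # energy density stays positive
    return pd.DataFrame(
        {
            "product_id": np.arange(cfg.n_products),
            "category": np.array(cats, dtype=object)[cat_idx],
            "ed_y0": ed_y0,
            "ed_y1": ed_y1,
            "labelled": labelled,
        }
    )


def generate_consumption(cfg: SyntheticConfig) -> pd.DataFrame:
    """Grams/day of each food category by age group and sex.

    Daily packaged-food intake ramps from ~350 g in infancy to ~900 g in
    adulthood (males eating ~15% more), split across categories by a
    Dirichlet share vector common to all cohorts.
    """
    rng = _rng(cfg, "consumption")
    cats = category_names(cfg.n_categories)
    shares = rng.dirichlet(np.full(cfg.n_categories, 2.0))

    rows = []
    for lo, hi in cfg.age_groups:
        mid = (lo + hi) / 2.0
        ramp = min(mid / 20.0, 1.0)  # intake grows until ~age 20
        for sex in SEXES:
            total = 900.0 * ramp * (1.15 if sex == "male" else 1.0)
            total = max(total, 350.0 * min(mid / 2.5, 1.0) + 50.0)
            grams = total * shares * np.exp(rng.normal(0.0, 0.10, cfg.n_categories))
            for cat, g in zip(cats, grams):
                rows.append((lo, hi, sex, cat, g))
    return pd.DataFrame(
        rows, columns=["age_lo", "age_hi", "sex", "category", "grams_per_day"]
    )


def _bmi_mean_by_age(mid: float) -> float:
    # Natural-scale mean BMI: childhood ~16-21, rising through adulthood to
    # ~28.5 around age 65, easing slightly at the oldest ages.
    if mid < 18:
        return 15.5 + 0.32 * mid
    if mid < 65:
        return 21.3 + 7.2 * (mid - 18) / 47.0
    return 28.5 - 0.02 * (mid - 65)


def _mortality_by_age(mid: float) -> float:
    # Stylised period mortality: infant bump, childhood minimum, then
    # Gompertz growth; capped below 1.
    if mid < 5:
        return 0.0012
    gompertz = 3.2e-5 * np.exp(0.088 * mid)
    return float(min(0.0002 + gompertz, 0.45))


def generate_population(cfg: SyntheticConfig) -> pd.DataFrame:
    """Population table by age group and sex.

    Carries the 2010 cohort sizes, lognormal BMI parameters (log-scale mu
    and sigma), mean height, and the all-cause mortality and total
    years-lived-with-disability (YLD) rate schedules.
    """
    rng = _rng(cfg, "population")
    rows = []
    for lo, hi in cfg.age_groups:
        mid = (lo + hi) / 2.0
        # Cohort size: ~1.4m per 5-year group, tapering beyond age 65.
        taper = 1.0 if mid < 65 else np.exp(-0.06 * (mid - 65))
        size_group = 1.4e6 * taper
        mort = _mortality_by_age(mid)
        yld = min(0.02 + 0.0028 * mid, 0.35)
        for sex in SEXES:
            mean_bmi = _bmi_mean_by_age(mid) * np.exp(rng.normal(0.0, 0.01))
            cv = 0.17
            sigma = float(np.sqrt(np.log1p(cv**2)))
            mu = float(np.log(mean_bmi) - sigma**2 / 2.0)
            adult_height = 1.76 if sex == "male" else 1.63
            height = 0.55 + (adult_height - 0.55) * min(mid / 18.0, 1.0)
            m = mort * (1.12 if sex == "male" else 0.9)
            rows.append(
                (
                    lo,
                    hi,
                    sex,
                    size_group / 2.0,
                    mu,
                    sigma,
                    height,
                    float(np.clip(m, 1e-5, 0.6)),
                    float(np.clip(yld, 0.0, 0.95)),
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "age_lo",
            "age_hi",
            "sex",
            "size",
            "bmi_mu",
            "bmi_sigma",
            "height_m",
            "mortality",
            "yld",
        ],
    )
    # Enforce mortality monotone in age beyond the floor age.
    for sex in SEXES:
        mask = (df["sex"] == sex) & (df["age_lo"] >= cfg.mortality_floor_age)
        sub = df.loc[mask].sort_values("age_lo")
        df.loc[sub.index, "mortality"] = np.maximum.accumulate(sub["mortality"])
    return df


def generate_diseases(cfg: SyntheticConfig) -> pd.DataFrame:
    """Disease table: epidemiology by age group and sex for each disease.

    Each of ``n_diseases`` anonymous adult-onset conditions gets an
    age-increasing incidence and case fatality, zero remission, a
    disability weight, a relative risk per 5 BMI units above 1 with a
    log-scale standard error, and an annual treatment cost per prevalent
    case.
    """
    rng = _rng(cfg, "diseases")
    rows = []
    for d in range(cfg.n_diseases):
        name = f"disease_{d + 1:02d}"
        base_inc = rng.uniform(2e-4, 1.2e-3)
        inc_slope = rng.uniform(0.03, 0.06)  # log-linear rise with age
        base_cf = rng.uniform(0.004, 0.02)
        cf_slope = rng.uniform(0.02, 0.045)
        dw = rng.uniform(0.05, 0.35)
        rr = rng.uniform(1.10, 1.65)
        # Log-scale SE from a synthetic 95% CI of +/-8-18% around the RR.
        half_width = rng.uniform(0.08, 0.18)
        rr_log_se = (np.log1p(half_width) - np.log1p(-half_width)) / 3.92
        cost = rng.uniform(1500.0, 12000.0)
        for lo, hi in cfg.age_groups:
            mid = (lo + hi) / 2.0
            adult = mid >= cfg.adult_min_age
            inc = base_inc * np.exp(inc_slope * (mid - cfg.adult_min_age)) if adult else 0.0
            cf = base_cf * np.exp(cf_slope * (mid - cfg.adult_min_age)) if adult else 0.0
            for sex in SEXES:
                sex_f = 1.1 if sex == "male" else 0.95
                rows.append(
                    (
                        name,
                        lo,
                        hi,
                        sex,
                        float(np.clip(inc * sex_f, 0.0, 0.08)),
                        float(np.clip(cf * sex_f, 0.0, 0.30)),
                        0.0,  # remission: no data source, default 0
                        dw,
                        rr,
                        float(rr_log_se),
                        cost,
                        cfg.adult_min_age,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "disease",
            "age_lo",
            "age_hi",
            "sex",
            "incidence",
            "case_fatality",
            "remission",
            "disability_weight",
            "rr_per_5bmi",
            "rr_log_se",
            "cost_per_case_year",
            "min_age",
        ],
    )


def generate_costs(cfg: SyntheticConfig) -> pd.DataFrame:
    """Intervention cost table (published point values with expert ranges)."""
    return reference.COST_TABLE.copy()


def generate_dataset(cfg: SyntheticConfig | None = None) -> dict[str, pd.DataFrame]:
    """All five input tables keyed by name."""
    cfg = cfg or SyntheticConfig()
    return {
        "products": generate_products(cfg),
        "consumption": generate_consumption(cfg),
        "population": generate_population(cfg),
        "diseases": generate_diseases(cfg),
        "costs": generate_costs(cfg),
    }


def write_dataset(dataset: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write each table as ``<name>.csv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in dataset.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
    return paths


def read_dataset(indir: str | Path) -> dict[str, pd.DataFrame]:
    """Read the five CSVs written by :func:`write_dataset`."""
    indir = Path(indir)
    return {
        name: pd.read_csv(indir / f"{name}.csv")
        for name in ("products", "consumption", "population", "diseases", "costs")
    }
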