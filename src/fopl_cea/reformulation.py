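"""Label-attributable reformulation effect sizes.

The intervention effect is measured as a difference-in-difference (DiD) in
product energy density: the percentage change among products that carried
the front-of-pack label minus the percentage change among products that
did not, per food category.  The module also estimates label uptake with a
binomial confidence interval, tests the labelled-arm change with a paired
t-test, and rescales voluntary-scheme effects to a mandatory (100% uptake)
scenario by cross-multiplication:

    delta_ED(mandatory) = delta_ED(voluntary) * 100% / uptake%

per category.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    InvalidInputError,
    UndefinedScalingError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CategoryEffect:
    """Per-category arm means and the DiD in percentage points.

    Percentage changes are relative to each arm's own year-0 baseline, so
    the DiD (``pct_attributable``) is in percentage points.  When an arm
    is empty its fields are NaN and ``pct_attributable`` is undefined.
    """

    category: str
    mean_ed_labelled_y0: float
    mean_ed_unlabelled_y0: float
    mean_ed_labelled_y1: float
    mean_ed_unlabelled_y1: float

    @property
    def abs_change_labelled(self) -> float:
        return self.mean_ed_labelled_y1 - self.mean_ed_labelled_y0

    @property
    def abs_change_unlabelled(self) -> float:
        return self.mean_ed_unlabelled_y1 - self.mean_ed_unlabelled_y0

    @property
    def pct_change_labelled(self) -> float:
        return 100.0 * self.abs_change_labelled / self.mean_ed_labelled_y0

    @property
    def pct_change_unlabelled(self) -> float:
        return 100.0 * self.abs_change_unlabelled / self.mean_ed_unlabelled_y0

    @property
    def pct_attributable(self) -> float:
        return self.pct_change_labelled - self.pct_change_unlabelled

    @property
    def abs_attributable(self) -> float:
        """Absolute DiD in kJ/100 g (labelled minus unlabelled change)."""
        return self.abs_change_labelled - self.abs_change_unlabelled

    @property
    def complete(self) -> bool:
        return not (
            math.isnan(self.mean_ed_labelled_y0)
            or math.isnan(self.mean_ed_unlabelled_y0)
        )


@dataclass(frozen=True)
class UptakeEstimate:
    n_labelled: int
    n_total: int
    proportion: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PairedTestResult:
    mean_diff: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ScenarioEffect:
    """Per-category energy-density change applied to consumption.

    ``kj_per_g`` maps category -> change in kJ per gram of food consumed
    (kJ/100 g divided by 100), already multiplied by the attributable
    fraction sensitivity lever.
    """

    scenario: str
    attributable_fraction: float
    kj_per_g: dict[str, float]


def category_effect_from_means(
    category: str,
    ed_labelled_y0: float,
    ed_unlabelled_y0: float,
    change_labelled: float,
    change_unlabelled: float,
) -> CategoryEffect:
    """Build a :class:`CategoryEffect` from baselines and absolute changes,
    the form in which published category summaries are reported."""
    return CategoryEffect(
        category=category,
        mean_ed_labelled_y0=ed_labelled_y0,
        mean_ed_unlabelled_y0=ed_unlabelled_y0,
        mean_ed_labelled_y1=ed_labelled_y0 + change_labelled,
        mean_ed_unlabelled_y1=ed_unlabelled_y0 + change_unlabelled,
    )


def compute_category_effects(
    products: pd.DataFrame, exclusions: list[str] | None = None
) -> list[CategoryEffect]:
    """Per-category DiD from a product table.

    Arms are defined by the year-1 label flag (products that carried the
    label post-implementation); means are unweighted product means.
    Categories in ``exclusions`` are removed before analysis.  A category
    with an empty arm yields NaN means for that arm and is flagged
    incomplete (downstream weighting skips it with a warning).
    """
    exclusions = set(exclusions or ())
    df = products[~products["category"].isin(exclusions)]
    if df.empty:
        raise InvalidInputError("no products left after exclusions")
    effects = []
    for cat, grp in df.groupby("category", sort=True):
        lab = grp[grp["labelled"].astype(bool)]
        unlab = grp[~grp["labelled"].astype(bool)]
        eff = CategoryEffect(
            category=str(cat),
            mean_ed_labelled_y0=float(lab["ed_y0"].mean()) if len(lab) else math.nan,
            mean_ed_unlabelled_y0=float(unlab["ed_y0"].mean()) if len(unlab) else math.nan,
            mean_ed_labelled_y1=float(lab["ed_y1"].mean()) if len(lab) else math.nan,
            mean_ed_unlabelled_y1=float(unlab["ed_y1"].mean()) if len(unlab) else math.nan,
        )
        if not eff.complete:
            logger.warning(
                "category %r has an empty arm; DiD undefined, excluded from weighting",
                cat,
            )
        effects.append(eff)
    return effects


def estimate_uptake(products: pd.DataFrame | None = None,
                    n_labelled: int | None = None,
                    n_total: int | None = None) -> UptakeEstimate:
    """Label-uptake proportion with a 95% Wald binomial interval.

    Accepts either a product table or explicit counts.
    """
    if products is not None:
        n_total = int(len(products))
        n_labelled = int(products["labelled"].astype(bool).sum())
    if not n_total:
        raise InvalidInputError("n_total must be positive")
    p = n_labelled / n_total
    half = 1.959963984540054 * math.sqrt(p * (1.0 - p) / n_total)
    return UptakeEstimate(
        n_labelled=n_labelled,
        n_total=n_total,
        proportion=p,
        ci_low=max(0.0, p - half),
        ci_high=min(1.0, p + half),
    )


def uptake_by_category(products: pd.DataFrame) -> dict[str, float]:
    """Labelled fraction per category."""
    return (
        products.assign(labelled=products["labelled"].astype(bool))
        .groupby("category")["labelled"]
        .mean()
        .to_dict()
    )


def paired_energy_test(y0, y1) -> PairedTestResult:
    """Two-sided paired t-test on matched energy densities (y1 - y0)."""
    y0 = np.asarray(y0, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    if y0.shape != y1.shape:
        raise InvalidInputError("y0 and y1 must have equal length")
    n = y0.size
    if n < 2:
        raise InvalidInputError("need at least 2 matched pairs")
    d = y1 - y0
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateVarianceError("paired differences have zero variance")
    mean = float(d.mean())
    se = sd / math.sqrt(n)
    t = mean / se
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(0.975, df))
    return PairedTestResult(
        mean_diff=mean,
        ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se,
        t_stat=float(t),
        df=df,
        p_value=p,
    )


def voluntary_effect(
    effects: list[CategoryEffect],
    uptake: dict[str, float],
    attributable_fraction: float = 1.0,
) -> ScenarioEffect:
    """Voluntary-scheme per-category energy-density change in kJ/g.

    Under the voluntary scheme only the labelled share of each category
    reformulated, so the change in the category's average energy density
    attributable to the label is the absolute DiD diluted by the
    category's labelled share, converted from kJ/100 g to kJ/g.
    Incomplete categories contribute zero change (logged).
    """
    if not 0.0 <= attributable_fraction <= 1.0:
        raise InvalidInputError("attributable_fraction must be in [0, 1]")
    kj_per_g = {}
    for eff in effects:
        if not eff.complete:
            logger.warning("category %r incomplete; treated as zero change", eff.category)
            kj_per_g[eff.category] = 0.0
            continue
        share = uptake.get(eff.category, 0.0)
        kj_per_g[eff.category] = (
            eff.abs_attributable * share / 100.0 * attributable_fraction
        )
    return ScenarioEffect(
        scenario="voluntary",
        attributable_fraction=attributable_fraction,
        kj_per_g=kj_per_g,
    )


def scale_to_mandatory(
    effect: ScenarioEffect, uptake: dict[str, float]
) -> ScenarioEffect:
    """Cross-multiply each category's voluntary change to 100% uptake."""
    scaled = {}
    for cat, delta in effect.kj_per_g.items():
        u = uptake.get(cat, 0.0)
        if u <= 0.0:
            if delta != 0.0:
                raise UndefinedScalingError(
                    f"category {cat!r} has zero uptake but nonzero change"
                )
            scaled[cat] = 0.0
        else:
            if not u <= 1.0:
                raise InvalidInputError("uptake must be in (0, 1]")
            scaled[cat] = delta / u
    return replace(effect, scenario="mandatory", kj_per_g=scaled)


def apply_attributable_fraction(
    effect: ScenarioEffect, fraction: float
) -> ScenarioEffect:
    """Scale every category change by the attributable-fraction lever."""
    if not 0.0 <= fraction <= 1.0:
        raise InvalidInputError("fraction must be in [0, 1]")
    return replace(
        effect,
        attributable_fraction=effect.attributable_fraction * fraction,
        kj_per_g={c: v * fraction for c, v in effect.kj_per_g.items()},
    )


def effects_table(effects: list[CategoryEffect]) -> pd.DataFrame:
    """Tidy summary of category effects (percentages at full precision)."""
    rows = [
        {
            "category": e.category,
            "mean_ed_labelled_y0": e.mean_ed_labelled_y0,
            "mean_ed_unlabelled_y0": e.mean_ed_unlabelled_y0,
            "abs_change_labelled": e.abs_change_labelled,
            "abs_change_unlabelled": e.abs_change_unlabelled,
            "pct_change_labelled": e.pct_change_labelled,
            "pct_change_unlabelled": e.pct_change_unlabelled,
            "pct_attributable": e.pct_attributable,
        }
        for e in effects
    ]
    return pd.DataFrame(rows)
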