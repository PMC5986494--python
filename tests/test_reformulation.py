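"""Difference-in-difference arithmetic, uptake intervals, the paired
t-test, and scenario scaling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fopl_cea import reference
from fopl_cea.errors import (
    DegenerateVarianceError,
    InvalidInputError,
    UndefinedScalingError,
)
from fopl_cea.reformulation import (
    ScenarioEffect,
    apply_attributable_fraction,
    category_effect_from_means,
    compute_category_effects,
    estimate_uptake,
    paired_energy_test,
    scale_to_mandatory,
    uptake_by_category,
    voluntary_effect,
)


@pytest.mark.parametrize(
    "row", reference.CATEGORY_TABLE.to_dict(orient="records"),
    ids=reference.CATEGORIES,
)
def test_published_attributable_percentages_reproduce(row):
    """Every published category DiD cell is recovered at 1 dp from the
    published baselines and absolute changes."""
    eff = category_effect_from_means(
        row["category"],
        row["ed_labelled_y0"],
        row["ed_unlabelled_y0"],
        row["change_labelled"],
        row["change_unlabelled"],
    )
    assert round(eff.pct_attributable, 1) == pytest.approx(
        row["published_pct_attributable"]
    )


def test_dairy_and_convenience_examples():
    dairy = category_effect_from_means("Dairy", 608, 933, -13.4, -0.9)
    assert round(dairy.pct_change_labelled, 1) == -2.2
    assert round(dairy.pct_change_unlabelled, 1) == -0.1
    assert round(dairy.pct_attributable, 1) == -2.1
    conv = category_effect_from_means("Convenience foods", 444, 512, -10.9, -3.2)
    assert round(conv.pct_attributable, 1) == -1.8


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    base_l=st.floats(100, 3000),
    base_u=st.floats(100, 3000),
    chg_l=st.floats(-80, 80),
    chg_u=st.floats(-80, 80),
    shift=st.floats(-50, 500),
)
def test_did_invariant_to_common_additive_shift(base_l, base_u, chg_l, chg_u, shift):
    """Adding a constant to all four arm means leaves the absolute DiD
    unchanged (it is a pure difference of differences)."""
    a = category_effect_from_means("c", base_l, base_u, chg_l, chg_u)
    b = category_effect_from_means("c", base_l + shift, base_u + shift, chg_l, chg_u)
    assert a.abs_attributable == pytest.approx(b.abs_attributable, abs=1e-9)


def test_equal_percentage_change_gives_null_did():
    eff = category_effect_from_means("c", 500, 1000, -10.0, -20.0)  # both -2%
    assert eff.pct_attributable == pytest.approx(0.0, abs=1e-12)


def _products(rows):
    return pd.DataFrame(rows, columns=["product_id", "category", "ed_y0", "ed_y1", "labelled"])


def test_compute_category_effects_means_and_arms():
    prod = _products(
        [
            (0, "a", 100.0, 90.0, True),
            (1, "a", 300.0, 310.0, True),
            (2, "a", 200.0, 200.0, False),
            (3, "b", 400.0, 390.0, False),
        ]
    )
    effects = {e.category: e for e in compute_category_effects(prod)}
    assert effects["a"].mean_ed_labelled_y0 == 200.0
    assert effects["a"].abs_change_labelled == pytest.approx(0.0)
    assert effects["a"].abs_change_unlabelled == pytest.approx(0.0)
    assert not effects["b"].complete  # no labelled arm
    assert math.isnan(effects["b"].pct_attributable)


def test_exclusions_removed_before_analysis():
    prod = _products(
        [(0, "keep", 100, 90, True), (1, "keep", 100, 99, False),
         (2, "drop", 100, 50, True), (3, "drop", 100, 98, False)]
    )
    effects = compute_category_effects(prod, exclusions=["drop"])
    assert [e.category for e in effects] == ["keep"]


def test_incomplete_category_contributes_zero_effect():
    prod = _products(
        [(0, "a", 100, 90, True), (1, "a", 100, 99, False), (2, "b", 100, 80, False)]
    )
    effects = compute_category_effects(prod)
    eff = voluntary_effect(effects, uptake_by_category(prod))
    assert eff.kj_per_g["b"] == 0.0


def test_uptake_published_counts():
    u = estimate_uptake(n_labelled=1004, n_total=14986)
    assert round(100 * u.proportion, 1) == 6.7
    assert round(100 * u.ci_low, 1) == 6.3
    assert round(100 * u.ci_high, 1) == 7.1


def test_uptake_wald_formula_half():
    u = estimate_uptake(n_labelled=50, n_total=100)
    assert u.proportion == 0.5
    assert round(100 * u.ci_low, 1) == 40.2
    assert round(100 * u.ci_high, 1) == 59.8


def test_uptake_degenerate_zero():
    u = estimate_uptake(n_labelled=0, n_total=500)
    assert (u.proportion, u.ci_low, u.ci_high) == (0.0, 0.0, 0.0)


def test_uptake_empty_rejected():
    with pytest.raises(InvalidInputError):
        estimate_uptake(n_labelled=0, n_total=0)


def test_paired_t_textbook_example():
    res = paired_energy_test([1, 2, 3], [2, 4, 3])
    assert res.mean_diff == pytest.approx(1.0)
    assert res.t_stat == pytest.approx(math.sqrt(3), rel=1e-9)
    assert res.df == 2
    assert res.p_value == pytest.approx(0.2254, abs=2e-4)
    assert res.ci_low <= res.mean_diff <= res.ci_high


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 50))
def test_paired_t_matches_independent_implementation(seed, n):
    """Cross-check against scipy's paired test and the explicit formula."""
    rng = np.random.default_rng(seed)
    y0 = rng.normal(1000, 100, n)
    y1 = y0 + rng.normal(-5, 20, n)
    if np.std(y1 - y0, ddof=1) == 0:
        return
    res = paired_energy_test(y0, y1)
    t_ref, p_ref = stats.ttest_rel(y1, y0)
    assert res.t_stat == pytest.approx(float(t_ref), abs=1e-10)
    assert res.p_value == pytest.approx(float(p_ref), abs=1e-10)
    d = y1 - y0
    assert res.t_stat == pytest.approx(
        d.mean() / (d.std(ddof=1) / math.sqrt(n)), abs=1e-10
    )


def test_paired_t_degenerate_variance():
    with pytest.raises(DegenerateVarianceError):
        paired_energy_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])  # constant shift
    with pytest.raises(DegenerateVarianceError):
        paired_energy_test([1.0, 2.0], [1.0, 2.0])  # identical


def test_paired_t_input_contracts():
    with pytest.raises(InvalidInputError):
        paired_energy_test([1.0], [2.0])
    with pytest.raises(InvalidInputError):
        paired_energy_test([1.0, 2.0], [1.0, 2.0, 3.0])


def test_scale_to_mandatory_cross_multiplication():
    eff = ScenarioEffect("voluntary", 1.0, {"a": -0.02})
    scaled = scale_to_mandatory(eff, {"a": 0.10})
    assert scaled.scenario == "mandatory"
    assert scaled.kj_per_g["a"] == pytest.approx(-0.20)


def test_scale_roundtrip_and_identity():
    eff = ScenarioEffect("voluntary", 1.0, {"a": -0.02, "b": 0.005})
    uptake = {"a": 0.067, "b": 0.25}
    scaled = scale_to_mandatory(eff, uptake)
    back = {c: scaled.kj_per_g[c] * uptake[c] for c in uptake}
    assert back == pytest.approx(eff.kj_per_g)
    same = scale_to_mandatory(ScenarioEffect("voluntary", 1.0, {"a": -0.02}), {"a": 1.0})
    assert same.kj_per_g["a"] == -0.02


def test_scale_zero_uptake_rules():
    zero = scale_to_mandatory(ScenarioEffect("voluntary", 1.0, {"a": 0.0}), {"a": 0.0})
    assert zero.kj_per_g["a"] == 0.0
    with pytest.raises(UndefinedScalingError):
        scale_to_mandatory(ScenarioEffect("voluntary", 1.0, {"a": -0.1}), {"a": 0.0})


def test_attributable_fraction_scaling():
    eff = ScenarioEffect("voluntary", 1.0, {"a": -0.10, "b": 0.02})
    assert apply_attributable_fraction(eff, 1.0).kj_per_g == eff.kj_per_g
    assert all(v == 0 for v in apply_attributable_fraction(eff, 0.0).kj_per_g.values())
    assert apply_attributable_fraction(eff, 0.3).kj_per_g["a"] == pytest.approx(-0.03)
    with pytest.raises(InvalidInputError):
        apply_attributable_fraction(eff, 1.2)


def test_fixture_uptake_near_target(dataset):
    u = estimate_uptake(dataset["products"])
    assert u.ci_low <= u.proportion <= u.ci_high
    assert abs(u.proportion - 0.067) < 0.005
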