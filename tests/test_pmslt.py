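"""Potential impact fraction, disease sub-model, and life-table engine."""

import numpy as np
import pandas as pd
import pytest

from fopl_cea.config import RunConfig
from fopl_cea.errors import (
    InvalidInputError,
    InvalidPairingError,
    RateOverflowError,
)
from fopl_cea.pmslt import (
    DiseaseState,
    Model,
    compute_pif,
    disease_model_step,
    incremental_halys,
    run_life_table,
)


def single_cohort_population(mortality=0.01, yld=0.0, mu=np.log(27.0), sigma=0.16):
    """One cohort starting at age 0 whose rates are constant to age 100."""
    return pd.DataFrame(
        [
            {
                "age_lo": 0,
                "age_hi": 100,
                "sex": "female",
                "size": 1.0,
                "bmi_mu": mu,
                "bmi_sigma": sigma,
                "height_m": 1.65,
                "mortality": mortality,
                "yld": yld,
            }
        ]
    )


NO_DISEASES = pd.DataFrame(
    columns=[
        "disease", "age_lo", "age_hi", "sex", "incidence", "case_fatality",
        "remission", "disability_weight", "rr_per_5bmi", "rr_log_se",
        "cost_per_case_year", "min_age",
    ]
)


# ---------------------------------------------------------------- PIF


def test_pif_zero_shift_is_zero():
    assert compute_pif(np.log(27), 0.15, 0.0, 1.3) == 0.0


def test_pif_point_mass_closed_form():
    # Nearly degenerate distribution at BMI 30: RR drops from 2^1 to 2^0
    # under a 5-unit reduction, so PIF -> 1 - 1/2 = 0.5.
    pif = compute_pif(np.log(30.0), 1e-6, 5.0, 2.0, ref_bmi=25.0)
    assert pif == pytest.approx(0.5, abs=1e-4)


def test_pif_matches_monte_carlo_oracle():
    """Grid integration agrees with simulation from the same lognormal."""
    mu, sigma, rr, ref, delta = np.log(27.0), 0.15, 1.3, 21.0, 0.5
    pif = compute_pif(mu, sigma, delta, rr, ref_bmi=ref)
    rng = np.random.default_rng(123)
    log_rr = np.log(rr) / 5.0
    batches = []
    for _ in range(10):
        b = rng.lognormal(mu, sigma, 100_000)
        num = np.exp(log_rr * np.maximum(b - delta - ref, 0.0)).mean()
        den = np.exp(log_rr * np.maximum(b - ref, 0.0)).mean()
        batches.append(1.0 - num / den)
    batches = np.array(batches)
    se = batches.std(ddof=1) / np.sqrt(len(batches))
    assert abs(pif - batches.mean()) < 3 * se


def test_pif_sign_follows_shift_direction():
    down = compute_pif(np.log(27), 0.15, 0.5, 1.3)
    up = compute_pif(np.log(27), 0.15, -0.5, 1.3)
    assert 0 < down < 1
    assert up < 0


def test_pif_input_contracts():
    with pytest.raises(InvalidInputError):
        compute_pif(np.log(27), 0.0, 0.5, 1.3)
    with pytest.raises(InvalidInputError):
        compute_pif(np.log(27), 0.15, 0.5, 0.0)


# ------------------------------------------------- disease sub-model


def test_disease_step_null_rates_are_absorbing():
    s = disease_model_step(DiseaseState(1000.0, 50.0, 5.0), 0.0, 0.0, 0.0)
    assert (s.healthy, s.cases, s.dead) == (1000.0, 50.0, 5.0)


def test_disease_step_one_step_arithmetic():
    s = disease_model_step(DiseaseState(1000.0, 0.0, 0.0), 0.1, 0.0, 0.0)
    assert s.healthy == pytest.approx(900.0)
    assert s.cases == pytest.approx(100.0)
    assert s.dead == 0.0


def test_disease_step_conserves_persons_over_50_random_steps():
    rng = np.random.default_rng(42)
    s = DiseaseState(900.0, 90.0, 10.0)
    total = 1000.0
    for _ in range(50):
        i, f, r = rng.uniform(0, 0.3, 3)
        s = disease_model_step(s, i, f, r)
        assert s.healthy + s.cases + s.dead == pytest.approx(total, abs=1e-9)
        assert min(s.healthy, s.cases, s.dead) >= 0


def test_disease_step_rejects_invalid_rates():
    with pytest.raises(InvalidInputError):
        disease_model_step(DiseaseState(1.0, 0.0, 0.0), 1.0, 0.0, 0.0)
    with pytest.raises(RateOverflowError):
        disease_model_step(DiseaseState(0.0, 1.0, 0.0), 0.0, 0.6, 0.6)


# ------------------------------------------------------- life table


def test_null_intervention_arms_identical(dataset):
    comp, interv = run_life_table(
        dataset["population"], dataset["diseases"], None, RunConfig()
    )
    assert np.array_equal(comp.survivors, interv.survivors)
    assert np.array_equal(comp.halys, interv.halys)
    assert np.array_equal(comp.prevalent_cases, interv.prevalent_cases)
    assert incremental_halys(comp, interv) == 0.0


def test_discounted_person_years_match_geometric_closed_form():
    m, r = 0.01, 0.03
    cfg = RunConfig(discount_rate=r)
    comp, _ = run_life_table(single_cohort_population(mortality=m), NO_DISEASES, None, cfg)
    expected = sum(((1 - m) / (1 + r)) ** t for t in range(100))
    assert comp.halys.sum() == pytest.approx(expected, abs=1e-12)
    assert comp.person_years.sum() == pytest.approx(
        sum((1 - m) ** t for t in range(100)), abs=1e-12
    )


def test_one_cycle_undiscounted_haly_identity():
    cfg = RunConfig(discount_rate=0.0, horizon_age=1)
    pop = single_cohort_population(mortality=0.02, yld=0.1)
    pop["size"] = 1234.0
    comp, _ = run_life_table(pop, NO_DISEASES, None, cfg)
    assert comp.halys.sum() == 1234.0 * (1 - 0.1)


def test_survivors_nonincreasing_and_halys_bounded(dataset):
    comp, _ = run_life_table(dataset["population"], dataset["diseases"], None, RunConfig())
    n_cyc = comp.survivors.shape[1]
    for c in range(comp.survivors.shape[0]):
        active = comp.person_years[c] > 0
        surv = comp.survivors[c, active]
        assert (np.diff(surv) <= 1e-9).all()
    assert (comp.halys <= comp.person_years + 1e-9).all()


def test_comparator_bit_identical_across_runs(dataset):
    a, _ = run_life_table(dataset["population"], dataset["diseases"], None, RunConfig())
    b, _ = run_life_table(dataset["population"], dataset["diseases"], None, RunConfig())
    assert np.array_equal(a.halys, b.halys)
    assert np.array_equal(a.prevalent_cases, b.prevalent_cases)


def _delta_frame(population, delta):
    return pd.DataFrame(
        {
            "age_lo": population["age_lo"],
            "sex": population["sex"],
            "delta_bmi": delta,
        }
    )


def test_bmi_reduction_yields_nonnegative_halys_and_lower_prevalence(dataset):
    pop, dis = dataset["population"], dataset["diseases"]
    delta = _delta_frame(pop, -0.05)
    comp, interv = run_life_table(pop, dis, delta, RunConfig())
    gain = incremental_halys(comp, interv)
    assert gain >= 0
    # per-capita disease prevalence falls in every cohort-cycle (absolute
    # case counts need not: the intervention arm keeps more people alive)
    alive = comp.survivors > 0
    rate_c = comp.prevalent_cases[alive] / comp.survivors[alive, None]
    rate_i = interv.prevalent_cases[alive] / interv.survivors[alive, None]
    assert (rate_i <= rate_c + 1e-12).all()
    assert rate_i.sum() < rate_c.sum()
    assert (interv.survivors >= comp.survivors - 1e-9).all()


def test_harmful_shift_reverses_sign(dataset):
    pop, dis = dataset["population"], dataset["diseases"]
    comp, interv = run_life_table(pop, dis, _delta_frame(pop, +0.05), RunConfig())
    assert incremental_halys(comp, interv) < 0


def test_effect_scales_nearly_linearly(dataset):
    pop, dis = dataset["population"], dataset["diseases"]
    c1, i1 = run_life_table(pop, dis, _delta_frame(pop, -0.02), RunConfig())
    c2, i2 = run_life_table(pop, dis, _delta_frame(pop, -0.04), RunConfig())
    ratio = incremental_halys(c1, i1) / incremental_halys(c2, i2)
    assert 0.45 <= ratio <= 0.55


def test_incremental_halys_rejects_mismatched_runs(dataset):
    pop = dataset["population"]
    comp, _ = run_life_table(pop, dataset["diseases"], None, RunConfig())
    other, _ = run_life_table(
        single_cohort_population(), NO_DISEASES, None, RunConfig()
    )
    with pytest.raises(InvalidPairingError):
        incremental_halys(comp, other)


def test_model_rejects_wrong_delta_length(dataset):
    model = Model.from_tables(dataset["population"], dataset["diseases"], RunConfig())
    with pytest.raises(InvalidInputError):
        model.run(np.zeros(3))
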