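"""Proportional multi-state life table (PMSLT) engine.

The model follows each 2010 age-by-sex cohort annually until age 100 or
extinction, in two arms sharing identical background rates:

* a comparator ("do nothing") arm, where the cohort's lognormal BMI
  distribution and all disease rates are unchanged; and
* an intervention arm, where each obesity-related disease's incidence is
  multiplied by ``1 - PIF``, the potential impact fraction implied by the
  cohort's permanent BMI shift.

Each disease runs as an independent three-state sub-model (healthy,
prevalent case, dead-of-disease) with annual difference equations.  The
proportional step feeds sub-model differences back into the main life
table: the intervention arm's all-cause mortality is the background rate
plus the summed change in disease-specific mortality (case fatality x
prevalence), and its morbidity is the background years-lived-with-
disability (YLD) rate plus the disability-weighted change in prevalence.

Person-years use start-of-cycle survivorship (no half-cycle correction);
health-adjusted life years (HALYs) weight person-years by ``1 - YLD`` and
are discounted to cycle 0 at the configured annual rate.

The potential impact fraction for a continuous exposure is

    PIF = 1 - E[RR(B - d)] / E[RR(B)],

with ``B`` lognormal, ``RR(b) = rr^((b - ref)/5)`` above the reference
BMI and 1 at or below it, and ``d > 0`` denoting a BMI *reduction*.  The
expectation is taken by fixed-grid integration over the central 99.99%
of the lognormal mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .errors import (
    InvalidInputError,
    InvalidPairingError,
    ModelConsistencyError,
    RateOverflowError,
)

_PIF_GRID_POINTS = 2001
_PIF_TAIL_MASS = 5e-5  # each tail; grid spans the central 99.99%
# standard-normal quantile of the tail mass (avoids per-call ppf cost)
_PIF_Z = float(stats.norm.ppf(1.0 - _PIF_TAIL_MASS))


def _pif_grid(
    bmi_mu: np.ndarray, bmi_sigma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Integration grid and lognormal pdf weights, per cohort row."""
    mu = bmi_mu[:, None]
    sigma = bmi_sigma[:, None]
    lo = np.exp(mu - sigma * _PIF_Z)
    hi = np.exp(mu + sigma * _PIF_Z)
    frac = np.linspace(0.0, 1.0, _PIF_GRID_POINTS)[None, :]
    grid = lo + (hi - lo) * frac
    w = np.exp(-((np.log(grid) - mu) ** 2) / (2.0 * sigma**2)) / (
        grid * sigma * np.sqrt(2.0 * np.pi)
    )
    return grid, w


def _mean_rr(
    grid: np.ndarray, w: np.ndarray, shift: np.ndarray, log_rr: float, ref_bmi: float
) -> np.ndarray:
    """E[RR(B - shift)] per cohort row via trapezoidal integration."""
    excess = np.maximum(grid - shift[:, None] - ref_bmi, 0.0)
    vals = np.exp(log_rr * excess)
    if not np.all(np.isfinite(vals)):
        raise ModelConsistencyError("non-finite PIF integrand")
    num = np.trapezoid(vals * w, grid, axis=1)
    den = np.trapezoid(w, grid, axis=1)
    return num / den


def compute_pif(
    bmi_mu: float,
    bmi_sigma: float,
    delta_bmi: float,
    rr_per_5bmi: float,
    ref_bmi: float = 21.0,
) -> float:
    """Potential impact fraction for a lognormal BMI shift.

    ``delta_bmi > 0`` means the exposure distribution moves *down* by
    that many BMI units; a negative value models a harmful shift and
    yields a negative PIF.
    """
    if not bmi_sigma > 0:
        raise InvalidInputError("bmi_sigma must be positive")
    if not rr_per_5bmi > 0:
        raise InvalidInputError("rr_per_5bmi must be positive")
    if delta_bmi == 0.0 or rr_per_5bmi == 1.0:
        return 0.0
    grid, w = _pif_grid(np.array([bmi_mu]), np.array([bmi_sigma]))
    log_rr = np.log(rr_per_5bmi) / 5.0
    shifted = _mean_rr(grid, w, np.array([delta_bmi]), log_rr, ref_bmi)
    base = _mean_rr(grid, w, np.zeros(1), log_rr, ref_bmi)
    return float(1.0 - shifted[0] / base[0])


@dataclass
class DiseaseState:
    """Closed three-state disease sub-model occupancy (persons or
    per-capita proportions; arrays broadcast elementwise)."""

    healthy: np.ndarray | float
    cases: np.ndarray | float
    dead: np.ndarray | float


def disease_model_step(
    state: DiseaseState,
    incidence,
    case_fatality,
    remission=0.0,
) -> DiseaseState:
    """One annual step of the difference equations.

    healthy' = healthy - i*healthy + r*cases
    cases'   = cases + i*healthy - r*cases - f*cases
    dead'    = dead + f*cases
    """
    h, c, d = (
        np.asarray(state.healthy, dtype=float),
        np.asarray(state.cases, dtype=float),
        np.asarray(state.dead, dtype=float),
    )
    i = np.asarray(incidence, dtype=float)
    f = np.asarray(case_fatality, dtype=float)
    r = np.asarray(remission, dtype=float)
    if np.any(i < 0) or np.any(f < 0) or np.any(r < 0) or np.any(i >= 1) or np.any(f >= 1) or np.any(r >= 1):
        raise InvalidInputError("annual rates must lie in [0, 1)")
    h2 = h - i * h + r * c
    c2 = c + i * h - r * c - f * c
    d2 = d + f * c
    if np.any(h2 < 0) or np.any(c2 < 0) or np.any(d2 < 0):
        raise RateOverflowError("annual rates too large: negative occupancy")
    return DiseaseState(healthy=h2, cases=c2, dead=d2)


@dataclass
class LifeTableRun:
    """Per-cohort, per-cycle trajectories for one arm.

    Arrays are shaped ``(n_cohorts, n_cycles)`` (cycle 0 = baseline year);
    entries beyond a cohort's horizon are zero.  ``halys`` are already
    discounted to cycle 0.
    """

    cohorts: pd.DataFrame  # age_lo, age_hi, sex, start_age, size
    disease_names: list[str]
    discount_rate: float
    survivors: np.ndarray
    person_years: np.ndarray
    yld_rate: np.ndarray
    halys: np.ndarray
    prevalent_cases: np.ndarray  # (n_cohorts, n_cycles, n_diseases)

    def total_halys(self) -> float:
        return float(self.halys.sum())

    def same_cohorts(self, other: "LifeTableRun") -> bool:
        a = self.cohorts[["age_lo", "sex", "size"]].reset_index(drop=True)
        b = other.cohorts[["age_lo", "sex", "size"]].reset_index(drop=True)
        return a.equals(b) and self.disease_names == other.disease_names


@dataclass
class Model:
    """Precomputed per-year rate arrays for fast repeated runs.

    Built once from the population and disease tables; the PSA reruns
    :meth:`run` with per-iteration parameter draws without touching
    pandas again.
    """

    cohorts: pd.DataFrame
    config: RunConfig
    disease_names: list[str]
    # per-cohort arrays
    start_age: np.ndarray
    size: np.ndarray
    bmi_mu: np.ndarray
    bmi_sigma: np.ndarray
    # schedules indexed [cohort, cycle] (already expanded along each
    # cohort's own age path; inactive cycles hold 0 rates)
    mort: np.ndarray
    yld: np.ndarray
    inc: np.ndarray  # (cohort, cycle, disease)
    cf: np.ndarray
    rem: np.ndarray
    # per-disease attributes
    dw: np.ndarray
    rr: np.ndarray
    rr_log_se: np.ndarray
    cost_per_case_year: np.ndarray
    min_age: np.ndarray
    n_cycles: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_cycles = self.mort.shape[1]

    # -- construction -----------------------------------------------------

    @classmethod
    def from_tables(
        cls,
        population: pd.DataFrame,
        diseases: pd.DataFrame,
        config: RunConfig | None = None,
    ) -> "Model":
        config = config or RunConfig()
        pop = population.sort_values(["age_lo", "sex"]).reset_index(drop=True)
        horizon = config.horizon_age
        n_coh = len(pop)
        start_age = pop["age_lo"].to_numpy(dtype=int)
        n_cycles = int((horizon - start_age).max())

        names = sorted(diseases["disease"].unique()) if len(diseases) else []
        n_dis = len(names)

        # Expand age-group schedules to single years of age, per sex.
        def year_schedule(df: pd.DataFrame, col: str) -> dict[str, np.ndarray]:
            out = {}
            for sex, grp in df.groupby("sex"):
                arr = np.zeros(horizon)
                for _, row in grp.iterrows():
                    lo, hi = int(row["age_lo"]), int(row["age_hi"])
                    arr[lo:min(hi, horizon)] = row[col]
                out[sex] = arr
            return out

        mort_by_sex = year_schedule(pop, "mortality")
        yld_by_sex = year_schedule(pop, "yld")

        mort = np.zeros((n_coh, n_cycles))
        yld = np.zeros((n_coh, n_cycles))
        inc = np.zeros((n_coh, n_cycles, n_dis))
        cf = np.zeros((n_coh, n_cycles, n_dis))
        rem = np.zeros((n_coh, n_cycles, n_dis))

        dis_sched = {}
        for k, name in enumerate(names):
            sub = diseases[diseases["disease"] == name]
            dis_sched[name] = {
                "incidence": year_schedule(sub, "incidence"),
                "case_fatality": year_schedule(sub, "case_fatality"),
                "remission": year_schedule(sub, "remission"),
            }

        for c in range(n_coh):
            sex = pop.loc[c, "sex"]
            ages = start_age[c] + np.arange(n_cycles)
            active = ages < horizon
            idx = ages[active]
            mort[c, active] = mort_by_sex[sex][idx]
            yld[c, active] = yld_by_sex[sex][idx]
            for k, name in enumerate(names):
                sched = dis_sched[name]
                inc[c, active, k] = sched["incidence"][sex][idx]
                cf[c, active, k] = sched["case_fatality"][sex][idx]
                rem[c, active, k] = sched["remission"][sex][idx]

        if n_dis:
            attrs = (
                diseases.groupby("disease")[
                    ["disability_weight", "rr_per_5bmi", "rr_log_se",
                     "cost_per_case_year", "min_age"]
                ]
                .first()
                .loc[names]
            )
            dw = attrs["disability_weight"].to_numpy(dtype=float)
            rr = attrs["rr_per_5bmi"].to_numpy(dtype=float)
            rr_log_se = attrs["rr_log_se"].to_numpy(dtype=float)
            cost = attrs["cost_per_case_year"].to_numpy(dtype=float)
            min_age = attrs["min_age"].to_numpy(dtype=float)
        else:
            dw = rr = rr_log_se = cost = min_age = np.zeros(0)

        cohorts = pop[["age_lo", "age_hi", "sex", "size"]].copy()
        cohorts["start_age"] = start_age
        return cls(
            cohorts=cohorts,
            config=config,
            disease_names=names,
            start_age=start_age,
            size=pop["size"].to_numpy(dtype=float),
            bmi_mu=pop["bmi_mu"].to_numpy(dtype=float),
            bmi_sigma=pop["bmi_sigma"].to_numpy(dtype=float),
            mort=mort,
            yld=yld,
            inc=inc,
            cf=cf,
            rem=rem,
            dw=dw,
            rr=rr,
            rr_log_se=rr_log_se,
            cost_per_case_year=cost,
            min_age=min_age,
        )

    # -- simulation -------------------------------------------------------

    def pif_matrix(
        self,
        delta_bmi: np.ndarray,
        rr: np.ndarray | None = None,
        bmi_mu: np.ndarray | None = None,
        bmi_sigma: np.ndarray | None = None,
    ) -> np.ndarray:
        """PIF per (cohort, disease) from each cohort's permanent BMI
        change (negative = reduction, as produced by the intake stage)."""
        rr = self.rr if rr is None else np.asarray(rr, dtype=float)
        bmi_mu = self.bmi_mu if bmi_mu is None else np.asarray(bmi_mu, dtype=float)
        bmi_sigma = (
            self.bmi_sigma if bmi_sigma is None else np.asarray(bmi_sigma, dtype=float)
        )
        n_coh, n_dis = len(self.start_age), len(self.disease_names)
        pif = np.zeros((n_coh, n_dis))
        shifted_mask = delta_bmi != 0.0
        if not shifted_mask.any() or n_dis == 0:
            return pif
        if np.any(bmi_sigma <= 0):
            raise InvalidInputError("bmi_sigma must be positive")
        if np.any(rr <= 0):
            raise InvalidInputError("rr_per_5bmi must be positive")
        idx = np.where(shifted_mask)[0]
        grid, w = _pif_grid(bmi_mu[idx], bmi_sigma[idx])
        # engine convention: negative delta_bmi = reduction
        shift = -delta_bmi[idx]
        for k in range(n_dis):
            if rr[k] == 1.0:
                continue
            log_rr = np.log(rr[k]) / 5.0
            shifted = _mean_rr(grid, w, shift, log_rr, self.config.ref_bmi)
            base = _mean_rr(grid, w, np.zeros(len(idx)), log_rr, self.config.ref_bmi)
            pif[idx, k] = 1.0 - shifted / base
        return pif

    def run(
        self,
        delta_bmi: np.ndarray | None = None,
        rr: np.ndarray | None = None,
        bmi_mu: np.ndarray | None = None,
        bmi_sigma: np.ndarray | None = None,
    ) -> tuple[LifeTableRun, LifeTableRun]:
        """Simulate comparator and intervention arms jointly.

        ``delta_bmi`` is the per-cohort permanent BMI change (negative =
        reduction); ``None`` or zeros gives a null intervention.
        The comparator is fully deterministic given the input tables.
        """
        n_coh, n_cyc, n_dis = self.mort.shape[0], self.n_cycles, len(self.disease_names)
        if delta_bmi is None:
            delta_bmi = np.zeros(n_coh)
        delta_bmi = np.asarray(delta_bmi, dtype=float)
        if delta_bmi.shape != (n_coh,):
            raise InvalidInputError("delta_bmi must have one entry per cohort")

        pif = (
            self.pif_matrix(delta_bmi, rr=rr, bmi_mu=bmi_mu, bmi_sigma=bmi_sigma)
            if n_dis
            else np.zeros((n_coh, 0))
        )

        r_disc = self.config.discount_rate
        disc = (1.0 + r_disc) ** -np.arange(n_cyc)
        ages = self.start_age[:, None] + np.arange(n_cyc)[None, :]
        active = ages < self.config.horizon_age

        def empty():
            return dict(
                survivors=np.zeros((n_coh, n_cyc)),
                person_years=np.zeros((n_coh, n_cyc)),
                yld_rate=np.zeros((n_coh, n_cyc)),
                halys=np.zeros((n_coh, n_cyc)),
                prevalent_cases=np.zeros((n_coh, n_cyc, n_dis)),
            )

        out_c, out_i = empty(), empty()

        L_c = self.size.copy()
        L_i = self.size.copy()
        # per-capita disease occupancy (cohort, disease)
        H_c = np.ones((n_coh, n_dis)); C_c = np.zeros((n_coh, n_dis))
        H_i = np.ones((n_coh, n_dis)); C_i = np.zeros((n_coh, n_dis))

        for t in range(n_cyc):
            act = active[:, t]
            if not act.any():
                break
            if n_dis:
                alive_c = H_c + C_c
                alive_i = H_i + C_i
                prev_c = np.divide(C_c, alive_c, out=np.zeros_like(C_c), where=alive_c > 0)
                prev_i = np.divide(C_i, alive_i, out=np.zeros_like(C_i), where=alive_i > 0)
                d_prev = prev_i - prev_c
                excess_mort = (self.cf[:, t, :] * d_prev).sum(axis=1)
                excess_yld = (self.dw[None, :] * d_prev).sum(axis=1)
            else:
                prev_c = prev_i = np.zeros((n_coh, 0))
                excess_mort = excess_yld = np.zeros(n_coh)

            yld_c = self.yld[:, t]
            m_c = self.mort[:, t]
            yld_i = yld_c + excess_yld
            m_i = m_c + excess_mort
            bad = act & ((m_i < 0) | (m_i >= 1) | (yld_i < 0) | (yld_i >= 1))
            if bad.any():
                raise ModelConsistencyError(
                    "adjusted mortality or YLD left [0, 1) at cycle %d" % t
                )

            for out, L, prev, yld_rate in (
                (out_c, L_c, prev_c, yld_c),
                (out_i, L_i, prev_i, yld_i),
            ):
                out["survivors"][act, t] = L[act]
                out["person_years"][act, t] = L[act]
                out["yld_rate"][act, t] = yld_rate[act]
                out["halys"][act, t] = L[act] * (1.0 - yld_rate[act]) * disc[t]
                if n_dis:
                    out["prevalent_cases"][act, t, :] = prev[act] * L[act, None]

            L_c = np.where(act, L_c * (1.0 - m_c), L_c)
            L_i = np.where(act, L_i * (1.0 - m_i), L_i)

            if n_dis:
                i_c = self.inc[:, t, :]
                i_i = i_c * (1.0 - pif)
                f = self.cf[:, t, :]
                rm = self.rem[:, t, :]
                H_c, C_c = (
                    H_c - i_c * H_c + rm * C_c,
                    C_c + i_c * H_c - rm * C_c - f * C_c,
                )
                H_i, C_i = (
                    H_i - i_i * H_i + rm * C_i,
                    C_i + i_i * H_i - rm * C_i - f * C_i,
                )

        runs = []
        for out in (out_c, out_i):
            runs.append(
                LifeTableRun(
                    cohorts=self.cohorts.copy(),
                    disease_names=list(self.disease_names),
                    discount_rate=r_disc,
                    **out,
                )
            )
        return runs[0], runs[1]


def run_life_table(
    population: pd.DataFrame,
    diseases: pd.DataFrame,
    delta_bmi_by_cohort: pd.DataFrame | None,
    config: RunConfig | None = None,
) -> tuple[LifeTableRun, LifeTableRun]:
    """Build the model from tables and simulate both arms.

    ``delta_bmi_by_cohort`` carries columns ``age_lo, sex, delta_bmi``
    (negative = reduction); missing cohorts default to zero change.
    """
    config = config or RunConfig()
    model = Model.from_tables(population, diseases, config)
    delta = np.zeros(len(model.cohorts))
    if delta_bmi_by_cohort is not None:
        key = {(int(r.age_lo), r.sex): r.delta_bmi
               for r in delta_bmi_by_cohort.itertuples()}
        for j, row in model.cohorts.iterrows():
            delta[j] = key.get((int(row["age_lo"]), row["sex"]), 0.0)
    return model.run(delta)


def incremental_halys(comparator: LifeTableRun, intervention: LifeTableRun) -> float:
    """Discounted HALY total of intervention minus comparator."""
    if not comparator.same_cohorts(intervention):
        raise InvalidPairingError("runs do not share the same cohort structure")
    return intervention.total_halys() - comparator.total_halys()
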