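"""Probabilistic sensitivity analysis (PSA).

Every uncertain input is sampled per iteration from its assigned family:

* the intervention weight-change effect — Normal, with SD equal to the
  mean (the convention when no sampling variance is available); the draw
  rescales the whole per-cohort effect vector, preserving its age/sex
  structure;
* intervention costs — Pert (scaled Beta, lambda = 4) over expert
  (min, mode, max) ranges; the legislation item uses a Gamma matched to
  its point estimate and range;
* cohort mean BMI — lognormal, multiplicative around the point estimate;
* disease relative risks per 5 BMI units — lognormal on the log scale.

The deterministic pipeline is rerun per draw and each iteration yields a
cost-effectiveness outcome.  Iterations are summarised by means with
percentile 95% uncertainty intervals and by cost-effectiveness-plane
quadrant shares; iteration ``k`` uses its own derived substream so it is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .costing import (
    CEOutcome,
    CostItem,
    aggregate_intervention_costs,
    compute_cost_offsets,
    iteration_icer,
    net_and_icer,
)
from .errors import InvalidConfigError, InvalidInputError, ModelConsistencyError
from .pmslt import Model, incremental_halys

_PERT_LAMBDA = 4.0


@dataclass(frozen=True)
class ParamDistribution:
    """One uncertain parameter: family plus family-specific parameters.

    families and parameters:
      normal     — mean, sd
      pert       — min, mode, max
      lognormal  — log_mean, log_sd
      gamma      — shape, scale
    """

    name: str
    family: str
    parameters: dict

    def __post_init__(self) -> None:
        p = self.parameters
        if self.family == "normal":
            if p["sd"] < 0:
                raise InvalidConfigError("normal sd must be >= 0")
        elif self.family == "pert":
            if not p["min"] <= p["mode"] <= p["max"]:
                raise InvalidConfigError("pert requires min <= mode <= max")
        elif self.family == "lognormal":
            if p["log_sd"] < 0:
                raise InvalidConfigError("lognormal log_sd must be >= 0")
        elif self.family == "gamma":
            if p["shape"] <= 0 or p["scale"] <= 0:
                raise InvalidConfigError("gamma shape and scale must be > 0")
        else:
            raise InvalidConfigError(f"unknown family {self.family!r}")


def sample_parameter(dist: ParamDistribution, rng: np.random.Generator) -> float:
    """One draw from a parameter distribution."""
    p = dist.parameters
    if dist.family == "normal":
        return float(p["mean"]) if p["sd"] == 0 else float(rng.normal(p["mean"], p["sd"]))
    if dist.family == "pert":
        lo, mode, hi = p["min"], p["mode"], p["max"]
        if hi == lo:
            return float(lo)
        alpha = 1.0 + _PERT_LAMBDA * (mode - lo) / (hi - lo)
        beta = 1.0 + _PERT_LAMBDA * (hi - mode) / (hi - lo)
        return float(lo + (hi - lo) * rng.beta(alpha, beta))
    if dist.family == "lognormal":
        if p["log_sd"] == 0:
            return float(np.exp(p["log_mean"]))
        return float(rng.lognormal(p["log_mean"], p["log_sd"]))
    if dist.family == "gamma":
        return float(rng.gamma(p["shape"], p["scale"]))
    raise InvalidConfigError(f"unknown family {dist.family!r}")


def pert_mean(lo: float, mode: float, hi: float) -> float:
    """Analytic mean of the modified Pert with lambda = 4."""
    return (lo + 4.0 * mode + hi) / 6.0


def gamma_from_range(point: float, lo: float, hi: float) -> ParamDistribution:
    """Gamma matched to a point estimate (mean) and a 95% expert range
    (SD taken as range width / 3.92)."""
    sd = (hi - lo) / 3.92
    if sd <= 0:
        sd = max(point * 1e-12, 1e-12)
    shape = (point / sd) ** 2
    scale = sd**2 / point
    return ParamDistribution("gamma", "gamma", {"shape": shape, "scale": scale})


@dataclass
class PSAInputs:
    """Everything the PSA needs to rerun the pipeline per draw."""

    model: Model
    delta_kg: np.ndarray  # per-cohort point-estimate weight change (kg)
    heights: np.ndarray  # per-cohort mean height (m)
    mean_delta_kg: float  # population-mean weight change (Normal draw centre)
    costs: pd.DataFrame  # cost table rows (all scenarios)
    scenario: str
    config: RunConfig


@dataclass
class PSAResult:
    iterations: list[CEOutcome]
    n: int
    n_failed: int
    summaries: dict
    quadrant_shares: dict
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "intervention_cost": it.intervention_cost,
                    "cost_offsets": it.cost_offsets,
                    "net_cost": it.net_cost,
                    "halys": it.halys,
                    "icer": it.icer if it.icer is not None else np.nan,
                    "label": it.label,
                }
                for it in self.iterations
            ]
        )


def _draw_costs(
    cost_rows: pd.DataFrame, rng: np.random.Generator, enabled: bool
) -> list[CostItem]:
    items = []
    for _, row in cost_rows.iterrows():
        if not enabled:
            value = float(row["value"])
        elif row.get("distribution", "pert") == "gamma":
            value = sample_parameter(
                gamma_from_range(row["value"], row["min"], row["max"]), rng
            )
        else:
            value = sample_parameter(
                ParamDistribution(
                    row["item"], "pert",
                    {"min": row["min"], "mode": row["value"], "max": row["max"]},
                ),
                rng,
            )
        items.append(CostItem(name=row["item"], value=value, schedule=row["schedule"]))
    return items


def run_iteration(inputs: PSAInputs, rng: np.random.Generator) -> CEOutcome:
    """One PSA iteration: draw parameters, rerun the pipeline."""
    cfg = inputs.config
    psa = cfg.psa
    model = inputs.model

    # Effect draw: rescale the whole cohort weight-change vector.
    mean = inputs.mean_delta_kg
    sd = abs(mean) * psa.effect_sd_ratio
    draw = sample_parameter(
        ParamDistribution("effect", "normal", {"mean": mean, "sd": sd}), rng
    )
    scale = 1.0 if mean == 0.0 else draw / mean
    delta_kg = inputs.delta_kg * scale
    delta_bmi = delta_kg / inputs.heights**2

    # Relative-risk draws (log scale).
    if psa.rr_uncertainty and len(model.rr):
        rr = np.exp(rng.normal(np.log(model.rr), model.rr_log_se))
    else:
        rr = model.rr

    # Cohort mean-BMI draws (multiplicative lognormal).
    if psa.bmi_mean_rel_se > 0:
        bmi_mu = model.bmi_mu + rng.normal(
            0.0, psa.bmi_mean_rel_se, size=model.bmi_mu.shape
        )
    else:
        bmi_mu = model.bmi_mu

    comp, interv = model.run(delta_bmi, rr=rr, bmi_mu=bmi_mu)
    halys = incremental_halys(comp, interv)
    offsets = compute_cost_offsets(comp, interv, model.cost_per_case_year)

    cost_rows = inputs.costs[inputs.costs["scenario"] == inputs.scenario]
    items = _draw_costs(cost_rows, rng, psa.cost_uncertainty)
    cost = aggregate_intervention_costs(
        items, cfg.horizon_age, cfg.discount_rate, cfg.labelling_cycle_years
    )
    return net_and_icer(cost, offsets, halys, cfg.wtp)


def run_psa(inputs: PSAInputs, n_iter: int | None = None, seed: int | None = None) -> PSAResult:
    """Run the Monte Carlo PSA and summarise it.

    Iterations that raise a model-consistency error are counted in
    ``n_failed`` rather than silently dropped.
    """
    cfg = inputs.config
    n_iter = cfg.n_iter if n_iter is None else n_iter
    seed = cfg.seed if seed is None else seed
    iterations: list[CEOutcome] = []
    n_failed = 0
    for k in range(n_iter):
        rng = np.random.default_rng([seed, k])
        try:
            iterations.append(run_iteration(inputs, rng))
        except ModelConsistencyError:
            n_failed += 1
    summaries, shares = summarize(iterations, wtp=cfg.wtp)
    return PSAResult(
        iterations=iterations,
        n=n_iter,
        n_failed=n_failed,
        summaries=summaries,
        quadrant_shares=shares,
        seed=seed,
    )


def summarize(iterations: list[CEOutcome], wtp: float = 50_000.0) -> tuple[dict, dict]:
    """Means, percentile 95% UIs and CE-plane quadrant shares.

    Quadrants are assigned from the signs of (incremental HALYs, net
    cost); boundary iterations count toward the positive side (zero net
    cost is "North", zero HALYs is "East").  The ICER summary averages
    per-iteration ratios over iterations with positive HALYs (cost-saving
    iterations keep their negative ratio); its lower bound is reported as
    "dominant" when the 2.5th-percentile iteration is cost saving.
    """
    if not iterations:
        raise InvalidInputError("need at least one iteration")
    df = pd.DataFrame(
        {
            "halys": [it.halys for it in iterations],
            "net_cost": [it.net_cost for it in iterations],
            "intervention_cost": [it.intervention_cost for it in iterations],
            "cost_offsets": [it.cost_offsets for it in iterations],
        }
    )
    summaries = {}
    for col in df.columns:
        v = df[col].to_numpy()
        summaries[col] = {
            "mean": float(v.mean()),
            "ui_low": float(np.percentile(v, 2.5)),
            "ui_high": float(np.percentile(v, 97.5)),
        }
    ratios = np.array(
        [r for r in (iteration_icer(it.net_cost, it.halys) for it in iterations)
         if r is not None]
    )
    if len(ratios):
        lo, hi = np.percentile(ratios, [2.5, 97.5])
        summaries["icer"] = {
            "mean": float(ratios.mean()),
            "ui_low": float(lo),
            "ui_high": float(hi),
            "ui_low_label": "dominant" if lo < 0 else f"{lo:.0f}",
            "n_positive_haly": int(len(ratios)),
        }
    else:
        summaries["icer"] = {"mean": None, "ui_low": None, "ui_high": None,
                             "ui_low_label": "undefined", "n_positive_haly": 0}

    east = df["halys"] >= 0
    north = df["net_cost"] >= 0
    n = len(df)
    shares = {
        "NE": float((east & north).sum() / n),
        "NW": float((~east & north).sum() / n),
        "SE": float((east & ~north).sum() / n),
        "SW": float((~east & ~north).sum() / n),
    }
    return summaries, shares


def plot_ce_plane(
    iterations: list[CEOutcome],
    wtp: float = 50_000.0,
    path=None,
    title: str = "Cost-effectiveness plane",
):
    """Scatter of (incremental HALYs, net cost) with the WTP line.

    Returns the matplotlib figure; writes it to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not iterations:
        raise InvalidInputError("need at least one iteration")
    halys = np.array([it.halys for it in iterations])
    net = np.array([it.net_cost for it in iterations])
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(halys, net / 1e6, s=8, alpha=0.5, edgecolors="none")
    span = max(abs(halys).max(), 1.0) * 1.1
    xs = np.linspace(-span, span, 2)
    ax.plot(xs, wtp * xs / 1e6, color="firebrick", lw=1,
            label=f"WTP A${wtp:,.0f}/HALY")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental HALYs")
    ax.set_ylabel("Incremental net cost (A$ millions)")
    ax.set_title(title)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
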