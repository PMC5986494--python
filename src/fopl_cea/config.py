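"""Configuration objects shared across the pipeline.

All randomness in the package flows from explicit integer seeds held in
these objects; no module reads the global NumPy RNG or a clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from .errors import InvalidConfigError

#: Default 5-year age groups covering [0, 100).
DEFAULT_AGE_GROUPS: tuple[tuple[int, int], ...] = tuple(
    (lo, lo + 5) for lo in range(0, 100, 5)
)

SEXES = ("female", "male")


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidConfigError(msg)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic input-data generator.

    Defaults encode the evaluated Australian setting: ~6.7% voluntary HSR
    uptake among pre-packaged products, a mean extra energy-density
    reduction of 7.11 kJ/100 g among labelled products, 13 reformulable
    food categories, nine obesity-related diseases, and a 3% annual
    discount rate.
    """

    seed: int = 20100614
    n_products: int = 14986
    n_categories: int = 13
    uptake_target: float = 0.067
    labelled_reform_mean: float = -7.11  # kJ/100 g extra change, labelled arm
    unlabelled_drift_mean: float = -1.0  # kJ/100 g secular change, both arms
    product_noise_sd: float = 40.0  # kJ/100 g product-level change noise
    age_groups: Sequence[tuple[int, int]] = DEFAULT_AGE_GROUPS
    n_diseases: int = 9
    discount_rate: float = 0.03
    adult_min_age: int = 18  # disease onset and adult energy-balance rule
    mortality_floor_age: int = 10  # mortality nondecreasing beyond this age

    def __post_init__(self) -> None:
        _check(self.n_products > 0, "n_products must be positive")
        _check(self.n_categories >= 1, "n_categories must be >= 1")
        _check(self.n_diseases >= 1, "n_diseases must be >= 1")
        _check(0 < self.uptake_target <= 1, "uptake_target must be in (0, 1]")
        _check(self.product_noise_sd >= 0, "product_noise_sd must be >= 0")
        _check(0 <= self.discount_rate < 1, "discount_rate must be in [0, 1)")
        groups = [tuple(g) for g in self.age_groups]
        _check(len(groups) > 0, "age_groups must be non-empty")
        groups.sort()
        _check(groups[0][0] == 0 and groups[-1][1] == 100,
               "age groups must cover [0, 100)")
        for (lo, hi), (lo2, _hi2) in zip(groups, groups[1:]):
            _check(lo < hi and hi == lo2, "age groups must partition [0, 100)")
        _check(groups[-1][0] < groups[-1][1], "age groups must partition [0, 100)")
        self.age_groups = tuple(groups)


@dataclass
class EnergyWeightParams:
    """Linear steady-state energy-balance coefficients.

    ``rho`` is the sustained change in daily energy intake (kJ/day) that
    produces 1 kg of eventual body-weight change.  The default of 100
    kJ/day per kg is a round-number approximation to published adult
    energy-balance equations; it is a configuration parameter precisely
    because that literature offers a range of values.
    """

    rho_adult: float = 100.0
    rho_child: float = 100.0
    adult_age_threshold: int = 18

    def __post_init__(self) -> None:
        _check(self.rho_adult > 0 and self.rho_child > 0, "rho must be > 0")

    def rho(self, age: float) -> float:
        return self.rho_adult if age >= self.adult_age_threshold else self.rho_child


@dataclass
class PSAConfig:
    """Which sources of parameter uncertainty the PSA samples.

    ``effect_sd_ratio`` scales the standard deviation of the normal draw
    around the mean intervention weight change (1.0 reproduces the
    SD-equals-mean convention used when no sampling variance is
    available).  Setting every field to its degenerate value makes the
    PSA reproduce the deterministic pipeline exactly.
    """

    effect_sd_ratio: float = 1.0
    cost_uncertainty: bool = True
    rr_uncertainty: bool = True
    bmi_mean_rel_se: float = 0.02

    def __post_init__(self) -> None:
        _check(self.effect_sd_ratio >= 0, "effect_sd_ratio must be >= 0")
        _check(self.bmi_mean_rel_se >= 0, "bmi_mean_rel_se must be >= 0")

    @classmethod
    def degenerate(cls) -> "PSAConfig":
        return cls(effect_sd_ratio=0.0, cost_uncertainty=False,
                   rr_uncertainty=False, bmi_mean_rel_se=0.0)


@dataclass
class RunConfig:
    """Full configuration of one scenario evaluation."""

    scenario: str = "voluntary"
    attributable_fraction: float = 1.0
    discount_rate: float = 0.03
    wtp: float = 50_000.0  # A$ per HALY
    horizon_age: int = 100
    labelling_cycle_years: int = 3
    ref_bmi: float = 21.0  # kg/m^2; relative risk floored to 1 at/below this
    n_iter: int = 2000
    seed: int = 0
    energy_weight: EnergyWeightParams = field(default_factory=EnergyWeightParams)
    psa: PSAConfig = field(default_factory=PSAConfig)
    excluded_categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _check(self.scenario in ("voluntary", "mandatory"),
               "scenario must be 'voluntary' or 'mandatory'")
        _check(0 <= self.attributable_fraction <= 1,
               "attributable_fraction must be in [0, 1]")
        _check(0 <= self.discount_rate < 1, "discount_rate must be in [0, 1)")
        _check(self.wtp > 0, "wtp must be positive")
        _check(self.horizon_age >= 1, "horizon_age must be >= 1")
        _check(self.labelling_cycle_years >= 1, "labelling_cycle must be >= 1")
        _check(self.n_iter >= 1, "n_iter must be >= 1")
        if isinstance(self.energy_weight, dict):
            self.energy_weight = EnergyWeightParams(**self.energy_weight)
        if isinstance(self.psa, dict):
            self.psa = PSAConfig(**self.psa)

    def to_dict(self) -> dict:
        return asdict(self)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def load_synthetic_config(path: str | Path) -> SyntheticConfig:
    """Load a :class:`SyntheticConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "age_groups" in raw:
        raw["age_groups"] = [tuple(g) for g in raw["age_groups"]]
    return SyntheticConfig(**raw)
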