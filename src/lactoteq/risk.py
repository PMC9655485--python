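"""Infant intake modelling and regulatory screening.

Daily intake is ``TEQ_ww * milk volume * density / body weight`` in
pg-TEQ/kg bw/day; the weekly value (x7) is compared against the tolerable
weekly intake (TWI, 2 pg-TEQ/kg bw/week; legacy value 14).  Compliance
screening compares wet-weight dl-TEQ and the ndl indicator sum against the
EU maximum levels for foods for infants and young children
(0.1 pg-TEQ/g w.w. and 1 ng/g w.w.).
"""

from __future__ import annotations

from dataclasses import dataclass

from .congeners import CongenerGroup
from .datamodel import Basis, MilkSample
from .errors import DomainError
from .teq import BoundStrategy, TEFScheme, WHO_2005, compute_teq, sum_group

__all__ = [
    "IntakeScenario",
    "RiskThresholds",
    "IntakeResult",
    "ComplianceResult",
    "daily_intake",
    "default_sex_volumes",
    "compliance_check",
    "infant_weight_at",
    "GrowthModel",
]

VOLUME_BOUNDS_ML = (478.0, 1356.0)
DEFAULT_VOLUME_ML = 798.0
DEFAULT_SEX_GAP_ML = 76.0


@dataclass(frozen=True)
class IntakeScenario:
    """One infant-feeding scenario for intake arithmetic."""

    sex: str
    milk_volume_ml_per_day: float
    body_weight_kg: float
    milk_density_g_per_ml: float = 1.0
    stage_days: int | None = None
    volume_bounds_ml: tuple[float, float] = VOLUME_BOUNDS_ML

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex must be 'male' or 'female', got {self.sex!r}")
        lo, hi = self.volume_bounds_ml
        if not (lo <= self.milk_volume_ml_per_day <= hi):
            raise DomainError(
                f"milk volume {self.milk_volume_ml_per_day} mL/day outside [{lo}, {hi}]"
            )
        if self.body_weight_kg <= 0:
            raise DomainError("body_weight_kg must be > 0")
        if self.milk_density_g_per_ml <= 0:
            raise DomainError("milk_density_g_per_ml must be > 0")


@dataclass(frozen=True)
class RiskThresholds:
    twi_pg_teq_per_kg_week: float = 2.0
    twi_legacy: float = 14.0
    max_dl_teq_pg_per_g_ww: float = 0.1
    max_ndl_ng_per_g_ww: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "twi_pg_teq_per_kg_week",
            "twi_legacy",
            "max_dl_teq_pg_per_g_ww",
            "max_ndl_ng_per_g_ww",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")


@dataclass(frozen=True)
class IntakeResult:
    daily_pg_teq_per_kg: float
    weekly_pg_teq_per_kg: float
    twi_fraction: float
    exceeds_twi: bool
    twi_pg_teq_per_kg_week: float


@dataclass(frozen=True)
class ComplianceResult:
    dl_teq_ww: float
    ndl_sum_ww: float
    dl_fraction_of_limit: float
    ndl_fraction_of_limit: float
    compliant_dl: bool
    compliant_ndl: bool


def daily_intake(
    teq_ww: float,
    scenario: IntakeScenario,
    thresholds: RiskThresholds = RiskThresholds(),
) -> IntakeResult:
    """Daily and weekly pg-TEQ intake per kg body weight, with TWI check.

    *teq_ww* is the milk TEQ on a wet-weight basis in pg-TEQ/g.
    """
    if teq_ww < 0:
        raise DomainError("teq_ww must be >= 0")
    grams = scenario.milk_volume_ml_per_day * scenario.milk_density_g_per_ml
    daily = teq_ww * grams / scenario.body_weight_kg
    weekly = 7.0 * daily
    twi = thresholds.twi_pg_teq_per_kg_week
    fraction = weekly / twi
    return IntakeResult(
        daily_pg_teq_per_kg=daily,
        weekly_pg_teq_per_kg=weekly,
        twi_fraction=fraction,
        exceeds_twi=fraction > 1.0,
        twi_pg_teq_per_kg_week=twi,
    )


def default_sex_volumes(
    overall_mean: float = DEFAULT_VOLUME_ML,
    sex_gap: float = DEFAULT_SEX_GAP_ML,
    male_fraction: float = 0.625,
) -> tuple[float, float]:
    """(female_mean, male_mean) daily volumes consistent with an overall mean.

    Males drink *sex_gap* mL more than females; the *male_fraction*-weighted
    mean of the two reproduces *overall_mean*.
    """
    if not (0.0 <= male_fraction <= 1.0):
        raise DomainError("male_fraction must be in [0, 1]")
    female = overall_mean - male_fraction * sex_gap
    male = female + sex_gap
    if female <= 0 or male <= 0:
        raise DomainError("sex gap produces a non-positive volume")
    return female, male


def compliance_check(
    sample: MilkSample,
    thresholds: RiskThresholds = RiskThresholds(),
    bound: BoundStrategy = BoundStrategy.UPPER,
    scheme: TEFScheme = WHO_2005,
) -> ComplianceResult:
    """Screen one sample against the wet-weight EU maximum levels."""
    teq = compute_teq(sample, scheme=scheme, bound=bound, basis=Basis.WET_WEIGHT)
    ndl = sum_group(
        sample, CongenerGroup.NDL_INDICATOR, bound=bound, basis=Basis.WET_WEIGHT
    )
    dl_frac = teq.teq / thresholds.max_dl_teq_pg_per_g_ww
    ndl_frac = ndl / thresholds.max_ndl_ng_per_g_ww
    return ComplianceResult(
        dl_teq_ww=teq.teq,
        ndl_sum_ww=ndl,
        dl_fraction_of_limit=dl_frac,
        ndl_fraction_of_limit=ndl_frac,
        compliant_dl=dl_frac <= 1.0,
        compliant_ndl=ndl_frac <= 1.0,
    )


@dataclass(frozen=True)
class GrowthModel:
    """Piecewise-linear infant growth; ``mode="none"`` keeps birth weight."""

    mode: str = "linear"
    gain_kg_per_month_early: float = 0.6
    gain_kg_per_month_late: float = 0.4
    early_months: int = 6
    month_days: float = 30.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "linear"):
            raise DomainError(f"growth mode must be 'none' or 'linear', got {self.mode!r}")


def infant_weight_at(
    stage_days: float,
    birth_weight_kg: float,
    growth: GrowthModel = GrowthModel(),
) -> float:
    """Infant body weight at a lactation stage under the growth model."""
    if stage_days < 0:
        raise DomainError("stage_days must be >= 0")
    if growth.mode == "none":
        return birth_weight_kg
    early_days = growth.early_months * growth.month_days
    d_early = min(stage_days, early_days)
    d_late = max(stage_days - early_days, 0.0)
    return (
        birth_weight_kg
        + growth.gain_kg_per_month_early * d_early / growth.month_days
        + growth.gain_kg_per_month_late * d_late / growth.month_days
    )
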