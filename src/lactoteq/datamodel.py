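"""Core domain types: measurements, samples, maternal/infant profiles.

Concentrations live in a small unit system (wet-weight vs lipid basis;
ng/g vs pg/g).  Every type validates its invariants on construction, so a
successfully built object graph is safe to compute on.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .congeners import CongenerID
from .errors import DomainError, ValidationError

__all__ = [
    "Basis",
    "Units",
    "CensorState",
    "CongenerMeasurement",
    "MilkComposition",
    "MilkSample",
    "MaternalProfile",
    "InfantProfile",
    "StageSchedule",
    "DEFAULT_SCHEDULE",
    "stage_label_for",
    "FOOD_CATEGORIES",
    "FREQUENCY_CODES",
]


class Basis(str, enum.Enum):
    WET_WEIGHT = "wet_weight"
    LIPID = "lipid"


class Units(str, enum.Enum):
    NG_PER_G = "ng_per_g"
    PG_PER_G = "pg_per_g"


#: multiplicative factor taking a value in the given units to pg/g
_TO_PG = {Units.NG_PER_G: 1000.0, Units.PG_PER_G: 1.0}


class CensorState(str, enum.Enum):
    DETECTED = "detected"
    BELOW_LOQ = "below_loq"
    BELOW_LOD = "below_lod"


@dataclass(frozen=True)
class CongenerMeasurement:
    """One concentration value for one congener in one milk sample.

    For censored states (``below_lod`` / ``below_loq``) ``value`` carries the
    applicable analytical limit, not an actual measurement.
    """

    congener: CongenerID
    value: float
    basis: Basis
    units: Units
    censor: CensorState = CensorState.DETECTED
    lod: float | None = None
    loq: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise ValidationError(
                f"PCB {self.congener.iupac_number}: concentration must be a finite "
                f"non-negative number, got {self.value!r}"
            )
        if self.lod is not None and self.lod < 0:
            raise ValidationError("lod must be >= 0")
        if self.loq is not None:
            if self.loq < 0:
                raise ValidationError("loq must be >= 0")
            if self.lod is not None and self.loq < self.lod:
                raise ValidationError(f"loq ({self.loq}) < lod ({self.lod})")
        if self.censor is CensorState.BELOW_LOD:
            if self.lod is None:
                raise ValidationError("below_lod measurement must carry its LOD")
            if not math.isclose(self.value, self.lod, rel_tol=1e-9, abs_tol=1e-15):
                raise ValidationError(
                    "below_lod measurement must store the LOD as its value"
                )
        elif self.censor is CensorState.BELOW_LOQ:
            if self.loq is None:
                raise ValidationError("below_loq measurement must carry its LOQ")
            if not math.isclose(self.value, self.loq, rel_tol=1e-9, abs_tol=1e-15):
                raise ValidationError(
                    "below_loq measurement must store the LOQ as its value"
                )

    @property
    def limit(self) -> float | None:
        """The applicable limit for a censored state (LOD or LOQ)."""
        if self.censor is CensorState.BELOW_LOD:
            return self.lod
        if self.censor is CensorState.BELOW_LOQ:
            return self.loq
        return None

    def value_pg_per_g(self) -> float:
        """The stored value expressed in pg/g (same basis)."""
        return self.value * _TO_PG[self.units]


_COMPOSITION_TOL = 0.5  # percentage points of slack on the dry-matter balance


@dataclass(frozen=True)
class MilkComposition:
    """Milk macro-composition, as percentages of whole milk."""

    lipid_pct: float
    dry_matter_pct: float
    protein_pct: float
    lactose_pct: float

    def __post_init__(self) -> None:
        for name in ("lipid_pct", "dry_matter_pct", "protein_pct", "lactose_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name}={v!r} outside [0, 100]")
        components = self.lipid_pct + self.protein_pct + self.lactose_pct
        if components > self.dry_matter_pct + _COMPOSITION_TOL:
            raise ValidationError(
                f"lipid+protein+lactose ({components:.2f}%) exceeds dry matter "
                f"({self.dry_matter_pct:.2f}%) beyond tolerance"
            )

    @property
    def lipid_fraction(self) -> float:
        return self.lipid_pct / 100.0


@dataclass(frozen=True)
class StageSchedule:
    """Mapping from days postpartum to the 17-point collection schedule.

    Weekly collections in the first month (days 7, 14, 21, 28), then monthly
    bins of ``month_length_days``, then an open-ended final stage.  A day is
    assigned to the most recent completed scheduled point (half-open bins).
    """

    month_length_days: float = 30.44
    n_months: int = 12
    final_label: str = ">1 year of feeding"

    @property
    def labels(self) -> tuple[str, ...]:
        monthly = tuple(f"{m} months" for m in range(2, self.n_months + 1))
        return ("<7 days", "7 days", "14 days", "21 days", "28 days") + monthly + (
            self.final_label,
        )

    def label_for(self, days: int) -> str:
        if days < 1:
            raise DomainError(f"days postpartum must be >= 1, got {days}")
        if days < 7:
            return "<7 days"
        if days < 14:
            return "7 days"
        if days < 21:
            return "14 days"
        if days < 28:
            return "21 days"
        if days <= self.month_length_days:
            return "28 days"
        if days > self.month_length_days * self.n_months:
            return self.final_label
        month = math.ceil(days / self.month_length_days)
        return f"{month} months"

    def representative_day(self, label: str) -> int:
        """A canonical day inside the bin of *label* (used by the simulator)."""
        if label == "<7 days":
            return 3
        if label.endswith(" days"):
            return int(label.split()[0])
        if label == self.final_label:
            return 400
        month = int(label.split()[0])
        return int(self.month_length_days * month)  # end-of-month collection


DEFAULT_SCHEDULE = StageSchedule()


def stage_label_for(days: int, schedule: StageSchedule = DEFAULT_SCHEDULE) -> str:
    """Map days postpartum to a collection-schedule stage label."""
    return schedule.label_for(days)


# ---------------------------------------------------------------------------
# questionnaire codebooks
# ---------------------------------------------------------------------------

AGE_BANDS = ("<18", "18-22", "23-27", "28-32", "33-36")
WEIGHT_BEFORE_BANDS = ("<55", "56-60", "61-65", ">65")
WEIGHT_AFTER_BANDS = ("55-60", "61-65", "66-70", ">70")
RESIDENCE_LEVELS = ("city_gt_5000", "town_lt_5000", "country")
EDUCATION_LEVELS = ("primary", "secondary", "higher")
DELIVERY_MODES = ("natural", "c_section")
SMOKING_LEVELS = ("never", "quit_before_pregnancy", "up_to_one_pack", "more_than_one_pack")
BIRTH_WEIGHT_BANDS = ("2.4-2.8", "2.9-3.2", "3.3-3.6", "3.7-4.0", ">4.0")

FOOD_CATEGORIES = (
    "fish",
    "dairy",
    "beef",
    "pork",
    "poultry",
    "eggs",
    "vegetables",
    "fruit",
    "whole_grains",
    "wheat_rye_bread",
)

#: ordinal consumption-frequency codes, least to most frequent
FREQUENCY_CODES = ("never", "rarely", "weekly", "twice_weekly_plus", "daily")


def _check_level(name: str, value: str, levels: tuple[str, ...]) -> None:
    if value not in levels:
        raise ValidationError(f"{name}={value!r} not in codebook {levels}")


@dataclass(frozen=True)
class MaternalProfile:
    """Questionnaire record for one mother."""

    mother_id: str
    age_band: str
    weight_before_band: str
    weight_after_band: str
    residence: str
    education: str
    parity: int
    delivery: str
    smoking: str
    food_frequency: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_level("age_band", self.age_band, AGE_BANDS)
        _check_level("weight_before_band", self.weight_before_band, WEIGHT_BEFORE_BANDS)
        _check_level("weight_after_band", self.weight_after_band, WEIGHT_AFTER_BANDS)
        _check_level("residence", self.residence, RESIDENCE_LEVELS)
        _check_level("education", self.education, EDUCATION_LEVELS)
        _check_level("delivery", self.delivery, DELIVERY_MODES)
        _check_level("smoking", self.smoking, SMOKING_LEVELS)
        if self.parity < 1:
            raise ValidationError(f"parity must be >= 1, got {self.parity}")
        for food, freq in self.food_frequency.items():
            if food not in FOOD_CATEGORIES:
                raise ValidationError(f"unknown food category {food!r}")
            _check_level(f"food_frequency[{food}]", freq, FREQUENCY_CODES)

    def frequency_code(self, food: str) -> int:
        """Ordinal code (0 = never ... 4 = daily) for a food category."""
        return FREQUENCY_CODES.index(self.food_frequency[food])


@dataclass(frozen=True)
class InfantProfile:
    mother_id: str
    sex: str
    birth_weight_kg: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex={self.sex!r} must be 'male' or 'female'")
        if not (1.5 <= self.birth_weight_kg <= 6.0):
            raise ValidationError(
                f"birth_weight_kg={self.birth_weight_kg!r} outside plausible [1.5, 6]"
            )


@dataclass(frozen=True)
class MilkSample:
    """One milk collection event with its composition and measurements."""

    sample_id: str
    mother_id: str
    stage_days: int
    composition: MilkComposition
    measurements: tuple[CongenerMeasurement, ...]
    stage_label: str | None = None
    schedule: StageSchedule = DEFAULT_SCHEDULE

    def __post_init__(self) -> None:
        if self.stage_days < 1:
            raise DomainError(f"stage_days must be >= 1, got {self.stage_days}")
        object.__setattr__(self, "measurements", tuple(self.measurements))
        seen: set[int] = set()
        for m in self.measurements:
            n = m.congener.iupac_number
            if n in seen:
                raise ValidationError(
                    f"sample {self.sample_id!r}: duplicate measurement for PCB {n}"
                )
            seen.add(n)
        expected = self.schedule.label_for(self.stage_days)
        if self.stage_label is None:
            object.__setattr__(self, "stage_label", expected)
        elif self.stage_label != expected:
            raise ValidationError(
                f"sample {self.sample_id!r}: stage_label {self.stage_label!r} "
                f"inconsistent with stage_days={self.stage_days} ({expected!r})"
            )

    def measurement_for(self, iupac_number: int) -> CongenerMeasurement | None:
        for m in self.measurements:
            if m.congener.iupac_number == iupac_number:
                return m
        return None
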