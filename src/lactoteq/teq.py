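"""TEF schemes, censoring-bound substitution, basis conversion, and the
TEF-weighted toxic-equivalent (TEQ) sum over dioxin-like congeners.

The central quantity is ``TEQ = sum_i c_i * TEF_i`` where ``c_i`` are
concentrations of the 12 dioxin-like congeners (pg/g) and ``TEF_i`` their
toxic equivalency factors relative to 2,3,7,8-TCDD.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

from .congeners import (
    CongenerGroup,
    CongenerID,
    DL_CONGENERS,
    group_members,
)
from .datamodel import Basis, CensorState, CongenerMeasurement, MilkSample, Units
from .errors import ConfigurationError, DegenerateSampleError, ValidationError

__all__ = [
    "TEFScheme",
    "WHO_2005",
    "BoundStrategy",
    "TEQResult",
    "convert_basis",
    "substitute_censored",
    "compute_teq",
    "sum_group",
]


@dataclass(frozen=True)
class TEFScheme:
    """A named map from dioxin-like congeners to toxic equivalency factors."""

    name: str
    tef: dict[int, float]

    def __post_init__(self) -> None:
        dl_numbers = {c.iupac_number for c in DL_CONGENERS}
        missing = dl_numbers - set(self.tef)
        if missing:
            raise ConfigurationError(
                f"TEF scheme {self.name!r} lacks factors for congeners {sorted(missing)}"
            )
        extra = set(self.tef) - dl_numbers
        if extra:
            raise ConfigurationError(
                f"TEF scheme {self.name!r} assigns factors to non-dl congeners "
                f"{sorted(extra)}"
            )
        for n, f in self.tef.items():
            if f < 0:
                raise ConfigurationError(f"TEF for PCB {n} must be >= 0, got {f}")

    def factor(self, congener: CongenerID) -> float:
        try:
            return self.tef[congener.iupac_number]
        except KeyError as exc:
            raise ConfigurationError(
                f"no TEF for PCB {congener.iupac_number} in scheme {self.name!r}"
            ) from exc


#: WHO-2005 factors for the 12 dl-PCBs (the scheme used throughout).
WHO_2005 = TEFScheme(
    name="WHO-2005",
    tef={
        77: 0.0001,
        81: 0.0003,
        126: 0.1,
        169: 0.03,
        105: 0.00003,
        114: 0.00003,
        118: 0.00003,
        123: 0.00003,
        156: 0.00003,
        157: 0.00003,
        167: 0.00003,
        189: 0.00003,
    },
)


class BoundStrategy(str, enum.Enum):
    """Substitution rule for censored (below-limit) values.

    ``lower`` substitutes 0, ``middle`` half the limit, ``upper`` the limit
    itself (LOD or LOQ depending on the censoring state).
    """

    LOWER = "lower"
    MIDDLE = "middle"
    UPPER = "upper"


def substitute_censored(m: CongenerMeasurement, bound: BoundStrategy) -> float:
    """Numeric value for a measurement under a censoring-bound strategy.

    Detected values pass through unchanged; censored values are replaced by
    0, limit/2, or the limit.  Units and basis are those of the measurement.
    """
    bound = BoundStrategy(bound)
    if m.censor is CensorState.DETECTED:
        return m.value
    limit = m.limit
    if limit is None:  # unreachable for validated measurements
        raise ValidationError(
            f"censored measurement for PCB {m.congener.iupac_number} lacks its limit"
        )
    if bound is BoundStrategy.LOWER:
        return 0.0
    if bound is BoundStrategy.MIDDLE:
        return limit / 2.0
    return limit


def convert_basis(
    value: float,
    from_basis: Basis,
    to_basis: Basis,
    lipid_pct: float | None = None,
) -> float:
    """Convert a concentration between wet-weight and lipid basis.

    Lipid-basis = wet-basis / (lipid_pct / 100).  Identity when the bases
    are equal.
    """
    from_basis, to_basis = Basis(from_basis), Basis(to_basis)
    if value < 0:
        raise ValidationError(f"concentration must be >= 0, got {value}")
    if from_basis is to_basis:
        return value
    if lipid_pct is None or not (0.0 < lipid_pct <= 100.0):
        raise DegenerateSampleError(
            f"basis conversion needs lipid_pct in (0, 100], got {lipid_pct!r}"
        )
    frac = lipid_pct / 100.0
    if to_basis is Basis.LIPID:
        return value / frac
    return value * frac


@dataclass(frozen=True)
class TEQResult:
    """A TEQ value with its per-congener breakdown (all pg-TEQ/g)."""

    teq: float
    basis: Basis
    bound: BoundStrategy
    per_congener: dict[int, float] = field(default_factory=dict)

    def top_contributors(self, k: int = 3) -> list[tuple[int, float]]:
        return sorted(self.per_congener.items(), key=lambda kv: -kv[1])[:k]


def _measurement_pg_per_g(
    m: CongenerMeasurement,
    bound: BoundStrategy,
    basis: Basis,
    lipid_pct: float,
) -> float:
    raw = substitute_censored(m, bound)
    pg = raw * (1000.0 if m.units is Units.NG_PER_G else 1.0)
    return convert_basis(pg, m.basis, basis, lipid_pct)


def compute_teq(
    sample: MilkSample,
    scheme: TEFScheme = WHO_2005,
    bound: BoundStrategy = BoundStrategy.UPPER,
    basis: Basis = Basis.WET_WEIGHT,
) -> TEQResult:
    """TEF-weighted toxic equivalent of a sample's dioxin-like congeners.

    Concentrations are normalized to pg/g on the requested basis before
    weighting.  Congeners absent from the sample contribute 0; under the
    upper-bound strategy a warning flags them since no limit is available
    for a conservative substitute.
    """
    bound, basis = BoundStrategy(bound), Basis(basis)
    lipid_pct = sample.composition.lipid_pct
    contributions: dict[int, float] = {}
    present = {m.congener.iupac_number for m in sample.measurements}
    for c in DL_CONGENERS:
        m = sample.measurement_for(c.iupac_number)
        if m is None:
            contributions[c.iupac_number] = 0.0
            continue
        conc = _measurement_pg_per_g(m, bound, basis, lipid_pct)
        contributions[c.iupac_number] = conc * scheme.factor(c)
    absent = sorted({c.iupac_number for c in DL_CONGENERS} - present)
    if absent and bound is BoundStrategy.UPPER:
        warnings.warn(
            f"sample {sample.sample_id!r}: dl congeners {absent} absent; they "
            "contribute 0 even under the upper bound (no limit available)",
            stacklevel=2,
        )
    return TEQResult(
        teq=sum(contributions.values()),
        basis=basis,
        bound=bound,
        per_congener=contributions,
    )


def sum_group(
    sample: MilkSample,
    group: CongenerGroup | str,
    bound: BoundStrategy = BoundStrategy.UPPER,
    basis: Basis = Basis.WET_WEIGHT,
    units: Units = Units.NG_PER_G,
) -> float:
    """Arithmetic sum of a congener group's concentrations in a sample.

    Returned in *units* on *basis*; congeners of the group that are absent
    from the sample contribute 0.
    """
    bound, basis, units = BoundStrategy(bound), Basis(basis), Units(units)
    lipid_pct = sample.composition.lipid_pct
    total_pg = 0.0
    for c in group_members(group):
        m = sample.measurement_for(c.iupac_number)
        if m is None:
            continue
        total_pg += _measurement_pg_per_g(m, bound, basis, lipid_pct)
    return total_pg / (1000.0 if units is Units.NG_PER_G else 1.0)
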