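"""Registry of the PCB congeners handled by the pipeline.

Three disjoint groups are tracked:

* ``non_ortho`` — the 4 non-ortho dioxin-like congeners (77, 81, 126, 169);
* ``mono_ortho`` — the 8 mono-ortho dioxin-like congeners
  (105, 114, 118, 123, 156, 157, 167, 189);
* ``ndl_indicator`` — the 6 non-dioxin-like marker congeners summed for
  regulatory purposes (28, 52, 101, 138, 153, 180).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "CongenerGroup",
    "CongenerID",
    "NON_ORTHO",
    "MONO_ORTHO",
    "NDL_INDICATORS",
    "DL_CONGENERS",
    "ALL_CONGENERS",
    "congener",
    "group_members",
]


class CongenerGroup(str, enum.Enum):
    NON_ORTHO = "non_ortho"
    MONO_ORTHO = "mono_ortho"
    NDL_INDICATOR = "ndl_indicator"


_GROUP_SETS: dict[CongenerGroup, frozenset[int]] = {
    CongenerGroup.NON_ORTHO: frozenset({77, 81, 126, 169}),
    CongenerGroup.MONO_ORTHO: frozenset({105, 114, 118, 123, 156, 157, 167, 189}),
    CongenerGroup.NDL_INDICATOR: frozenset({28, 52, 101, 138, 153, 180}),
}


@dataclass(frozen=True, order=True)
class CongenerID:
    """A PCB congener identified by IUPAC number, with its analysis group."""

    iupac_number: int
    group: CongenerGroup

    def __post_init__(self) -> None:
        if self.iupac_number <= 0:
            raise ValidationError(f"IUPAC number must be positive, got {self.iupac_number}")
        members = _GROUP_SETS[CongenerGroup(self.group)]
        if self.iupac_number not in members:
            raise ValidationError(
                f"PCB {self.iupac_number} is not a member of group {self.group!r}"
            )

    @property
    def is_dioxin_like(self) -> bool:
        return self.group in (CongenerGroup.NON_ORTHO, CongenerGroup.MONO_ORTHO)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"PCB {self.iupac_number}"


def _build_registry() -> dict[int, CongenerID]:
    reg: dict[int, CongenerID] = {}
    for grp, members in _GROUP_SETS.items():
        for n in sorted(members):
            reg[n] = CongenerID(n, grp)
    return reg


_REGISTRY: dict[int, CongenerID] = _build_registry()

NON_ORTHO: tuple[CongenerID, ...] = tuple(
    _REGISTRY[n] for n in sorted(_GROUP_SETS[CongenerGroup.NON_ORTHO])
)
MONO_ORTHO: tuple[CongenerID, ...] = tuple(
    _REGISTRY[n] for n in sorted(_GROUP_SETS[CongenerGroup.MONO_ORTHO])
)
NDL_INDICATORS: tuple[CongenerID, ...] = tuple(
    _REGISTRY[n] for n in sorted(_GROUP_SETS[CongenerGroup.NDL_INDICATOR])
)
DL_CONGENERS: tuple[CongenerID, ...] = NON_ORTHO + MONO_ORTHO
ALL_CONGENERS: tuple[CongenerID, ...] = NDL_INDICATORS + DL_CONGENERS


def congener(iupac_number: int) -> CongenerID:
    """Look up a congener by IUPAC number.

    Raises
    ------
    ValidationError
        If the number is not in the registry.
    """
    try:
        return _REGISTRY[int(iupac_number)]
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"Unknown PCB congener: {iupac_number!r}") from exc


def group_members(group: CongenerGroup | str) -> tuple[CongenerID, ...]:
    """All congeners belonging to *group*, sorted by IUPAC number."""
    grp = CongenerGroup(group)
    return tuple(_REGISTRY[n] for n in sorted(_GROUP_SETS[grp]))
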