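"""CSV interchange and run configuration.

The canonical interchange layout is a long-format CSV with one row per
(sample, congener):

    sample_id, mother_id, stage_days, lipid_pct, dry_matter_pct,
    protein_pct, lactose_pct, congener, value, basis, units, censor,
    lod, loq

A wide per-sample layout (one column per congener) is accepted through a
:class:`TableDialect`.  Profiles (mother + infant questionnaire records)
travel in a second CSV with ``ff_<food>`` frequency columns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .congeners import congener
from .datamodel import (
    Basis,
    CensorState,
    CongenerMeasurement,
    DEFAULT_SCHEDULE,
    FOOD_CATEGORIES,
    InfantProfile,
    MaternalProfile,
    MilkComposition,
    MilkSample,
    StageSchedule,
    Units,
)
from .errors import SchemaError, ValidationError

logger = logging.getLogger("lactoteq")

__all__ = [
    "TableDialect",
    "read_samples",
    "write_samples",
    "read_profiles",
    "write_profiles",
    "load_config",
    "config_digest",
]

_LONG_REQUIRED = (
    "sample_id",
    "mother_id",
    "stage_days",
    "lipid_pct",
    "dry_matter_pct",
    "protein_pct",
    "lactose_pct",
    "congener",
    "value",
    "basis",
    "units",
    "censor",
)


@dataclass(frozen=True)
class TableDialect:
    """Declares how a samples table is laid out.

    ``layout="long"`` (default) expects one row per (sample, congener).
    ``layout="wide"`` expects one row per sample with congener columns named
    ``<congener_prefix><iupac>``; wide values are taken as detected, with
    *wide_basis*/*wide_units* applying to every congener column.
    """

    layout: str = "long"
    rename: dict[str, str] = field(default_factory=dict)
    congener_prefix: str = "pcb_"
    wide_basis: Basis = Basis.LIPID
    wide_units: Units = Units.NG_PER_G

    def __post_init__(self) -> None:
        if self.layout not in ("long", "wide"):
            raise SchemaError(f"layout must be 'long' or 'wide', got {self.layout!r}")


def _require_columns(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _optional_float(row, key) -> float | None:
    if key not in row or pd.isna(row[key]):
        return None
    return float(row[key])


def _build_long_sample(
    sample_id: str,
    rows: pd.DataFrame,
    schedule: StageSchedule,
) -> MilkSample:
    first = rows.iloc[0]
    comp = MilkComposition(
        lipid_pct=float(first["lipid_pct"]),
        dry_matter_pct=float(first["dry_matter_pct"]),
        protein_pct=float(first["protein_pct"]),
        lactose_pct=float(first["lactose_pct"]),
    )
    measurements = []
    for _, row in rows.iterrows():
        value = float(row["value"])
        if value < 0:
            raise ValidationError(
                f"sample {sample_id!r}, PCB {row['congener']}: negative concentration {value}"
            )
        measurements.append(
            CongenerMeasurement(
                congener=congener(int(row["congener"])),
                value=value,
                basis=Basis(row["basis"]),
                units=Units(row["units"]),
                censor=CensorState(row["censor"]),
                lod=_optional_float(row, "lod"),
                loq=_optional_float(row, "loq"),
            )
        )
    return MilkSample(
        sample_id=str(sample_id),
        mother_id=str(first["mother_id"]),
        stage_days=int(first["stage_days"]),
        composition=comp,
        measurements=tuple(measurements),
        schedule=schedule,
    )


def read_samples(
    path,
    dialect: TableDialect = TableDialect(),
    schedule: StageSchedule = DEFAULT_SCHEDULE,
    on_error: str = "raise",
) -> list[MilkSample]:
    """Read and validate milk samples from a CSV file.

    ``on_error="raise"`` (default) aborts on the first invalid record;
    ``"skip"`` drops offending samples and logs a rejected count.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    df = pd.read_csv(path, float_precision="round_trip")
    if dialect.rename:
        df = df.rename(columns=dialect.rename)

    if dialect.layout == "wide":
        df = _wide_to_long(df, dialect, path)
    _require_columns(df, _LONG_REQUIRED, path)

    samples: list[MilkSample] = []
    rejected = 0
    for sample_id, rows in df.groupby("sample_id", sort=False):
        try:
            samples.append(_build_long_sample(sample_id, rows, schedule))
        except (ValidationError, ValueError) as exc:
            if on_error == "raise":
                first_row = int(rows.index[0]) + 2  # 1-based, plus header
                raise ValidationError(
                    f"{path}, rows near line {first_row}: {exc}"
                ) from exc
            rejected += 1
            logger.warning("rejected sample %r: %s", sample_id, exc)
    logger.info(
        "read %d rows from %s: %d samples, %d rejected", len(df), path, len(samples), rejected
    )
    return samples


def _wide_to_long(df: pd.DataFrame, dialect: TableDialect, path) -> pd.DataFrame:
    base_cols = [c for c in _LONG_REQUIRED if c not in
                 ("congener", "value", "basis", "units", "censor")]
    _require_columns(df, base_cols, path)
    congener_cols = [c for c in df.columns if c.startswith(dialect.congener_prefix)]
    if not congener_cols:
        raise SchemaError(
            f"{path}: wide layout but no columns start with {dialect.congener_prefix!r}"
        )
    long = df.melt(
        id_vars=base_cols, value_vars=congener_cols, var_name="congener", value_name="value"
    ).dropna(subset=["value"])
    long["congener"] = long["congener"].str.removeprefix(dialect.congener_prefix).astype(int)
    long["basis"] = dialect.wide_basis.value
    long["units"] = dialect.wide_units.value
    long["censor"] = CensorState.DETECTED.value
    return long


def write_samples(samples: Iterable[MilkSample], path) -> None:
    """Write samples in the canonical long-format CSV."""
    records = []
    for s in samples:
        for m in s.measurements:
            records.append(
                {
                    "sample_id": s.sample_id,
                    "mother_id": s.mother_id,
                    "stage_days": s.stage_days,
                    "stage_label": s.stage_label,
                    "lipid_pct": s.composition.lipid_pct,
                    "dry_matter_pct": s.composition.dry_matter_pct,
                    "protein_pct": s.composition.protein_pct,
                    "lactose_pct": s.composition.lactose_pct,
                    "congener": m.congener.iupac_number,
                    "value": m.value,
                    "basis": m.basis.value,
                    "units": m.units.value,
                    "censor": m.censor.value,
                    "lod": m.lod,
                    "loq": m.loq,
                }
            )
    # %.17g round-trips float64 exactly
    pd.DataFrame.from_records(records).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def write_profiles(
    mothers: Iterable[MaternalProfile],
    infants: Iterable[InfantProfile],
    path,
) -> None:
    infant_by_mother = {i.mother_id: i for i in infants}
    records = []
    for m in mothers:
        rec = {
            "mother_id": m.mother_id,
            "age_band": m.age_band,
            "weight_before_band": m.weight_before_band,
            "weight_after_band": m.weight_after_band,
            "residence": m.residence,
            "education": m.education,
            "parity": m.parity,
            "delivery": m.delivery,
            "smoking": m.smoking,
        }
        inf = infant_by_mother.get(m.mother_id)
        rec["infant_sex"] = inf.sex if inf else None
        rec["infant_birth_weight_kg"] = inf.birth_weight_kg if inf else None
        for food in FOOD_CATEGORIES:
            rec[f"ff_{food}"] = m.food_frequency.get(food)
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_profiles(path) -> tuple[list[MaternalProfile], list[InfantProfile]]:
    df = pd.read_csv(path)
    required = (
        "mother_id", "age_band", "weight_before_band", "weight_after_band",
        "residence", "education", "parity", "delivery", "smoking",
    )
    _require_columns(df, required, path)
    mothers, infants = [], []
    for _, row in df.iterrows():
        food = {}
        for food_cat in FOOD_CATEGORIES:
            col = f"ff_{food_cat}"
            if col in df.columns and not pd.isna(row[col]):
                food[food_cat] = str(row[col])
        mothers.append(
            MaternalProfile(
                mother_id=str(row["mother_id"]),
                age_band=str(row["age_band"]),
                weight_before_band=str(row["weight_before_band"]),
                weight_after_band=str(row["weight_after_band"]),
                residence=str(row["residence"]),
                education=str(row["education"]),
                parity=int(row["parity"]),
                delivery=str(row["delivery"]),
                smoking=str(row["smoking"]),
                food_frequency=food,
            )
        )
        if "infant_sex" in df.columns and not pd.isna(row["infant_sex"]):
            infants.append(
                InfantProfile(
                    mother_id=str(row["mother_id"]),
                    sex=str(row["infant_sex"]),
                    birth_weight_kg=float(row["infant_birth_weight_kg"]),
                )
            )
    return mothers, infants


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a nested key-value run configuration (YAML)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping at top level")
    return cfg


def config_digest(cfg: dict) -> str:
    """Stable short digest of a configuration for run logs."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
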