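"""Seeded generator of synthetic mother/infant/milk datasets.

The raw cohort behind the published stage summaries is unavailable, so this
module fabricates datasets with the statistical structure the downstream
analysis assumes:

* log-normal congener concentrations with exponential decline over lactation
  (negative per-day slope on the log scale), between-mother random effects,
  and within-sample noise;
* milk composition with declining lipid/protein and a dry-matter balance;
* questionnaire covariates drawn from the study's marginal frequencies, with
  configurable multiplicative effects (fish consumption, smoking, urban
  residence) on selected congeners;
* censoring below a configurable wet-weight LOD.

Monthly collections are modelled as the mean of four weekly replicate draws,
mirroring the stated sampling protocol, so their within-sample noise variance
is a quarter of the weekly one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .congeners import ALL_CONGENERS, congener
from .datamodel import (
    Basis,
    CensorState,
    CongenerMeasurement,
    DEFAULT_SCHEDULE,
    FOOD_CATEGORIES,
    FREQUENCY_CODES,
    InfantProfile,
    MaternalProfile,
    MilkComposition,
    MilkSample,
    StageSchedule,
    Units,
)
from .errors import ConfigurationError

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "generate",
    "implied_lactation_r",
    "covariate_codes",
]

#: day-7 lipid-basis geometric mean (ng/g lipid) and per-day log-scale slope
_DEFAULT_BASELINE: dict[int, float] = {
    28: 3.2, 52: 2.8, 101: 2.4, 138: 3.9, 153: 4.6, 180: 2.9,
    77: 0.7, 81: 0.5, 126: 0.9, 169: 1.7,
    105: 1.8, 114: 1.2, 118: 4.5, 123: 0.8,
    156: 2.2, 157: 1.3, 167: 1.1, 189: 1.9,
}
_DEFAULT_DECLINE: dict[int, float] = {
    28: -0.0105, 52: -0.0115, 101: -0.0095, 138: -0.0100, 153: -0.0090, 180: -0.0100,
    77: -0.0090, 81: -0.0095, 126: -0.0100, 169: -0.0105,
    105: -0.0110, 114: -0.0105, 118: -0.0100, 123: -0.0105,
    156: -0.0110, 157: -0.0110, 167: -0.0105, 189: -0.0115,
}

#: positive fish effects on 77/81/118/189, smoking on 156/118/189,
#: urban residence on 123/167 (log-scale coefficients per code unit)
_DEFAULT_EFFECTS: dict[tuple[str, int], float] = {
    ("fish", 77): 0.35, ("fish", 81): 0.35, ("fish", 118): 0.30, ("fish", 189): 0.30,
    ("smoking", 156): 0.40, ("smoking", 118): 0.30, ("smoking", 189): 0.30,
    ("city", 123): 0.40, ("city", 167): 0.40,
}

_NON_FOOD_COVARIATES = ("smoking", "city", "parity")

# marginal frequencies from the study questionnaire
_AGE_P = {"<18": 0.042, "18-22": 0.0, "23-27": 0.25, "28-32": 0.375, "33-36": 0.333}
_WBEFORE_P = {"<55": 0.25, "56-60": 0.125, "61-65": 0.208, ">65": 0.417}
_WAFTER_P = {"55-60": 0.208, "61-65": 0.208, "66-70": 0.25, ">70": 0.334}
_RESIDENCE_P = {"city_gt_5000": 0.833, "town_lt_5000": 0.042, "country": 0.125}
_EDUCATION_P = {"primary": 0.042, "secondary": 0.0, "higher": 0.958}
_SMOKING_P = {
    "never": 0.75,
    "quit_before_pregnancy": 0.167,
    "up_to_one_pack": 0.042,
    "more_than_one_pack": 0.042,
}
_BW_BAND_P = {"2.4-2.8": 0.042, "2.9-3.2": 0.458, "3.3-3.6": 0.458, "3.7-4.0": 0.0, ">4.0": 0.042}
_BW_BAND_RANGE = {
    "2.4-2.8": (2.4, 2.8),
    "2.9-3.2": (2.9, 3.2),
    "3.3-3.6": (3.3, 3.6),
    "3.7-4.0": (3.7, 4.0),
    ">4.0": (4.0, 4.4),
}
_MALE_FRACTION = 0.625

#: food-frequency marginals over (never, rarely, weekly, twice_weekly_plus, daily)
_FOOD_P: dict[str, tuple[float, ...]] = {
    "fish": (0.041, 0.30, 0.40, 0.20, 0.059),
    "dairy": (0.0, 0.05, 0.15, 0.30, 0.50),
    "beef": (0.05, 0.25, 0.40, 0.25, 0.05),
    "pork": (0.05, 0.20, 0.40, 0.30, 0.05),
    "poultry": (0.0, 0.05, 0.25, 0.70, 0.0),
    "eggs": (0.02, 0.13, 0.35, 0.35, 0.15),
    "vegetables": (0.0, 0.02, 0.08, 0.10, 0.80),
    "fruit": (0.0, 0.05, 0.10, 0.15, 0.70),
    "whole_grains": (0.15, 0.50, 0.208, 0.042, 0.10),
    "wheat_rye_bread": (0.05, 0.15, 0.25, 0.25, 0.30),
}


@dataclass(frozen=True)
class CompositionTrends:
    """Linear stage trends for milk macro-composition (percent scales)."""

    lipid_day7: float = 4.60
    lipid_final: float = 2.37
    protein_day7: float = 1.49
    protein_final: float = 0.84
    lactose_week1: float = 5.33
    lactose_day7: float = 7.27
    lactose_slope: float = -0.001
    final_day: float = 400.0
    lipid_sd: float = 0.45
    protein_sd: float = 0.08
    lactose_sd: float = 0.30


@dataclass(frozen=True)
class GeneratorConfig:
    n_mothers: int = 96
    seed: int = 0
    schedule: StageSchedule = DEFAULT_SCHEDULE
    baseline: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_BASELINE))
    decline: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_DECLINE))
    mother_sd: float = 0.30
    noise_sd: float = 0.25
    covariate_effects: dict[tuple[str, int], float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS)
    )
    censor_at_lod: bool = True
    lod_ng_per_g_ww: float = 0.0001
    dropout_p: float = 0.0
    composition: CompositionTrends = CompositionTrends()

    def __post_init__(self) -> None:
        for n, b in self.baseline.items():
            congener(n)  # raises for unknown numbers
            if b <= 0:
                raise ConfigurationError(f"baseline for PCB {n} must be > 0, got {b}")
        for n in self.decline:
            congener(n)
        valid_covs = set(FOOD_CATEGORIES) | set(_NON_FOOD_COVARIATES)
        for (cov, n) in self.covariate_effects:
            if cov not in valid_covs:
                raise ConfigurationError(f"unknown covariate {cov!r} in covariate_effects")
            congener(n)
        if not (0.0 <= self.dropout_p < 1.0):
            raise ConfigurationError("dropout_p must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticDataset:
    mothers: tuple[MaternalProfile, ...]
    infants: tuple[InfantProfile, ...]
    samples: tuple[MilkSample, ...]
    truth: GeneratorConfig


def covariate_codes(profile: MaternalProfile) -> dict[str, float]:
    """Numeric codes used by the generator's covariate effects.

    Food categories map to their ordinal frequency code (0-4), ``smoking``
    to its ordinal level (0-3), ``city`` to a 0/1 urban-residence flag, and
    ``parity`` to the birth count.
    """
    codes: dict[str, float] = {
        food: float(FREQUENCY_CODES.index(profile.food_frequency[food]))
        for food in profile.food_frequency
    }
    codes["smoking"] = float(
        ("never", "quit_before_pregnancy", "up_to_one_pack", "more_than_one_pack").index(
            profile.smoking
        )
    )
    codes["city"] = 1.0 if profile.residence == "city_gt_5000" else 0.0
    codes["parity"] = float(profile.parity)
    return codes


def _pick(rng: np.random.Generator, table: dict[str, float]) -> str:
    keys = list(table)
    p = np.array([table[k] for k in keys], dtype=float)
    p = p / p.sum()
    return keys[int(rng.choice(len(keys), p=p))]


def _draw_mother(rng: np.random.Generator, idx: int) -> tuple[MaternalProfile, InfantProfile]:
    mid = f"M{idx:03d}"
    food = {
        cat: FREQUENCY_CODES[int(rng.choice(5, p=np.array(_FOOD_P[cat]) / sum(_FOOD_P[cat])))]
        for cat in FOOD_CATEGORIES
    }
    parity = 1 if rng.random() < 0.625 else int(rng.choice([2, 3]))
    mother = MaternalProfile(
        mother_id=mid,
        age_band=_pick(rng, _AGE_P),
        weight_before_band=_pick(rng, _WBEFORE_P),
        weight_after_band=_pick(rng, _WAFTER_P),
        residence=_pick(rng, _RESIDENCE_P),
        education=_pick(rng, _EDUCATION_P),
        parity=parity,
        delivery="natural" if rng.random() < 0.5 else "c_section",
        smoking=_pick(rng, _SMOKING_P),
        food_frequency=food,
    )
    band = _pick(rng, _BW_BAND_P)
    lo, hi = _BW_BAND_RANGE[band]
    infant = InfantProfile(
        mother_id=mid,
        sex="male" if rng.random() < _MALE_FRACTION else "female",
        birth_weight_kg=float(round(rng.uniform(lo, hi), 2)),
    )
    return mother, infant


def _composition_at(rng: np.random.Generator, day: int, ct: CompositionTrends) -> MilkComposition:
    span = ct.final_day - 7.0
    t = (day - 7.0) / span
    lipid = ct.lipid_day7 + (ct.lipid_final - ct.lipid_day7) * t + rng.normal(0, ct.lipid_sd)
    protein = (
        ct.protein_day7 + (ct.protein_final - ct.protein_day7) * t + rng.normal(0, ct.protein_sd)
    )
    if day < 7:
        lactose = ct.lactose_week1 + rng.normal(0, ct.lactose_sd)
    else:
        lactose = ct.lactose_day7 + ct.lactose_slope * (day - 7) + rng.normal(0, ct.lactose_sd)
    lipid = float(np.clip(lipid, 0.8, 8.0))
    protein = float(np.clip(protein, 0.3, 3.0))
    lactose = float(np.clip(lactose, 3.0, 9.0))
    residual = max(0.1, 1.0 + rng.normal(0, 0.2))
    dry = min(100.0, lipid + protein + lactose + residual)
    return MilkComposition(
        lipid_pct=lipid, dry_matter_pct=dry, protein_pct=protein, lactose_pct=lactose
    )


def generate(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate a fully deterministic synthetic dataset from *config*.

    The same config (including seed) always produces an identical dataset.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    schedule = cfg.schedule
    labels = schedule.labels
    weekly_labels = set(labels[:5])  # single-draw collections; the rest average 4

    mothers: list[MaternalProfile] = []
    infants: list[InfantProfile] = []
    for i in range(cfg.n_mothers):
        m, inf = _draw_mother(rng, i)
        mothers.append(m)
        infants.append(inf)

    loq_ww = cfg.lod_ng_per_g_ww * (10.0 / 3.3)
    samples: list[MilkSample] = []
    for m in mothers:
        codes = covariate_codes(m)
        mother_effect = {
            n: rng.normal(0.0, cfg.mother_sd) for n in cfg.baseline
        }
        for si, label in enumerate(labels):
            if cfg.dropout_p > 0 and rng.random() < cfg.dropout_p:
                continue
            day = schedule.representative_day(label)
            comp = _composition_at(rng, day, cfg.composition)
            lipid_frac = comp.lipid_fraction
            measurements: list[CongenerMeasurement] = []
            for n, base in cfg.baseline.items():
                slope = cfg.decline.get(n, 0.0)
                mu = math.log(base) + slope * (day - 7)
                for (cov, cn), beta in cfg.covariate_effects.items():
                    if cn == n:
                        mu += beta * codes[cov]
                mu += mother_effect[n]
                n_draws = 1 if label in weekly_labels else 4
                eps = float(np.mean(rng.normal(0.0, cfg.noise_sd, size=n_draws)))
                conc_lipid = math.exp(mu + eps)  # ng/g lipid
                conc_ww = conc_lipid * lipid_frac
                lod_lipid = cfg.lod_ng_per_g_ww / lipid_frac
                loq_lipid = loq_ww / lipid_frac
                if cfg.censor_at_lod and conc_ww < cfg.lod_ng_per_g_ww:
                    measurements.append(
                        CongenerMeasurement(
                            congener=congener(n),
                            value=lod_lipid,
                            basis=Basis.LIPID,
                            units=Units.NG_PER_G,
                            censor=CensorState.BELOW_LOD,
                            lod=lod_lipid,
                            loq=loq_lipid,
                        )
                    )
                else:
                    measurements.append(
                        CongenerMeasurement(
                            congener=congener(n),
                            value=conc_lipid,
                            basis=Basis.LIPID,
                            units=Units.NG_PER_G,
                            censor=CensorState.DETECTED,
                            lod=lod_lipid,
                            loq=loq_lipid,
                        )
                    )
            samples.append(
                MilkSample(
                    sample_id=f"{m.mother_id}-S{si:02d}",
                    mother_id=m.mother_id,
                    stage_days=day,
                    composition=comp,
                    measurements=tuple(measurements),
                    schedule=schedule,
                )
            )

    return SyntheticDataset(
        mothers=tuple(mothers),
        infants=tuple(infants),
        samples=tuple(samples),
        truth=cfg,
    )


def _code_variance(cov: str) -> float:
    """Population variance of a covariate code under the sampling marginals."""
    if cov == "city":
        p = _RESIDENCE_P["city_gt_5000"] / sum(_RESIDENCE_P.values())
        return p * (1 - p)
    if cov == "smoking":
        p = np.array(list(_SMOKING_P.values()))
        p = p / p.sum()
        codes = np.arange(len(p), dtype=float)
    elif cov == "parity":
        # 1 w.p. 0.625, else uniform on {2, 3}
        p = np.array([0.625, 0.1875, 0.1875])
        codes = np.array([1.0, 2.0, 3.0])
    else:
        p = np.array(_FOOD_P[cov], dtype=float)
        p = p / p.sum()
        codes = np.arange(len(p), dtype=float)
    mean = float(np.dot(p, codes))
    return float(np.dot(p, (codes - mean) ** 2))


def implied_lactation_r(config: GeneratorConfig, iupac_number: int) -> float:
    """Closed-form correlation between days and log concentration.

    Under the generative model the log lipid-basis concentration is linear
    in days with independent mother, covariate, and noise terms, so

        r = slope * sd(days) / sqrt(slope^2 var(days) + var(other terms))

    where var(days) is taken over the (equally weighted) schedule days and
    the noise variance accounts for monthly 4-replicate averaging.
    """
    labels = config.schedule.labels
    days = np.array([config.schedule.representative_day(lb) for lb in labels], dtype=float)
    var_d = float(days.var())
    slope = config.decline.get(iupac_number, 0.0)

    noise_vars = [
        config.noise_sd**2 if i < 5 else config.noise_sd**2 / 4.0 for i in range(len(labels))
    ]
    var_noise = float(np.mean(noise_vars))
    var_cov = sum(
        beta**2 * _code_variance(cov)
        for (cov, n), beta in config.covariate_effects.items()
        if n == iupac_number
    )
    total = slope**2 * var_d + config.mother_sd**2 + var_noise + var_cov
    return slope * math.sqrt(var_d) / math.sqrt(total)


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """A copy of *config* with a different seed."""
    return replace(config, seed=seed)
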