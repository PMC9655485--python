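"""Stage-wise summaries, Pearson correlation with Guilford interpretation,
and the standard group-comparison battery (ANOVA, Levene, K-S, Tukey HSD).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .congeners import CongenerGroup
from .datamodel import Basis, MilkSample, Units
from .errors import DomainError
from .teq import BoundStrategy, substitute_censored, sum_group, convert_basis

__all__ = [
    "StageSummary",
    "summarize_stage",
    "grand_summary",
    "coefficient_of_variation",
    "CorrelationResult",
    "guilford_class",
    "correlate",
    "StageTestReport",
    "stage_group_tests",
    "quantity_selector",
    "lactation_trend",
]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageSummary:
    """Per-stage descriptive summary: n, mean, SD (n-1), CV in percent."""

    stage_label: str
    n: int
    mean: float
    sd: float
    cv: float


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV as a percentage, 100 * sd / mean; requires mean > 0."""
    if mean <= 0:
        raise DomainError(f"CV undefined for mean <= 0 (got {mean})")
    return 100.0 * sd / mean


def summarize_stage(values: Sequence[float], stage_label: str) -> StageSummary:
    """Mean, sample SD and CV of one stage's values.

    SD uses the n-1 denominator (0 for a single value).  CV is 0 for a
    constant vector and undefined (error) when the mean is not positive.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError(f"stage {stage_label!r}: empty value set")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    cv = 0.0 if sd == 0.0 else coefficient_of_variation(mean, sd)
    return StageSummary(stage_label=stage_label, n=int(arr.size), mean=mean, sd=sd, cv=cv)


def grand_summary(
    stage_means: Sequence[float],
    n_expected: int = 17,
    allow_partial: bool = False,
) -> tuple[float, float]:
    """Unweighted mean and sample SD across the per-stage means.

    The schedule has 17 stages; a different count is an error unless
    *allow_partial* is set.
    """
    arr = np.asarray(stage_means, dtype=float)
    if arr.size != n_expected and not allow_partial:
        raise DomainError(
            f"expected {n_expected} stage means, got {arr.size} "
            "(pass allow_partial=True to override)"
        )
    if arr.size < 2:
        raise DomainError("need at least 2 stage means")
    return float(arr.mean()), float(arr.std(ddof=1))


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

#: Guilford interpretation bands for |r|, lower edge inclusive.
_GUILFORD_BANDS = (
    (0.9, "very high"),
    (0.7, "high"),
    (0.4, "moderate"),
    (0.2, "low"),
    (0.0, "negligible"),
)


def guilford_class(r: float) -> str:
    """Qualitative strength label for a correlation coefficient."""
    a = abs(r)
    if a > 1 + 1e-12:
        raise DomainError(f"|r| must be <= 1, got {r}")
    for lower, label in _GUILFORD_BANDS:
        if a >= lower:
            return label
    return "negligible"  # pragma: no cover


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float
    guilford_class: str
    direction: str  # "positive" | "negative"


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-sided p-value and Guilford label.

    Requires n >= 3 finite pairs and nonzero variance in both vectors.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise DomainError("x and y must be 1-D vectors of equal length")
    if xa.size < 3:
        raise DomainError(f"correlation needs n >= 3, got {xa.size}")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise DomainError("correlation inputs must be finite")
    if xa.std() == 0 or ya.std() == 0:
        raise DomainError("correlation undefined: zero variance in an input")
    res = sps.pearsonr(xa, ya)
    r = float(res.statistic)
    return CorrelationResult(
        r=r,
        n=int(xa.size),
        p_value=float(res.pvalue),
        guilford_class=guilford_class(r),
        direction="negative" if r < 0 else "positive",
    )


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageTestReport:
    """One-way ANOVA with its assumption checks and Tukey HSD table."""

    anova_f: float
    anova_p: float
    levene_stat: float
    levene_p: float
    ks_normality_p: dict[str, float]
    tukey: pd.DataFrame
    alpha: float = 0.05
    excluded: tuple[str, ...] = ()
    #: K-S p-values use moment-estimated parameters and are approximate
    ks_approximate: bool = True


def stage_group_tests(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> StageTestReport:
    """ANOVA + Levene + per-group K-S normality + Tukey HSD across stages.

    Groups with fewer than 2 observations are excluded with a warning.
    """
    usable: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            excluded.append(label)
            warnings.warn(f"group {label!r} has n < 2; excluded from tests", stacklevel=2)
            continue
        usable[label] = arr
    if len(usable) < 2:
        raise DomainError("need at least 2 groups with n >= 2")

    arrays = list(usable.values())
    f_stat, f_p = sps.f_oneway(*arrays)
    lev_stat, lev_p = sps.levene(*arrays)

    ks_p: dict[str, float] = {}
    for label, arr in usable.items():
        sd = arr.std(ddof=1)
        if sd == 0:
            ks_p[label] = 0.0
        else:
            ks_p[label] = float(sps.kstest(arr, "norm", args=(arr.mean(), sd)).pvalue)

    values = np.concatenate(arrays)
    labels = np.concatenate([[lab] * a.size for lab, a in usable.items()])
    hsd = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairs = list(itertools.combinations(range(len(hsd.groupsunique)), 2))
    tukey = pd.DataFrame(
        {
            "group1": [hsd.groupsunique[i] for i, _ in pairs],
            "group2": [hsd.groupsunique[j] for _, j in pairs],
            "meandiff": hsd.meandiffs,
            "p_adj": hsd.pvalues,
            "lower": hsd.confint[:, 0],
            "upper": hsd.confint[:, 1],
            "reject": hsd.reject,
        }
    )
    return StageTestReport(
        anova_f=float(f_stat),
        anova_p=float(f_p),
        levene_stat=float(lev_stat),
        levene_p=float(lev_p),
        ks_normality_p=ks_p,
        tukey=tukey,
        alpha=alpha,
        excluded=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# lactation trends
# ---------------------------------------------------------------------------

def quantity_selector(
    quantity,
    basis: Basis = Basis.LIPID,
    bound: BoundStrategy = BoundStrategy.MIDDLE,
    units: Units = Units.NG_PER_G,
) -> Callable[[MilkSample], float]:
    """Build a per-sample scalar extractor.

    *quantity* may be an IUPAC number (congener concentration), a
    :class:`CongenerGroup` or its name (group sum), a composition field name
    such as ``"lipid_pct"``, or any callable taking a sample.
    """
    if callable(quantity):
        return quantity
    if isinstance(quantity, int):
        def get_congener(s: MilkSample) -> float:
            m = s.measurement_for(quantity)
            if m is None:
                return math.nan
            raw = substitute_censored(m, bound)
            pg = raw * (1000.0 if m.units is Units.NG_PER_G else 1.0)
            pg = convert_basis(pg, m.basis, basis, s.composition.lipid_pct)
            return pg / (1000.0 if units is Units.NG_PER_G else 1.0)
        return get_congener
    if isinstance(quantity, CongenerGroup) or (
        isinstance(quantity, str) and quantity in CongenerGroup._value2member_map_
    ):
        grp = CongenerGroup(quantity)
        return lambda s: sum_group(s, grp, bound=bound, basis=basis, units=units)
    if isinstance(quantity, str):
        def get_field(s: MilkSample) -> float:
            try:
                return float(getattr(s.composition, quantity))
            except AttributeError as exc:
                raise DomainError(f"unknown quantity {quantity!r}") from exc
        return get_field
    raise DomainError(f"cannot interpret quantity {quantity!r}")


def lactation_trend(
    samples: Iterable[MilkSample],
    quantity,
    log: bool = False,
    **selector_kwargs,
) -> CorrelationResult:
    """Correlation between days postpartum and a per-sample quantity.

    With ``log=True`` the quantity is log-transformed (strictly positive
    values required), which matches multiplicative decline models.
    """
    select = quantity_selector(quantity, **selector_kwargs)
    days: list[float] = []
    vals: list[float] = []
    for s in samples:
        v = select(s)
        if math.isnan(v):
            continue
        if log:
            if v <= 0:
                continue
            v = math.log(v)
        days.append(float(s.stage_days))
        vals.append(v)
    return correlate(days, vals)
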