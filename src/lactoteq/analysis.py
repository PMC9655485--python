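"""Frame builders bridging the object model and matrix-based analyses."""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import Basis, MaternalProfile, MilkSample, Units
from .simulate import covariate_codes
from .stats import quantity_selector
from .teq import BoundStrategy

__all__ = ["congener_matrix", "covariate_frame"]


def congener_matrix(
    samples: Sequence[MilkSample],
    congeners: Iterable[int],
    basis: Basis = Basis.LIPID,
    bound: BoundStrategy = BoundStrategy.MIDDLE,
    log: bool = False,
) -> pd.DataFrame:
    """Samples x congeners concentration matrix (ng/g on *basis*).

    With ``log=True`` values are natural-log transformed; non-positive
    values become NaN.  Row index is sample_id.
    """
    congeners = list(congeners)
    selectors = {
        n: quantity_selector(n, basis=basis, bound=bound, units=Units.NG_PER_G)
        for n in congeners
    }
    data = {}
    for n, sel in selectors.items():
        col = np.array([sel(s) for s in samples], dtype=float)
        if log:
            col = np.where(col > 0, np.log(np.where(col > 0, col, 1.0)), math.nan)
        data[f"PCB{n}"] = col
    return pd.DataFrame(data, index=[s.sample_id for s in samples])


def covariate_frame(
    samples: Sequence[MilkSample],
    mothers: Sequence[MaternalProfile],
    covariates: Sequence[str] = ("stage_days", "fish", "smoking", "city", "parity"),
) -> pd.DataFrame:
    """Per-sample explanatory frame with numeric covariate codes.

    ``stage_days`` and ``lipid_pct``/``dry_matter_pct``/... come from the
    sample; any other name is resolved through the mother's questionnaire
    codes (food frequencies, smoking level, urban residence, parity).
    """
    by_mother = {m.mother_id: covariate_codes(m) for m in mothers}
    rows = []
    for s in samples:
        codes = by_mother[s.mother_id]
        row = {}
        for cov in covariates:
            if cov == "stage_days":
                row[cov] = float(s.stage_days)
            elif cov.endswith("_pct"):
                row[cov] = float(getattr(s.composition, cov))
            else:
                row[cov] = codes[cov]
        rows.append(row)
    return pd.DataFrame(rows, index=[s.sample_id for s in samples])
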