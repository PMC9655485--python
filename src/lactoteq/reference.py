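"""Published per-stage reference summaries for the three congener group sums.

These are the stage-wise mean +/- SD (ng/g lipid) and CV values reported by
the source monitoring study across its 17-point collection schedule.  They
serve as a packaged fixture: the per-mother raw data are not public, but
the stage summaries are, and several pipeline quantities (grand means,
CVs) can be recomputed from them.
"""

from __future__ import annotations

from .stats import StageSummary

__all__ = ["reference_stage_summaries", "REFERENCE_GROUPS"]

REFERENCE_GROUPS = ("ndl_indicator", "non_ortho", "mono_ortho")

# stage label, n, (ndl mean, sd, cv), (non-ortho mean, sd, cv), (mono-ortho mean, sd, cv)
_ROWS: tuple[tuple[str, int, tuple, tuple, tuple], ...] = (
    ("<7 days", 17, (16.63, 1.37, 8.24), (1.71, 0.23, 13.31), (7.84, 0.75, 9.52)),
    ("7 days", 26, (19.83, 1.26, 6.35), (3.81, 0.50, 13.15), (14.85, 1.19, 8.01)),
    ("14 days", 59, (20.31, 1.36, 6.70), (3.04, 0.44, 14.52), (12.19, 1.04, 8.53)),
    ("21 days", 98, (17.94, 1.10, 6.13), (2.45, 0.32, 13.00), (9.85, 0.83, 8.43)),
    ("28 days", 39, (14.49, 0.74, 5.11), (2.37, 0.22, 9.12), (8.56, 0.94, 10.98)),
    ("2 months", 75, (15.90, 1.25, 7.86), (2.06, 0.20, 9.81), (8.99, 0.74, 8.26)),
    ("3 months", 75, (15.24, 1.14, 7.48), (1.65, 0.15, 9.02), (7.02, 0.61, 8.65)),
    ("4 months", 92, (15.22, 1.14, 7.49), (1.47, 0.18, 12.22), (6.21, 0.65, 10.44)),
    ("5 months", 88, (12.83, 0.97, 7.56), (1.39, 0.19, 13.54), (5.23, 0.55, 10.43)),
    ("6 months", 88, (10.82, 0.89, 8.23), (1.36, 0.09, 6.72), (3.37, 0.42, 12.42)),
    ("7 months", 69, (15.39, 1.46, 9.49), (1.25, 0.07, 5.77), (4.23, 0.38, 8.95)),
    ("8 months", 39, (15.71, 1.32, 8.40), (1.16, 0.10, 8.89), (3.55, 0.43, 12.04)),
    ("9 months", 29, (13.81, 1.28, 9.27), (1.15, 0.12, 10.49), (2.85, 0.37, 12.84)),
    ("10 months", 29, (11.63, 0.88, 7.57), (0.74, 0.12, 16.02), (2.35, 0.27, 11.54)),
    ("11 months", 29, (10.48, 0.72, 6.87), (0.42, 0.06, 14.89), (1.76, 0.22, 12.75)),
    ("12 months", 29, (7.75, 0.54, 7.00), (0.15, 0.03, 18.82), (1.02, 0.17, 17.12)),
    (">1 year of feeding", 39, (0.343, 0.035, 10.20), (0.14, 0.05, 32.16), (0.21, 0.04, 17.45)),
)

_GROUP_SLOT = {"ndl_indicator": 2, "non_ortho": 3, "mono_ortho": 4}


def reference_stage_summaries(group: str = "ndl_indicator") -> list[StageSummary]:
    """The 17 published (stage, n, mean, sd, cv) rows for one group sum.

    *group* is one of ``ndl_indicator``, ``non_ortho``, ``mono_ortho``.
    Values are as printed (ng/g lipid; CV in percent).
    """
    if group not in _GROUP_SLOT:
        raise KeyError(f"group must be one of {REFERENCE_GROUPS}, got {group!r}")
    slot = _GROUP_SLOT[group]
    out = []
    for row in _ROWS:
        mean, sd, cv = row[slot]
        out.append(StageSummary(stage_label=row[0], n=row[1], mean=mean, sd=sd, cv=cv))
    return out
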