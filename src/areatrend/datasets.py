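"""Published national-level aggregates used as worked-example inputs.

Per 5-year period, the national number of incident AMIs and of deaths
within 28 days in Denmark, 1987-2016, as published at the study's national
level.  These are inputs for the descriptive arithmetic (period mortality
percentages and grand totals); the municipality-level registry data behind
the spatial models are not publicly available, which is exactly what the
synthetic-data generator replaces.
"""

from __future__ import annotations

import numpy as np

from .panel import ArealPanel

#: Period labels for the six 5-year windows.
PERIODS: tuple[str, ...] = (
    "1987-1991",
    "1992-1996",
    "1997-2001",
    "2002-2006",
    "2007-2011",
    "2012-2016",
)

#: National incident AMI counts per period.
NATIONAL_CASES: tuple[int, ...] = (85_146, 69_906, 58_408, 59_454, 50_601, 45_324)

#: National deaths within 28 days per period.
NATIONAL_DEATHS: tuple[int, ...] = (39_518, 29_236, 20_592, 17_342, 13_163, 9_106)


def national_panel() -> ArealPanel:
    """The national totals as a one-unit panel (no covariates).

    Treating the whole country as a single areal unit lets the period
    aggregation reproduce the published mortality percentages directly.
    """
    y = np.array([NATIONAL_DEATHS], dtype=np.int64)
    n = np.array([NATIONAL_CASES], dtype=np.int64)
    return ArealPanel(("Denmark",), PERIODS, y, n, {})
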