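"""Published summary statistics from a large cross-sectional adolescent cohort.

A survey of 6,666 urban Chinese middle- and high-school students reported
geometric means of the five 24-hour activity behaviors, a pairwise
log-ratio variation matrix, per-component pivot regression coefficients
against PHQ-9 depression scores, and the depression-severity distribution.
Those printed summaries are reproduced here verbatim: they serve as the
defaults of the synthetic-cohort generator and as the inputs of the
external-coefficients workflow (reconstructing substitution effects from a
published pivot table when the raw data are unavailable).

All compositions use the canonical part order (mvpa, lpa, nsst, slp, st).
"""

from __future__ import annotations

import numpy as np

#: Canonical part order used by the pivot (sequential-binary-partition) basis.
PARTS: tuple[str, ...] = ("mvpa", "lpa", "nsst", "slp", "st")

#: Minutes in a day; the closure total of every composition.
DAY_MINUTES: float = 1440.0

#: Published geometric means of daily minutes, canonical order.
#: They sum to exactly 1440.00.
GEOMETRIC_MEAN_MINUTES = np.array([44.11, 32.02, 385.04, 658.24, 320.59])

#: Published shares of the day (%), same order, printed to 2 dp.
GEOMETRIC_MEAN_PERCENT = np.array([3.06, 2.22, 26.74, 45.72, 22.26])

#: Published per-component pivot regression coefficients (PHQ-9 points per
#: pivot ILR unit): each entry is the first-pivot coefficient of the model
#: in which that part is contrasted against the geometric mean of the rest.
PIVOT_COEFFICIENTS = {
    "mvpa": -0.293,
    "lpa": -0.132,
    "nsst": 0.712,
    "slp": -0.981,
    "st": 0.693,
}

#: Published standard errors of the pivot coefficients.
PIVOT_STANDARD_ERRORS = {
    "mvpa": 0.051,
    "lpa": 0.059,
    "nsst": 0.091,
    "slp": 0.142,
    "st": 0.064,
}

#: Published pairwise log-ratio variation matrix, canonical order.
VARIATION_MATRIX = np.array(
    [
        [0.0, 3.296999, 3.46981, 2.618966, 4.411397],
        [3.296999, 0.0, 2.546195, 1.797028, 3.355167],
        [3.46981, 2.546195, 0.0, 0.779976, 2.963138],
        [2.618966, 1.797028, 0.779976, 0.0, 1.580719],
        [4.411397, 3.355167, 2.963138, 1.580719, 0.0],
    ]
)

#: Published depression-severity counts (none, mild, moderate, severe).
SEVERITY_COUNTS = {"none": 3134, "mild": 2109, "moderate": 794, "severe": 629}

#: Published mean and SD of the PHQ-9 total score.
SCORE_MEAN = 6.18
SCORE_SD = 5.79
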