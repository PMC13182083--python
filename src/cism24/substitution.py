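"""Compositional isotemporal substitution: reallocating minutes between
activities at a baseline day and predicting the change in depression score.

A reallocation moves ``delta`` minutes from one part to another at a
baseline composition (typically the sample's geometric-mean day), leaving
the other parts and the 1440-minute total untouched.  The predicted change
is the difference of model predictions at the new and baseline days, which
for a linear ILR model collapses to the log-contrast form

    change = a' (ln x_new - ln x_base)

with a the sum-zero clr coefficient vector.  Covariates cancel in the
difference, so estimates are identical for every covariate profile.

When a full coefficient covariance is available (a fit on raw data), a
delta-method normal confidence interval accompanies the estimate: the
change is the linear contrast c'beta with c = ilr(new) - ilr(base) padded
with zeros over intercept and covariates, so var = c' Sigma c.  Fits
reconstructed from a published pivot table carry no covariance and produce
point estimates only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coda import Composition, ilr_transform
from .regression import CompositionalFit

logger = logging.getLogger(__name__)

__all__ = [
    "Reallocation",
    "SubstitutionEstimate",
    "reallocate",
    "max_feasible_delta",
    "predicted_change",
    "substitution_matrix",
    "substitution_curve",
]


@dataclass(frozen=True)
class Reallocation:
    """Move ``delta`` minutes from ``from_part`` to ``to_part``."""

    from_part: str
    to_part: str
    delta: float

    def __post_init__(self) -> None:
        if self.from_part == self.to_part:
            raise ValueError("from_part and to_part must differ")
        if not self.delta > 0:
            raise ValueError(f"delta must be positive, got {self.delta}")


@dataclass(frozen=True)
class SubstitutionEstimate:
    """Predicted outcome change for one reallocation, with optional 95% CI."""

    estimate: float
    reallocation: Reallocation
    baseline: Composition
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None and self.ci_high is not None


def max_feasible_delta(base: Composition, from_part: str) -> float:
    """Largest delta that keeps ``from_part`` strictly positive."""
    return base[from_part]


def reallocate(base: Composition, r: Reallocation) -> Composition:
    """Apply a reallocation; errors if the donor part would be exhausted."""
    if r.from_part not in base.names or r.to_part not in base.names:
        raise ValueError(f"unknown part in {r}; parts are {base.names}")
    if base[r.from_part] - r.delta <= 0:
        raise ValueError(
            f"reallocating {r.delta:g} min would exhaust {r.from_part!r} "
            f"({base[r.from_part]:g} min); maximum feasible delta is just "
            f"under {max_feasible_delta(base, r.from_part):g}"
        )
    values = base.values.copy()
    values[base.names.index(r.from_part)] -= r.delta
    values[base.names.index(r.to_part)] += r.delta
    return Composition(values, base.names, base.total)


def predicted_change(
    fit: CompositionalFit,
    base: Composition,
    r: Reallocation,
    confidence: float = 0.95,
) -> SubstitutionEstimate:
    """Predicted outcome change for one reallocation at a baseline day.

    Point estimate: coefficient contrast over the ILR difference.  CI: delta
    method on the same contrast when the fit carries a covariance; otherwise
    the estimate is returned with the CI marked unavailable.
    """
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    new = reallocate(base, r)
    dz = ilr_transform(new, fit.basis) - ilr_transform(base, fit.basis)
    estimate = float(fit.ilr_coefficients @ dz)

    ci_low = ci_high = None
    if fit.coefficient_covariance is not None:
        k = len(fit.ilr_coefficients)
        contrast = np.zeros(fit.coefficient_covariance.shape[0])
        contrast[1 : 1 + k] = dz  # intercept and covariate positions stay zero
        se = float(np.sqrt(contrast @ fit.coefficient_covariance @ contrast))
        zcrit = stats.norm.ppf(0.5 + confidence / 2.0)
        ci_low, ci_high = estimate - zcrit * se, estimate + zcrit * se
    return SubstitutionEstimate(estimate, r, base, ci_low, ci_high)


def substitution_matrix(
    fit: CompositionalFit,
    base: Composition,
    deltas: tuple[float, ...] = (10.0, 20.0, 30.0),
    confidence: float = 0.95,
) -> pd.DataFrame:
    """All ordered part pairs at each delta, long format.

    Columns: delta, decrease_part, increase_part, estimate, ci_low, ci_high,
    feasible.  Infeasible cells (donor part too small) are flagged rather
    than raised, with NaN estimates.
    """
    rows = []
    for delta in deltas:
        for dn in base.names:
            for up in base.names:
                if dn == up:
                    continue
                row = {
                    "delta": float(delta),
                    "decrease_part": dn,
                    "increase_part": up,
                    "estimate": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "feasible": base[dn] - delta > 0,
                }
                if row["feasible"]:
                    est = predicted_change(
                        fit, base, Reallocation(dn, up, delta), confidence
                    )
                    row["estimate"] = est.estimate
                    if est.has_ci:
                        row["ci_low"], row["ci_high"] = est.ci_low, est.ci_high
                rows.append(row)
    return pd.DataFrame(rows)


def substitution_curve(
    fit: CompositionalFit,
    base: Composition,
    moving_part: str,
    against: str,
    min_delta: float = -60.0,
    max_delta: float = 60.0,
    step: float = 5.0,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Dose-response curve for one part pair on a delta grid.

    Positive delta moves minutes from ``against`` into ``moving_part``;
    negative delta moves them back.  Grid points that would exhaust either
    part are clipped away (with a warning), and delta 0 contributes an exact
    zero.  Columns: delta, estimate, ci_low, ci_high.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if moving_part == against:
        raise ValueError("moving_part and against must differ")
    grid = np.arange(min_delta, max_delta + step / 2.0, step)
    # positivity: moving + d > 0 and against - d > 0
    feasible = (base[moving_part] + grid > 0) & (base[against] - grid > 0)
    if not feasible.all():
        logger.warning(
            "clipping %d infeasible grid point(s) for %s vs %s",
            int((~feasible).sum()), moving_part, against,
        )
        grid = grid[feasible]

    rows = []
    for d in grid:
        if d == 0:
            rows.append(
                {"delta": 0.0, "estimate": 0.0, "ci_low": np.nan, "ci_high": np.nan}
            )
            continue
        r = (
            Reallocation(against, moving_part, d)
            if d > 0
            else Reallocation(moving_part, against, -d)
        )
        est = predicted_change(fit, base, r, confidence)
        rows.append(
            {
                "delta": float(d),
                "estimate": est.estimate,
                "ci_low": est.ci_low if est.has_ci else np.nan,
                "ci_high": est.ci_high if est.has_ci else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.insert(0, "against", against)
    out.insert(0, "moving_part", moving_part)
    return out
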