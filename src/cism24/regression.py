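"""Compositional linear regression of depression scores on ILR coordinates.

The model is ordinary least squares on the design
``[1, z1, z2, z3, z4, dummy-coded covariates]`` where z are pivot ILR
coordinates of the daily composition:

    y = b0 + b1*z1 + b2*z2 + b3*z3 + b4*z4 + g'dummies + e

Because the ILR basis is orthonormal in clr space, the fitted surface is
invariant to basis rotation; rotating each part to the first pivot position
and refitting yields the per-component ("part vs. remaining behaviors")
coefficient table, and the clr coefficient vector a = B @ b (sum zero)
gives the log-contrast form y = b0 + a'ln(x) + ... used by the
substitution model.

A fit can also be reconstructed from a published per-component pivot table
(:func:`fit_from_pivot_table`): each pivot coefficient is scaled by
sqrt((D-1)/D) to the clr scale and the vector re-centred to exact sum zero.
Such a fit has no coefficient covariance, so it yields point estimates but
no confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._reference import PARTS
from .coda import Composition, SBPBasis, ilr_transform, pivot_basis

__all__ = [
    "CompositionalFit",
    "fit_compositional_model",
    "fit_from_pivot_table",
    "pivot_coefficient_table",
    "predict",
]


@dataclass(frozen=True)
class CompositionalFit:
    """A fitted (or reconstructed) compositional regression.

    ``param_names`` orders the full coefficient vector as
    ``["const", "z1".."z{D-1}", <dummy columns>]``; ``coefficient_covariance``
    (if present) is over that same order.  ``clr_coefficients`` is the
    sum-zero log-contrast vector in ``basis.part_order``.
    """

    basis: SBPBasis
    intercept: float
    ilr_coefficients: np.ndarray
    covariate_coefficients: dict[str, float] = field(default_factory=dict)
    coefficient_covariance: np.ndarray | None = None
    residual_variance: float | None = None
    n: int | None = None
    covariate_levels: dict[str, list[str]] = field(default_factory=dict)

    @property
    def clr_coefficients(self) -> np.ndarray:
        return self.basis.basis_matrix @ self.ilr_coefficients

    @property
    def param_names(self) -> list[str]:
        return (
            ["const"]
            + [f"z{i + 1}" for i in range(len(self.ilr_coefficients))]
            + list(self.covariate_coefficients)
        )

    def to_dict(self) -> dict:
        """JSON-serialisable representation; round-trips exactly."""
        return {
            "part_order": list(self.basis.part_order),
            "intercept": self.intercept,
            "ilr_coefficients": self.ilr_coefficients.tolist(),
            "covariate_coefficients": dict(self.covariate_coefficients),
            "coefficient_covariance": (
                None
                if self.coefficient_covariance is None
                else self.coefficient_covariance.tolist()
            ),
            "residual_variance": self.residual_variance,
            "n": self.n,
            "covariate_levels": {k: list(v) for k, v in self.covariate_levels.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompositionalFit":
        cov = d.get("coefficient_covariance")
        return cls(
            basis=pivot_basis(tuple(d["part_order"])),
            intercept=float(d["intercept"]),
            ilr_coefficients=np.asarray(d["ilr_coefficients"], dtype=float),
            covariate_coefficients=dict(d.get("covariate_coefficients", {})),
            coefficient_covariance=None if cov is None else np.asarray(cov, float),
            residual_variance=d.get("residual_variance"),
            n=d.get("n"),
            covariate_levels={
                k: list(v) for k, v in d.get("covariate_levels", {}).items()
            },
        )


def _dummy_design(
    data: pd.DataFrame,
    covariates: Sequence[str],
    levels: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Treatment-coded dummies; reference = first level in sorted or given order."""
    cols = {}
    level_map: dict[str, list[str]] = {}
    for cov in covariates:
        if levels and cov in levels:
            cats = list(levels[cov])
        else:
            cats = sorted(data[cov].astype(str).unique())
        observed = set(data[cov].astype(str))
        unknown = observed - set(cats)
        if unknown:
            raise ValueError(f"unknown level(s) for covariate {cov!r}: {sorted(unknown)}")
        level_map[cov] = cats
        for lvl in cats[1:]:
            cols[f"{cov}[{lvl}]"] = (data[cov].astype(str) == lvl).astype(float)
    return pd.DataFrame(cols, index=data.index), level_map


def fit_compositional_model(
    data: pd.DataFrame,
    basis: SBPBasis | None = None,
    covariates: Sequence[str] = (),
    outcome: str = "phq9_total",
    covariate_levels: Mapping[str, Sequence[str]] | None = None,
) -> CompositionalFit:
    """OLS of the outcome on pivot ILR coordinates plus covariate dummies.

    ``data`` must carry the five part columns (minutes), the outcome, and
    the covariate columns.  Raises on rank-deficient designs, naming the
    collinear columns.
    """
    if basis is None:
        basis = pivot_basis(PARTS)
    missing = [c for c in (*basis.part_order, outcome, *covariates) if c not in data]
    if missing:
        raise ValueError(f"dataset is missing columns: {missing}")

    parts = data[list(basis.part_order)].to_numpy(float)
    if np.any(parts <= 0):
        raise ValueError("all part columns must be strictly positive")
    z = ilr_transform(parts, basis)
    zcols = [f"z{i + 1}" for i in range(z.shape[1])]
    design = pd.DataFrame(z, columns=zcols, index=data.index)
    dummies, level_map = _dummy_design(data, covariates, covariate_levels)
    design = pd.concat([design, dummies], axis=1)
    design.insert(0, "const", 1.0)

    n, p = design.shape
    if n <= p:
        raise ValueError(f"need more than {p} observations, got {n}")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < p:
        # identify offending columns by incremental rank
        bad, cur = [], np.empty((n, 0))
        for col in design.columns:
            cand = np.column_stack([cur, design[col].to_numpy()])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(col)
            else:
                cur = cand
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    model = sm.OLS(data[outcome].to_numpy(float), design.to_numpy())
    res = model.fit()
    params = pd.Series(res.params, index=design.columns)
    return CompositionalFit(
        basis=basis,
        intercept=float(params["const"]),
        ilr_coefficients=params[zcols].to_numpy(),
        covariate_coefficients={c: float(params[c]) for c in dummies.columns},
        coefficient_covariance=np.asarray(res.cov_params()),
        residual_variance=float(res.mse_resid),
        n=n,
        covariate_levels=level_map,
    )


def pivot_coefficient_table(
    data: pd.DataFrame,
    covariates: Sequence[str] = (),
    part_order: Sequence[str] = PARTS,
    outcome: str = "phq9_total",
) -> pd.DataFrame:
    """Per-component pivot coefficients: each part vs. the rest.

    For each part, the model is refit with that part rotated to the first
    pivot position; the table reports that model's first ILR coefficient,
    its standard error, and a two-sided t-test p-value (n - p degrees of
    freedom).  All rotations describe the same fitted surface.
    """
    rows = []
    for part in part_order:
        order = (part, *[p for p in part_order if p != part])
        fit = fit_compositional_model(
            data, pivot_basis(order), covariates, outcome=outcome
        )
        se = float(np.sqrt(fit.coefficient_covariance[1, 1]))
        dof = fit.n - fit.coefficient_covariance.shape[0]
        tval = fit.ilr_coefficients[0] / se
        from scipy import stats

        pval = 2.0 * stats.t.sf(abs(tval), dof)
        rows.append(
            {
                "part": part,
                "coefficient": float(fit.ilr_coefficients[0]),
                "std_error": se,
                "p_value": float(pval),
            }
        )
    return pd.DataFrame(rows).set_index("part")


def fit_from_pivot_table(
    pivot_coefficients: Mapping[str, float],
    part_order: Sequence[str] = PARTS,
    intercept: float = 0.0,
    sum_tolerance: float = 0.01,
) -> CompositionalFit:
    """Reconstruct a fit from published per-component pivot coefficients.

    Each first-pivot coefficient b_k relates to the clr coefficient a_k by
    b_k = sqrt(D/(D-1)) * a_k, so a_k = sqrt((D-1)/D) * b_k.  Published
    tables are rounded, so the implied clr vector may miss sum-zero by
    printing error; it is re-centred exactly, after checking the raw sum is
    within ``sum_tolerance``.  No covariance is available, so downstream
    substitution estimates carry no confidence intervals.
    """
    order = tuple(part_order)
    missing = [p for p in order if p not in pivot_coefficients]
    if missing:
        raise ValueError(f"pivot table is missing parts: {missing}")
    d = len(order)
    b = np.array([float(pivot_coefficients[p]) for p in order])
    a = np.sqrt((d - 1) / d) * b
    if abs(a.sum()) > sum_tolerance:
        raise ValueError(
            f"implied clr coefficients sum to {a.sum():.4f}; "
            f"inconsistent pivot table (|sum| > {sum_tolerance})"
        )
    a = a - a.mean()
    basis = pivot_basis(order)
    return CompositionalFit(
        basis=basis,
        intercept=float(intercept),
        ilr_coefficients=basis.basis_matrix.T @ a,
    )


def predict(
    fit: CompositionalFit,
    composition: Composition,
    covariates: Mapping[str, str] | None = None,
) -> float:
    """Predicted outcome at a composition and covariate profile.

    Covariates are optional; omitted ones contribute their reference level
    (zero).  Differences of predictions at two compositions never depend on
    the covariate profile.
    """
    z = ilr_transform(composition, fit.basis)
    value = fit.intercept + float(fit.ilr_coefficients @ z)
    covariates = covariates or {}
    for cov, lvl in covariates.items():
        if cov not in fit.covariate_levels:
            raise ValueError(f"unknown covariate {cov!r}")
        levels = fit.covariate_levels[cov]
        if str(lvl) not in levels:
            raise ValueError(f"unknown level {lvl!r} for covariate {cov!r}")
        key = f"{cov}[{lvl}]"
        value += fit.covariate_coefficients.get(key, 0.0)
    return value
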