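"""Synthetic adolescent cohorts with the structure the analysis assumes.

The generator draws each subject's day from a logistic-normal law: ILR
coordinates are multivariate normal around the ILR image of a mean
composition, and days are mapped back to the simplex and closed to 1440
minutes.  Under this law the compositional linear regression is correctly
specified, so the full pipeline (transform, fit, substitute) can be
exercised end-to-end and checked for parameter recovery.

Defaults emulate the published cohort the package's reference constants
come from: a survey of 6,666 urban Chinese adolescents.  The mean
composition is that study's geometric-mean day; the ILR covariance is the
one implied by its published pairwise log-ratio variation matrix (the
variation matrix determines the clr covariance uniquely by double
centering, and hence the ILR covariance); the true log-contrast (clr)
coefficients are the published per-component pivot coefficients rescaled to
clr; and the intercept places the expected score at the published mean of
6.18 points.  Outcome noise defaults to 5 points, roughly the published
score SD (5.79) net of what composition and covariates explain.

Depression scores are left continuous by default so recovery tests are
clean; ``discretize=True`` rounds and clips to the 0-27 integer range for
realism at the cost of a small attenuation bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _reference as ref
from .coda import (
    Composition,
    SBPBasis,
    clr_transform,
    close,
    ilr_inverse,
    ilr_transform,
    pivot_basis,
)
from .instruments import phq9_severity

__all__ = [
    "CovariateSpec",
    "SyntheticConfig",
    "default_config",
    "ilr_covariance_from_variation",
    "generate_cohort",
    "theoretical_variation_matrix",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One categorical covariate: levels, sampling frequencies, additive
    effects (points) per level, and an optional per-level shift of the ILR
    mean (to induce composition-covariate confounding)."""

    levels: tuple[str, ...]
    frequencies: tuple[float, ...]
    effects: tuple[float, ...]
    ilr_shifts: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        k = len(self.levels)
        if not (len(self.frequencies) == len(self.effects) == k):
            raise ValueError("levels, frequencies and effects must align")
        freq = np.asarray(self.frequencies, float)
        if np.any(freq < 0) or not np.isclose(freq.sum(), 1.0, atol=1e-6):
            raise ValueError("frequencies must be non-negative and sum to 1")
        if self.ilr_shifts is not None and len(self.ilr_shifts) != k:
            raise ValueError("ilr_shifts must have one row per level")


def ilr_covariance_from_variation(
    variation: np.ndarray, basis: SBPBasis
) -> np.ndarray:
    """ILR covariance implied by a pairwise log-ratio variation matrix.

    Double-centering -(1/2) H T H (H the centering projector) recovers the
    clr covariance from the variation matrix exactly; projecting through the
    basis gives the ILR covariance.  Raises if the result is not positive
    definite (i.e. T is not a valid variation matrix).
    """
    t = np.asarray(variation, float)
    d = t.shape[0]
    if t.shape != (d, d) or not np.allclose(t, t.T, atol=1e-8):
        raise ValueError("variation matrix must be square and symmetric")
    h = np.eye(d) - np.ones((d, d)) / d
    clr_cov = -0.5 * h @ t @ h
    cov = basis.basis_matrix.T @ clr_cov @ basis.basis_matrix
    if np.any(np.linalg.eigvalsh(cov) <= 0):
        raise ValueError("variation matrix does not yield a positive-definite "
                         "ILR covariance")
    return cov


def _default_covariates() -> dict[str, CovariateSpec]:
    """Demographics with frequencies and modest effects on the published
    cohort's scale: girls score higher, scores rise with grade, small BMI
    gradient."""
    return {
        "sex": CovariateSpec(
            levels=("male", "female"),
            frequencies=(0.5381, 0.4619),
            effects=(0.0, 2.0),
        ),
        "grade": CovariateSpec(
            levels=("g7", "g8", "g10", "g11"),
            frequencies=(0.25, 0.25, 0.25, 0.25),
            effects=(0.0, 1.0, 3.0, 3.0),
        ),
        "bmi_class": CovariateSpec(
            levels=("underweight", "normal", "overweight", "obese"),
            frequencies=(0.2895, 0.5344, 0.1227, 0.0534),
            effects=(-0.5, 0.0, 0.3, 0.3),
        ),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Data-generating parameters for one synthetic cohort."""

    n: int = 6666
    mean_composition: Composition = field(
        default_factory=lambda: close(ref.GEOMETRIC_MEAN_MINUTES)
    )
    ilr_covariance: np.ndarray | None = None
    true_clr_coefficients: np.ndarray | None = None
    intercept: float | None = None
    covariates: Mapping[str, CovariateSpec] = field(default_factory=dict)
    noise_sd: float = 5.0
    discretize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        basis = self.basis
        d = basis.dim
        cov = self.ilr_covariance
        if cov is None:
            cov = ilr_covariance_from_variation(ref.VARIATION_MATRIX, basis)
        cov = np.asarray(cov, float)
        if cov.shape != (d - 1, d - 1) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("ilr_covariance must be a symmetric (D-1) square matrix")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("ilr_covariance must be positive definite")
        object.__setattr__(self, "ilr_covariance", cov)

        a = self.true_clr_coefficients
        if a is None:
            b = np.array([ref.PIVOT_COEFFICIENTS[p] for p in basis.part_order])
            a = np.sqrt((d - 1) / d) * b
            a = a - a.mean()
        a = np.asarray(a, float)
        if a.shape != (d,):
            raise ValueError(f"true_clr_coefficients must have length {d}")
        if abs(a.sum()) > 1e-10:
            raise ValueError("true_clr_coefficients must sum to zero")
        object.__setattr__(self, "true_clr_coefficients", a)

        if self.intercept is None:
            # place the expected score at the published cohort mean
            base = float(a @ clr_transform(self.mean_composition))
            cov_mean = sum(
                float(np.dot(spec.frequencies, spec.effects))
                for spec in self.covariates.values()
            )
            object.__setattr__(
                self, "intercept", ref.SCORE_MEAN - base - cov_mean
            )

    @property
    def basis(self) -> SBPBasis:
        return pivot_basis(self.mean_composition.names)


def default_config(**overrides) -> SyntheticConfig:
    """A config emulating the published cohort, with default demographics."""
    kwargs: dict = {"covariates": _default_covariates()}
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Draw one cohort; bit-reproducible for a given config and seed.

    Returns the analytic schema: part columns in minutes, ``phq9_total``
    (continuous, or integer 0-27 with ``discretize``), ``severity`` (only
    meaningful when discretized, still reported from the clipped rounded
    score otherwise), and one column per covariate.
    """
    rng = np.random.default_rng(config.seed)
    basis = config.basis
    mu = ilr_transform(config.mean_composition, basis)

    # covariates first so their ILR shifts can act on the composition draw
    cov_cols: dict[str, np.ndarray] = {}
    shift = np.zeros((config.n, basis.dim - 1))
    effect = np.zeros(config.n)
    for name, spec in config.covariates.items():
        idx = rng.choice(len(spec.levels), size=config.n, p=spec.frequencies)
        cov_cols[name] = np.array(spec.levels)[idx]
        effect += np.array(spec.effects)[idx]
        if spec.ilr_shifts is not None:
            shift += np.array(spec.ilr_shifts, float)[idx]

    z = rng.multivariate_normal(mu, config.ilr_covariance, size=config.n) + shift
    parts = ilr_inverse(z, basis, config.mean_composition.total)
    y = (
        config.intercept
        + clr_transform(parts) @ config.true_clr_coefficients
        + effect
        + rng.normal(0.0, config.noise_sd, size=config.n)
    )
    if config.discretize:
        y = np.clip(np.rint(y), 0, 27).astype(int)

    out = pd.DataFrame(parts, columns=list(basis.part_order))
    out["phq9_total"] = y
    clipped = np.clip(np.rint(np.asarray(y, float)), 0, 27).astype(int)
    out["severity"] = [phq9_severity(v) for v in clipped]
    for name, col in cov_cols.items():
        out[name] = col
    return out


def theoretical_variation_matrix(config: SyntheticConfig) -> np.ndarray:
    """Population variation matrix of the generator's logistic-normal law.

    With clr covariance S = B Sigma_ilr B', the pairwise log-ratio variance
    is T_ij = S_ii + S_jj - 2 S_ij.  The sample variation matrix of a large
    generated cohort converges to this.
    """
    b = config.basis.basis_matrix
    s = b @ config.ilr_covariance @ b.T
    diag = np.diag(s)
    t = diag[:, None] + diag[None, :] - 2.0 * s
    np.fill_diagonal(t, 0.0)
    return t
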