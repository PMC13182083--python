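"""Compositional geometry on the 5-part daily time-use simplex.

A day is a composition: five strictly positive parts (moderate-to-vigorous
physical activity, light physical activity, non-screen sedentary time,
sleep, screen time) that sum to 1440 minutes.  Because only relative
information is meaningful under the fixed total, analysis happens in
log-ratio coordinates: the centred log-ratio (clr) and an orthonormal
isometric log-ratio (ILR) basis built by sequential binary partition, whose
pivot form contrasts each part against the geometric mean of the parts
after it.

The functions here are deliberately small and array-first: they accept a
:class:`Composition` or a bare array of parts (one composition per row for
dataset-level operations) and return numpy arrays, so the regression and
simulation layers can stay vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._reference import DAY_MINUTES, PARTS

__all__ = [
    "Composition",
    "SBPBasis",
    "close",
    "geometric_mean_composition",
    "composition_percentages",
    "variation_matrix",
    "pivot_basis",
    "ilr_transform",
    "ilr_inverse",
    "clr_transform",
]


@dataclass(frozen=True)
class Composition:
    """A closed, strictly positive vector of daily minutes.

    Parameters
    ----------
    values
        Part values in the order given by ``names``; must be strictly
        positive and sum to ``total`` within 1e-6.
    names
        Part labels; defaults to the canonical order
        ``(mvpa, lpa, nsst, slp, st)``.
    total
        The closure constant, 1440 minutes by default.
    """

    values: np.ndarray
    names: tuple[str, ...] = PARTS
    total: float = DAY_MINUTES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != len(self.names):
            raise ValueError(
                f"expected {len(self.names)} parts, got shape {values.shape}"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"duplicate part names in {self.names}")
        if not np.all(np.isfinite(values)):
            raise ValueError("composition parts must be finite")
        if np.any(values <= 0):
            bad = [n for n, v in zip(self.names, values) if v <= 0]
            raise ValueError(f"composition parts must be strictly positive: {bad}")
        if abs(values.sum() - self.total) > 1e-6 * max(self.total, 1.0):
            raise ValueError(
                f"parts sum to {values.sum():.6f}, expected {self.total}"
            )

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def asdict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}

    def reorder(self, names: Sequence[str]) -> "Composition":
        """Return the same composition with parts permuted to ``names``."""
        if set(names) != set(self.names):
            raise ValueError(f"{tuple(names)} is not a permutation of {self.names}")
        idx = [self.names.index(n) for n in names]
        return Composition(self.values[idx], tuple(names), self.total)


def close(
    parts: Iterable[float],
    names: tuple[str, ...] = PARTS,
    total: float = DAY_MINUTES,
) -> Composition:
    """Rescale a positive vector so its parts sum to ``total``.

    Closure is the canonical projection onto the simplex: the output is
    proportional to the input, so it preserves all ratios and is idempotent.
    """
    arr = np.asarray(list(parts) if not isinstance(parts, np.ndarray) else parts,
                     dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("closure requires finite, strictly positive parts")
    return Composition(arr * (total / arr.sum()), names, total)


def _as_matrix(dataset) -> tuple[np.ndarray, tuple[str, ...], float]:
    """Normalise a dataset (list of Composition or 2-D array) to a matrix."""
    if isinstance(dataset, np.ndarray):
        mat = np.atleast_2d(np.asarray(dataset, dtype=float))
        return mat, PARTS[: mat.shape[1]], DAY_MINUTES
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset is empty")
    first = dataset[0]
    if isinstance(first, Composition):
        names, total = first.names, first.total
        for c in dataset:
            if c.names != names or c.total != total:
                raise ValueError("compositions disagree on part order or total")
        return np.vstack([c.values for c in dataset]), names, total
    return np.atleast_2d(np.asarray(dataset, dtype=float)), PARTS, DAY_MINUTES


def geometric_mean_composition(dataset) -> Composition:
    """Part-wise geometric mean across subjects, closed to the shared total.

    This is the compositional centre: the point the substitution model uses
    as its baseline day.
    """
    mat, names, total = _as_matrix(dataset)
    if np.any(mat <= 0):
        raise ValueError("geometric mean requires strictly positive parts")
    gm = np.exp(np.log(mat).mean(axis=0))
    return close(gm, names, total)


def composition_percentages(c: Composition) -> np.ndarray:
    """Each part's share of the day in percent; sums to 100."""
    return c.values / c.total * 100.0


def variation_matrix(dataset) -> np.ndarray:
    """Pairwise log-ratio variances T_ij = var(ln(x_i / x_j)).

    The variation matrix is the compositional measure of dispersion: entry
    (i, j) is the sample variance (n-1 denominator) of the log-ratio of
    parts i and j across subjects.  Symmetric with a zero diagonal.
    """
    mat, _, _ = _as_matrix(dataset)
    n, d = mat.shape
    if n < 2:
        raise ValueError("variation matrix needs at least 2 compositions")
    logs = np.log(mat)
    # var(l_i - l_j) computed from the log covariance matrix
    cov = np.cov(logs, rowvar=False, ddof=1)
    diag = np.diag(cov)
    t = diag[:, None] + diag[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


@dataclass(frozen=True)
class SBPBasis:
    """Orthonormal ILR basis from a sequential binary partition.

    ``contrast_matrix`` holds the signed partition (row k: +1 on part k,
    -1 on every later part); ``basis_matrix`` holds the corresponding
    orthonormal clr-space basis vectors as columns, so that
    ``z = basis_matrix.T @ clr(x)`` and ``clr(x) = basis_matrix @ z``.
    """

    part_order: tuple[str, ...]
    contrast_matrix: np.ndarray = field(repr=False)
    basis_matrix: np.ndarray = field(repr=False)

    @property
    def dim(self) -> int:
        return len(self.part_order)


def pivot_basis(part_order: Sequence[str] = PARTS) -> SBPBasis:
    """Pivot-coordinate basis: part k against the geometric mean of the rest.

    Coordinate k (1-based) is
    ``sqrt((D-k)/(D-k+1)) * ln( x_k / gmean(x_{k+1}, ..., x_D) )``,
    so the first coordinate isolates the first part against all others.
    Refitting with each part rotated to the front yields the per-component
    ("part vs. remaining behaviors") regression coefficients.
    """
    names = tuple(part_order)
    d = len(names)
    if d < 2:
        raise ValueError("need at least two parts")
    if len(set(names)) != d:
        raise ValueError(f"duplicate part names: {names}")
    contrast = np.zeros((d - 1, d))
    basis = np.zeros((d, d - 1))
    for k in range(d - 1):
        r = d - k - 1  # number of parts in the denominator group
        contrast[k, k] = 1.0
        contrast[k, k + 1 :] = -1.0
        scale = np.sqrt(r / (r + 1.0))
        basis[k, k] = scale
        basis[k + 1 :, k] = -scale / r
    return SBPBasis(names, contrast, basis)


def _values_for(basis: SBPBasis, c) -> np.ndarray:
    if isinstance(c, Composition):
        if c.names != basis.part_order:
            if set(c.names) != set(basis.part_order):
                raise ValueError(
                    f"composition parts {c.names} do not match basis "
                    f"{basis.part_order}"
                )
            c = c.reorder(basis.part_order)
        return c.values
    arr = np.asarray(c, dtype=float)
    if arr.shape[-1] != basis.dim:
        raise ValueError(f"expected {basis.dim} parts, got {arr.shape[-1]}")
    return arr


def clr_transform(c) -> np.ndarray:
    """Centred log-ratio: log parts minus their mean log.  Sums to zero.

    Accepts a :class:`Composition` or an array (rows = compositions).
    """
    values = c.values if isinstance(c, Composition) else np.asarray(c, dtype=float)
    if np.any(values <= 0):
        raise ValueError("clr requires strictly positive parts")
    logs = np.log(values)
    return logs - logs.mean(axis=-1, keepdims=True)


def ilr_transform(c, basis: SBPBasis | None = None) -> np.ndarray:
    """ILR coordinates z = basis.T @ clr(x); length D-1 per composition."""
    if basis is None:
        basis = pivot_basis(c.names if isinstance(c, Composition) else PARTS)
    values = _values_for(basis, c)
    return clr_transform(values) @ basis.basis_matrix


def ilr_inverse(
    z,
    basis: SBPBasis | None = None,
    total: float = DAY_MINUTES,
) -> Composition | np.ndarray:
    """Map ILR coordinates back to a closed composition.

    A single coordinate vector returns a :class:`Composition`; a matrix of
    coordinates (rows = subjects) returns the closed part matrix.
    """
    if basis is None:
        basis = pivot_basis()
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("ILR coordinates must be finite")
    clr = z @ basis.basis_matrix.T
    raw = np.exp(clr)
    if z.ndim == 1:
        return close(raw, basis.part_order, total)
    return raw * (total / raw.sum(axis=1, keepdims=True))
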