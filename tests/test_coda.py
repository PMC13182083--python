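"""Log-ratio geometry: closure, centres, dispersion, ILR/clr transforms.

scikit-bio's composition module serves as the independent oracle for the
clr transform and closure; the pivot ILR machinery is checked against its
explicit log-ratio formulas and brute-force loops.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.stats.composition import closure as skbio_closure
from skbio.stats.composition import clr as skbio_clr

from cism24 import _reference as ref
from cism24.coda import (
    Composition,
    close,
    clr_transform,
    composition_percentages,
    geometric_mean_composition,
    ilr_inverse,
    ilr_transform,
    pivot_basis,
    variation_matrix,
)
from conftest import random_compositions

positive_part = st.floats(1e-3, 1e4, allow_nan=False, allow_infinity=False)
part_vector = st.lists(positive_part, min_size=5, max_size=5)


class TestClose:
    def test_symmetric_input(self):
        comp = close([1, 1, 1, 1, 1])
        np.testing.assert_allclose(comp.values, 288.0)

    def test_published_geometric_means_already_closed(self):
        comp = close(ref.GEOMETRIC_MEAN_MINUTES)
        np.testing.assert_allclose(comp.values, ref.GEOMETRIC_MEAN_MINUTES, atol=1e-9)

    @given(part_vector)
    @settings(max_examples=100, derandomize=True)
    def test_idempotent_and_matches_skbio(self, parts):
        once = close(parts)
        twice = close(once.values)
        np.testing.assert_allclose(once.values, twice.values, rtol=1e-12)
        np.testing.assert_allclose(
            once.values / 1440.0, skbio_closure(np.array(parts)), rtol=1e-10
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            close([1, 2, 3, 4, 0])


class TestComposition:
    def test_sum_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            Composition(np.array([100.0, 100, 100, 100, 100]))

    def test_reorder_is_permutation(self):
        comp = close([10, 20, 30, 40, 50])
        back = comp.reorder(("st", "slp", "nsst", "lpa", "mvpa")).reorder(comp.names)
        np.testing.assert_array_equal(back.values, comp.values)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            Composition(np.full(5, 288.0), names=("a", "a", "b", "c", "d"))


class TestGeometricMean:
    def test_single_composition_is_identity(self):
        comp = close([10, 20, 30, 40, 50])
        np.testing.assert_allclose(
            geometric_mean_composition([comp]).values, comp.values, rtol=1e-12
        )

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        mat = random_compositions(rng, 20)
        gm = geometric_mean_composition(mat)
        brute = np.array(
            [np.prod(mat[:, j]) ** (1 / mat.shape[0]) for j in range(5)]
        )
        brute = brute * 1440 / brute.sum()
        np.testing.assert_allclose(gm.values, brute, rtol=1e-10)

    def test_scale_invariance(self):
        a = close([100, 25, 400, 600, 315])
        b = close(np.array([100, 25, 400, 600, 315]) * 3.7)
        gm = geometric_mean_composition([a, b])
        np.testing.assert_allclose(gm.values, a.values, rtol=1e-12)

    def test_commutes_with_closure(self):
        rng = np.random.default_rng(2)
        raw = np.exp(rng.normal(0, 1, size=(15, 5)))
        closed = raw * (1440 / raw.sum(axis=1, keepdims=True))
        gm_closed = geometric_mean_composition(closed)
        gm_raw = np.exp(np.log(raw).mean(axis=0))
        np.testing.assert_allclose(
            gm_closed.values, gm_raw * 1440 / gm_raw.sum(), rtol=1e-9
        )

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_composition([])


class TestPercentages:
    def test_equal_composition(self):
        np.testing.assert_allclose(
            composition_percentages(close([1] * 5)), [20.0] * 5
        )

    def test_sums_to_hundred(self):
        comp = close(ref.GEOMETRIC_MEAN_MINUTES)
        assert composition_percentages(comp).sum() == pytest.approx(100.0, abs=1e-9)


class TestVariationMatrix:
    def test_identical_subjects_give_zero(self):
        mat = np.tile(close([10, 20, 30, 40, 50]).values, (4, 1))
        np.testing.assert_allclose(variation_matrix(mat), 0.0, atol=1e-12)

    def test_two_subject_log_ratio_variance(self):
        # parts 0 and 1 have ratio 1 in subject A, e in subject B:
        # var({0, 1}) with n-1 denominator = 0.5
        a = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        b = np.array([np.e, 1.0, 1.0, 1.0, 1.0])
        mat = np.vstack([a * 1440 / a.sum(), b * 1440 / b.sum()])
        t = variation_matrix(mat)
        assert t[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(3)
        mat = random_compositions(rng, 30)
        t = variation_matrix(mat)
        for i in range(5):
            for j in range(5):
                expected = np.var(np.log(mat[:, i] / mat[:, j]), ddof=1)
                assert t[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(4)
        t = variation_matrix(random_compositions(rng, 10))
        np.testing.assert_allclose(t, t.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(t), 0.0, atol=1e-12)

    def test_equals_scaled_two_part_ilr_variance(self):
        # T_ij = 2 * var( sqrt(1/2) * ln(x_i/x_j) )
        rng = np.random.default_rng(5)
        mat = random_compositions(rng, 25)
        t = variation_matrix(mat)
        z = np.sqrt(0.5) * np.log(mat[:, 2] / mat[:, 4])
        assert t[2, 4] == pytest.approx(2.0 * np.var(z, ddof=1), abs=1e-12)

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            variation_matrix([close([1] * 5)])


class TestPivotBasis:
    def test_two_part_coordinate(self):
        basis = pivot_basis(("slp", "st"))
        comp = Composition(np.array([658.24, 320.59]), ("slp", "st"), 978.83)
        z = ilr_transform(comp, basis)
        assert z[0] == pytest.approx(np.sqrt(0.5) * np.log(658.24 / 320.59), abs=1e-12)

    def test_first_coordinate_scale_factor(self, canonical_basis):
        assert canonical_basis.basis_matrix[0, 0] == pytest.approx(
            np.sqrt(4 / 5), abs=1e-15
        )

    @pytest.mark.parametrize("d", [2, 3, 4, 5, 6])
    def test_orthonormal_and_centred(self, d):
        basis = pivot_basis(tuple(f"p{i}" for i in range(d)))
        b = basis.basis_matrix
        np.testing.assert_allclose(b.T @ b, np.eye(d - 1), atol=1e-12)
        np.testing.assert_allclose(b.sum(axis=0), 0.0, atol=1e-12)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            pivot_basis(("a", "a", "b"))


class TestIlr:
    def test_equal_composition_maps_to_origin(self, canonical_basis):
        z = ilr_transform(close([1] * 5), canonical_basis)
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_explicit_pivot_formulas(self, canonical_basis, published_baseline):
        v = published_baseline.values  # (mvpa, lpa, nsst, slp, st)
        z = ilr_transform(published_baseline, canonical_basis)
        gm = lambda x: np.exp(np.log(x).mean())
        expected = [
            np.sqrt(4 / 5) * np.log(v[0] / gm(v[1:])),
            np.sqrt(3 / 4) * np.log(v[1] / gm(v[2:])),
            np.sqrt(2 / 3) * np.log(v[2] / gm(v[3:])),
            np.sqrt(1 / 2) * np.log(v[3] / v[4]),
        ]
        np.testing.assert_allclose(z, expected, atol=1e-12)
        # last coordinate is the printed sleep-vs-screen balance
        assert z[3] == pytest.approx(np.sqrt(0.5) * np.log(658.24 / 320.59), abs=1e-4)

    @given(part_vector, part_vector)
    @settings(max_examples=100, derandomize=True)
    def test_linear_under_perturbation(self, p1, p2):
        c1, c2 = close(p1), close(p2)
        pert = close(c1.values * c2.values)
        np.testing.assert_allclose(
            ilr_transform(pert),
            ilr_transform(c1) + ilr_transform(c2),
            atol=1e-9,
        )

    def test_part_order_mismatch_rejected(self, canonical_basis):
        comp = Composition(np.full(3, 480.0), ("a", "b", "c"))
        with pytest.raises(ValueError):
            ilr_transform(comp, canonical_basis)


class TestIlrInverse:
    def test_origin_maps_to_equal_composition(self, canonical_basis):
        comp = ilr_inverse(np.zeros(4), canonical_basis)
        np.testing.assert_allclose(comp.values, 288.0, rtol=1e-12)

    def test_round_trip_on_random_compositions(self, canonical_basis):
        rng = np.random.default_rng(6)
        mat = random_compositions(rng, 1000)
        z = ilr_transform(mat, canonical_basis)
        back = ilr_inverse(z, canonical_basis)
        z2 = ilr_transform(back, canonical_basis)
        assert np.abs(z2 - z).max() < 1e-9
        np.testing.assert_allclose(back, mat, rtol=1e-9)

    def test_recovers_published_baseline(self, canonical_basis, published_baseline):
        z = ilr_transform(published_baseline, canonical_basis)
        back = ilr_inverse(z, canonical_basis)
        np.testing.assert_allclose(back.values, published_baseline.values, rtol=1e-6)

    def test_nonfinite_rejected(self, canonical_basis):
        with pytest.raises(ValueError):
            ilr_inverse(np.array([0.0, np.inf, 0.0, 0.0]), canonical_basis)


class TestClr:
    def test_equal_composition_maps_to_zero(self):
        np.testing.assert_allclose(clr_transform(close([1] * 5)), 0.0, atol=1e-15)

    @given(part_vector)
    @settings(max_examples=100, derandomize=True)
    def test_sums_to_zero_and_matches_skbio(self, parts):
        comp = close(parts)
        ours = clr_transform(comp)
        assert abs(ours.sum()) < 1e-12
        np.testing.assert_allclose(ours, skbio_clr(comp.values / 1440.0), atol=1e-10)

    def test_basis_identity(self, canonical_basis):
        rng = np.random.default_rng(7)
        mat = random_compositions(rng, 50)
        z = ilr_transform(mat, canonical_basis)
        np.testing.assert_allclose(
            clr_transform(mat), z @ canonical_basis.basis_matrix.T, atol=1e-12
        )

    def test_two_part_log_difference(self):
        g = 7.0
        comp = Composition(np.array([np.e * g, g]), ("a", "b"), np.e * g + g)
        np.testing.assert_allclose(clr_transform(comp), [0.5, -0.5], atol=1e-12)
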