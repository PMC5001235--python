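"""Distance covariance / correlation against a literal-equation oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dcorstrat import dcor
from dcorstrat.dcor import (
    CohortMismatchError,
    dcor_matrix,
    distance_correlation,
    distance_covariance,
    double_center,
    pairwise_column_distances,
)
from dcorstrat.expression import ExpressionMatrix, extract_submatrix
from dcorstrat.variant_io import SMGProfile

import pandas as pd


def literal_dcov_dcor(Ea, Eb):
    """Direct double-loop transcription of the defining equations; the
    independent oracle for the vectorized implementation."""
    Ea, Eb = np.atleast_2d(Ea), np.atleast_2d(Eb)
    N = Ea.shape[1]

    def dist(E):
        D = np.zeros((N, N))
        for j in range(N):
            for k in range(N):
                D[j, k] = np.sqrt(np.sum((E[:, j] - E[:, k]) ** 2))
        return D

    def center(D):
        C = np.zeros((N, N))
        for j in range(N):
            for k in range(N):
                C[j, k] = D[j, k] - D[j, :].mean() - D[:, k].mean() + D.mean()
        return C

    A, B = center(dist(Ea)), center(dist(Eb))
    dcov = sum(A[j, k] * B[j, k] for j in range(N) for k in range(N)) / N**2
    vaa = sum(A[j, k] ** 2 for j in range(N) for k in range(N)) / N**2
    vbb = sum(B[j, k] ** 2 for j in range(N) for k in range(N)) / N**2
    if vaa == 0 or vbb == 0:
        return dcov, 0.0
    return dcov, dcov / np.sqrt(vaa * vbb)


class TestPairwiseColumnDistances:
    def test_one_gene_absolute_differences(self):
        D = pairwise_column_distances(np.array([[0.0, 1.0, 2.0]])).values
        np.testing.assert_allclose(D, [[0, 1, 2], [1, 0, 1], [2, 1, 0]])

    def test_identical_columns_give_zero(self):
        D = pairwise_column_distances(np.array([[1.0, 1.0], [2.0, 2.0]])).values
        assert D[0, 1] == 0.0

    def test_pythagorean_triangle(self):
        D = pairwise_column_distances(np.array([[0.0, 3.0], [0.0, 4.0]])).values
        assert D[0, 1] == pytest.approx(5.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            pairwise_column_distances(np.array([[0.0, np.nan]]))


class TestDoubleCenter:
    def test_hand_example(self):
        C = double_center(np.array([[0.0, 1.0], [1.0, 0.0]])).values
        np.testing.assert_allclose(C, [[-0.5, 0.5], [0.5, -0.5]])

    def test_constant_matrix_centers_to_zero(self):
        C = double_center(np.full((4, 4), 3.0)).values
        np.testing.assert_allclose(C, 0.0, atol=1e-14)

    @settings(derandomize=True, max_examples=50)
    @given(
        arrays(
            float,
            st.integers(2, 6).map(lambda n: (n, n)),
            elements=st.floats(-50, 50, allow_nan=False),
        )
    )
    def test_row_and_column_sums_vanish(self, M):
        C = double_center(M).values
        np.testing.assert_allclose(C.sum(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(C.sum(axis=1), 0.0, atol=1e-9)


class TestDistanceCovariance:
    def test_one_gene_two_sample_value(self):
        # centered distance matrix is [[-.5,.5],[.5,-.5]]; sum of squares / 4
        E = np.array([[0.0, 1.0]])
        assert distance_covariance(E, E) == pytest.approx(0.25)

    def test_constant_profile_gives_zero(self):
        Ea = np.full((2, 5), 7.0)
        Eb = np.random.default_rng(0).normal(size=(3, 5))
        assert distance_covariance(Ea, Eb) == pytest.approx(0.0, abs=1e-14)

    def test_matches_literal_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            Ea = rng.normal(size=(3, 5))
            Eb = rng.normal(size=(2, 5))
            expected, _ = literal_dcov_dcor(Ea, Eb)
            assert distance_covariance(Ea, Eb) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_for_euclidean_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            Ea = rng.normal(size=(2, 6))
            Eb = rng.normal(size=(4, 6))
            assert distance_covariance(Ea, Eb) >= -1e-12

    def test_cohort_size_mismatch_rejected(self):
        with pytest.raises(CohortMismatchError):
            distance_covariance(np.zeros((1, 3)), np.zeros((1, 4)))


class TestDistanceCorrelation:
    def test_self_correlation_is_one(self):
        E = np.random.default_rng(0).normal(size=(3, 6))
        assert distance_correlation(E, E) == pytest.approx(1.0)

    def test_reversed_gradient_has_identical_distances(self):
        # (0,1,2) and (2,1,0) induce the same distance matrix, hence dCor 1
        assert distance_correlation(
            np.array([[0.0, 1.0, 2.0]]), np.array([[2.0, 1.0, 0.0]])
        ) == pytest.approx(1.0)

    def test_degenerate_constant_profile_returns_zero(self):
        Ea = np.full((1, 5), 2.0)
        Eb = np.random.default_rng(1).normal(size=(2, 5))
        assert distance_correlation(Ea, Eb) == 0.0

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            v = distance_correlation(rng.normal(size=(2, 5)), rng.normal(size=(3, 5)))
            assert 0.0 <= v <= 1.0

    def test_invariances(self):
        """Gene permutation, per-gene translation and global positive scaling
        all leave the column distance geometry (hence dCor) unchanged."""
        rng = np.random.default_rng(11)
        Ea = rng.normal(size=(4, 7))
        Eb = rng.normal(size=(3, 7))
        base = distance_correlation(Ea, Eb)
        perm = rng.permutation(4)
        assert distance_correlation(Ea[perm], Eb) == pytest.approx(base, abs=1e-12)
        shifted = Ea + rng.normal(size=(4, 1))
        assert distance_correlation(shifted, Eb) == pytest.approx(base, abs=1e-12)
        assert distance_correlation(3.7 * Ea, Eb) == pytest.approx(base, abs=1e-12)

    def test_detects_nonlinear_dependence_invisible_to_pearson(self):
        # y = x^2 on a symmetric grid: Pearson correlation exactly 0, while
        # dCor is positive; expected value frozen from the literal-equation
        # oracle (the dCov ratio without the square root)
        x = np.array([[-2.0, -1.0, 0.0, 1.0, 2.0]])
        y = x**2
        assert abs(np.corrcoef(x[0], y[0])[0, 1]) < 1e-12
        _, oracle = literal_dcov_dcor(x, y)
        assert oracle == pytest.approx(0.2661770133372712, abs=1e-12)
        assert distance_correlation(x, y) == pytest.approx(oracle, abs=1e-12)
        assert distance_correlation(x, y) > 0.25


class TestDcorMatrix:
    @staticmethod
    def _random_setup(rng, n_patients=5, n_genes=12, n_samples=9):
        genes = [f"G{i}" for i in range(n_genes)]
        samples = [f"S{i}" for i in range(n_samples)]
        expr = ExpressionMatrix(
            data=pd.DataFrame(rng.normal(size=(n_genes, n_samples)), index=genes, columns=samples),
            transform_tag="none",
        )
        profiles = [
            SMGProfile(f"P{i}", frozenset(rng.choice(genes, size=3, replace=False)))
            for i in range(n_patients)
        ]
        return expr, profiles

    def test_identical_profiles_give_unit_off_diagonal(self):
        rng = np.random.default_rng(0)
        expr, _ = self._random_setup(rng)
        same = frozenset(["G0", "G3", "G5"])
        profiles = [SMGProfile("P1", same), SMGProfile("P2", same)]
        D = dcor_matrix(profiles, expr)
        assert D.values[0, 1] == pytest.approx(1.0)

    def test_matches_pairwise_recomputation(self):
        rng = np.random.default_rng(5)
        expr, profiles = self._random_setup(rng)
        D = dcor_matrix(profiles, expr)
        for i, pi in enumerate(profiles):
            for j, pj in enumerate(profiles):
                direct = distance_correlation(
                    extract_submatrix(expr, pi), extract_submatrix(expr, pj)
                )
                assert D.values[i, j] == pytest.approx(direct, abs=1e-10)

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(9)
        expr, profiles = self._random_setup(rng, n_patients=6)
        D = dcor_matrix(profiles, expr)
        np.testing.assert_allclose(D.values, D.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(D.values), 1.0)
        assert not any(D.degenerate_flags.values())

    def test_unmatchable_profiles_dropped(self):
        rng = np.random.default_rng(2)
        expr, profiles = self._random_setup(rng, n_patients=3)
        profiles.append(SMGProfile("PX", frozenset(["ABSENT"])))
        D = dcor_matrix(profiles, expr)
        assert D.n_patients == 3
        assert "PX" not in D.patient_ids

    def test_fewer_than_two_matchable_profiles_rejected(self):
        rng = np.random.default_rng(2)
        expr, _ = self._random_setup(rng)
        with pytest.raises(ValueError, match="matchable"):
            dcor_matrix([SMGProfile("P1", frozenset(["G0"]))], expr)

    def test_run_is_reproducible(self):
        rng = np.random.default_rng(21)
        expr, profiles = self._random_setup(rng)
        D1 = dcor_matrix(profiles, expr)
        D2 = dcor_matrix(profiles, expr)
        np.testing.assert_array_equal(D1.values, D2.values)


def test_optimized_equals_literal_oracle_many_instances():
    """Sweep of random small instances: vectorized dCor vs the equation
    transcription, to 1e-12."""
    rng = np.random.default_rng(123)
    worst = 0.0
    for _ in range(60):
        N = int(rng.integers(2, 9))
        Ea = rng.normal(size=(int(rng.integers(1, 5)), N))
        Eb = rng.normal(size=(int(rng.integers(1, 5)), N))
        _, expected = literal_dcov_dcor(Ea, Eb)
        worst = max(worst, abs(distance_correlation(Ea, Eb) - expected))
    assert worst < 1e-12
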