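"""Pearson matrices, difference-matrix 2-sigma screening, t-test and coverage."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from proteocohere import (difference_matrix, gaussian_coverage, hub_intersection,
                          one_sample_t_test, pearson_matrix, screen_stages,
                          two_sigma_gene_screen)
from proteocohere.correlation_screen import CorrelationMatrix, DifferenceMatrix

from conftest import make_matrix, staged_random_matrix


def brute_force_pearson(x):
    """Independent double-loop implementation with 1/n moments."""
    g, n = x.shape
    r = np.eye(g)
    for i in range(g):
        for j in range(g):
            xi, xj = x[i], x[j]
            cov = np.sum((xi - xi.mean()) * (xj - xj.mean())) / n
            r[i, j] = cov / (xi.std() * xj.std())
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1, 1)


class TestPearsonMatrix:
    def test_matches_brute_force_oracle(self, rng):
        m = make_matrix(rng.normal(size=(10, 10)))
        r = pearson_matrix(m)
        np.testing.assert_allclose(r.values, brute_force_pearson(m.values),
                                   atol=1e-12)
        # cross-check against the standard library implementation
        np.testing.assert_allclose(r.values, np.corrcoef(m.values), atol=1e-12)

    def test_identical_rows_correlate_perfectly(self):
        m = make_matrix([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert pearson_matrix(m).values[0, 1] == pytest.approx(1.0)

    def test_reversed_rows_anticorrelate(self):
        m = make_matrix([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert pearson_matrix(m).values[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        m = make_matrix([[1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0]])
        assert pearson_matrix(m).values[0, 1] == pytest.approx(0.8, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    def test_affine_invariance_of_rows(self, a, b):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(3, 8))
        base = pearson_matrix(make_matrix(x)).values
        y = x.copy()
        y[0] = a * x[0] + b
        scaled = pearson_matrix(make_matrix(y)).values
        np.testing.assert_allclose(scaled, base, atol=1e-9)
        y[0] = -a * x[0] + b
        flipped = pearson_matrix(make_matrix(y)).values
        np.testing.assert_allclose(flipped[0, 1:], -base[0, 1:], atol=1e-9)

    def test_zero_variance_strict_names_gene(self):
        m = make_matrix([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                        gene_ids=["FLAT", "OK"])
        with pytest.raises(ValueError, match="FLAT"):
            pearson_matrix(m)

    def test_zero_variance_lenient_marks_undefined(self):
        m = make_matrix([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]],
                        gene_ids=["FLAT", "A", "B"])
        r = pearson_matrix(m, mode="lenient")
        assert np.isnan(r.values[0, 1]) and np.isnan(r.values[2, 0])
        assert r.values[0, 0] == 1.0
        assert np.isfinite(r.values[1, 2])

    def test_stage_restriction_uses_stage_samples_only(self, rng):
        m = staged_random_matrix(rng, n_genes=4, sizes=(5, 4, 4, 4))
        r = pearson_matrix(m, "CON")
        assert r.stage == "CON" and r.n_samples == 5
        con = m.restrict_stage("CON")
        np.testing.assert_allclose(r.values, np.corrcoef(con.values), atol=1e-12)


class TestDifferenceMatrix:
    def _corr(self, values, stage):
        return CorrelationMatrix(values=values, gene_ids=["A", "B"],
                                 stage=stage, n_samples=5)

    def test_self_difference_is_zero(self):
        r = self._corr(np.array([[1.0, 0.4], [0.4, 1.0]]), "CON")
        s = self._corr(np.array([[1.0, 0.4], [0.4, 1.0]]), "INC")
        np.testing.assert_array_equal(difference_matrix(s, r).values, 0)

    def test_elementwise_subtraction_and_zero_diagonal(self):
        r = self._corr(np.array([[1.0, 0.2], [0.2, 1.0]]), "CON")
        s = self._corr(np.array([[1.0, 0.9], [0.9, 1.0]]), "SEV")
        d = difference_matrix(s, r)
        assert d.values[0, 1] == pytest.approx(0.7)
        assert np.all(np.diag(d.values) == 0)

    def test_gene_order_mismatch_rejected(self):
        r = self._corr(np.eye(2), "CON")
        s = CorrelationMatrix(values=np.eye(2), gene_ids=["B", "A"],
                              stage="INC", n_samples=5)
        with pytest.raises(ValueError, match="order"):
            difference_matrix(s, r)

    def test_reference_must_be_control(self):
        r = self._corr(np.eye(2), "INC")
        s = self._corr(np.eye(2), "SEV")
        with pytest.raises(ValueError, match="CON"):
            difference_matrix(s, r)


def _diff_from_upper(upper, g):
    """Build a DifferenceMatrix whose strict upper triangle is ``upper``."""
    values = np.zeros((g, g))
    iu = np.triu_indices(g, k=1)
    values[iu] = upper
    values = values + values.T
    return DifferenceMatrix(values=values, gene_ids=[f"G{i}" for i in range(g)],
                            stage_pair=("SEV", "CON"))


class TestTwoSigmaScreen:
    def test_hand_computed_threshold_flags_single_outlier(self):
        # upper triangle {0 x 9, 5}: mean 0.5, population sigma 1.5, threshold 3.5
        d = _diff_from_upper([0] * 9 + [5], g=5)
        screen = two_sigma_gene_screen(d, k=2)
        assert screen.threshold == pytest.approx(3.5)
        assert screen.flagged_pairs == {("G3", "G4")}
        assert screen.gene_set == {"G3", "G4"}

    def test_tie_at_threshold_not_flagged(self):
        # same multiset with k=3: threshold 0.5 + 3*1.5 = 5.0 exactly
        d = _diff_from_upper([0] * 9 + [5], g=5)
        screen = two_sigma_gene_screen(d, k=3)
        assert screen.threshold == 5.0
        assert screen.flagged_pairs == set()

    def test_symmetric_triangle_has_no_flags(self):
        d = _diff_from_upper([-1, 0, 1], g=3)
        assert two_sigma_gene_screen(d, k=2).flagged_pairs == set()

    def test_constant_triangle_is_degenerate(self):
        d = _diff_from_upper([0.3, 0.3, 0.3], g=3)
        screen = two_sigma_gene_screen(d)
        assert screen.degenerate and screen.flagged_pairs == set()

    def test_two_sided_catches_lower_tail(self):
        d = _diff_from_upper([0] * 9 + [-5], g=5)
        assert two_sigma_gene_screen(d, sidedness="upper").flagged_pairs == set()
        assert two_sigma_gene_screen(d, sidedness="two_sided").gene_set == {"G3", "G4"}

    def test_min_pair_count_filters_genes(self):
        d = _diff_from_upper([0] * 9 + [5], g=5)
        screen = two_sigma_gene_screen(d, min_pair_count=2)
        assert screen.flagged_pairs == {("G3", "G4")}
        assert screen.gene_set == set()

    def test_raising_k_never_enlarges_flags(self, rng):
        d = _diff_from_upper(rng.normal(size=45), g=10)
        previous = two_sigma_gene_screen(d, k=1).flagged_pairs
        for k in (1.5, 2.0, 2.5, 3.0):
            current = two_sigma_gene_screen(d, k=k).flagged_pairs
            assert current <= previous
            previous = current


class TestHubIntersection:
    def test_set_algebra(self):
        assert hub_intersection([{"A", "B", "C"}, {"B", "C", "D"}, {"B", "C"}]) == ("B", "C")

    def test_disjoint_sets_empty(self):
        assert hub_intersection([{"A"}, {"B"}, {"C"}]) == ()

    def test_exactly_three_sets_required(self):
        with pytest.raises(ValueError, match="3"):
            hub_intersection([{"A"}, {"B"}])

    def test_order_invariance(self):
        sets = [{"A", "B"}, {"B", "C"}, {"B"}]
        assert hub_intersection(sets) == hub_intersection(sets[::-1])


class TestScreenStages:
    def test_omega_is_intersection_of_stage_gene_sets(self, default_cohort):
        expr, _, _ = default_cohort
        res = screen_stages(expr)
        expected = (res.screens["INC"].gene_set
                    & res.screens["MOD"].gene_set
                    & res.screens["SEV"].gene_set)
        assert set(res.omega) == expected

    def test_pair_mode_is_at_least_as_strict(self, default_cohort):
        expr, _, _ = default_cohort
        genes = set(screen_stages(expr, intersection_mode="genes").omega)
        pairs = set(screen_stages(expr, intersection_mode="pairs").omega)
        assert pairs <= genes


class TestTTest:
    def test_mean_equal_to_reference(self):
        res = one_sample_t_test([1, 2, 3], ref_mean=2)
        assert res.t == pytest.approx(0) and res.p == pytest.approx(1)

    def test_frozen_reference_example(self):
        res = one_sample_t_test([1, 2, 3, 4, 5], ref_mean=2)
        assert res.t == pytest.approx(1.414214, abs=1e-6)
        assert res.df == 4
        assert res.p == pytest.approx(0.2302, abs=1e-4)
        assert not res.reject

    def test_zero_spread_undefined(self):
        with pytest.raises(ValueError, match="spread"):
            one_sample_t_test([5, 5, 5], ref_mean=4)

    def test_t_sign_follows_mean_difference(self):
        assert one_sample_t_test([1, 2, 3], ref_mean=5).t < 0
        assert one_sample_t_test([1, 2, 3], ref_mean=0).t > 0


class TestGaussianCoverage:
    @pytest.mark.parametrize("k,expected", [(1, 0.6826), (2, 0.9544), (3, 0.9974)])
    def test_printed_coverage_values(self, k, expected):
        # the reference values are truncated to 4 decimals, so compare |diff|
        assert gaussian_coverage(k) == pytest.approx(expected, abs=1e-4)

    def test_coverage_plus_tails_is_one(self):
        from scipy.stats import norm
        for k in (0.5, 1, 1.7, 2, 3):
            assert gaussian_coverage(k) + 2 * norm.sf(k) == pytest.approx(1, abs=1e-12)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            gaussian_coverage(0)
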