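"""Determinant, eigenvalue-occupancy entropy and subset-determinant entropy."""
import math

import numpy as np
import pytest

from proteocohere import (determinant_entropy, disorder_summary, pearson_matrix,
                          subset_determinants, system_determinant, system_entropy)
from proteocohere.correlation_screen import CorrelationMatrix
from proteocohere.disorder_metrics import SubsetDeterminantSet

from conftest import make_matrix, staged_random_matrix


def corr(values):
    values = np.asarray(values, dtype=float)
    return CorrelationMatrix(values=values,
                             gene_ids=[f"G{i}" for i in range(len(values))],
                             stage=None, n_samples=10)


def equicorrelation(g, r):
    return corr(np.full((g, g), r) + (1 - r) * np.eye(g))


def _force(values):
    """Bypass the symmetric constructor check to probe the operation's guard."""
    obj = CorrelationMatrix.__new__(CorrelationMatrix)
    obj.values = np.asarray(values, dtype=float)
    obj.gene_ids = [f"G{i}" for i in range(len(values))]
    obj.stage = None
    obj.n_samples = 5
    return obj


class TestSystemDeterminant:
    def test_identity_has_unit_volume(self):
        assert system_determinant(corr(np.eye(3))) == pytest.approx(1.0)

    def test_two_gene_closed_form(self):
        assert system_determinant(equicorrelation(2, 0.6)) == pytest.approx(0.64, abs=1e-12)

    def test_three_gene_equicorrelation_closed_form(self):
        # (1 - r)^2 (1 + 2r) at r = 0.5
        assert system_determinant(equicorrelation(3, 0.5)) == pytest.approx(0.5, abs=1e-12)

    def test_asymmetric_input_rejected(self):
        bad = np.eye(3)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError, match="asymmetric"):
            system_determinant(_force(bad))

    def test_determinant_in_unit_interval_on_random_correlations(self, rng):
        for _ in range(20):
            x = rng.normal(size=(6, 30))
            r = pearson_matrix(make_matrix(x))
            det = system_determinant(r)
            assert -1e-9 <= det <= 1 + 1e-9


class TestSystemEntropy:
    def test_identity_attains_maximum(self):
        _, h = system_entropy(corr(np.eye(3)))
        assert h == pytest.approx(math.log2(3), abs=1e-12)

    def test_rank_one_matrix_has_zero_entropy(self):
        _, h = system_entropy(corr(np.ones((3, 3))))
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_equicorrelation_entropy(self):
        # r = 0.5: eigenvalues (2, 0.5, 0.5) -> P = (8/9, 1/18, 1/18)
        spec, h = system_entropy(equicorrelation(3, 0.5))
        np.testing.assert_allclose(spec.eigenvalues, [2, 0.5, 0.5], atol=1e-12)
        assert h == pytest.approx(0.614370, abs=1e-6)

    def test_occupancy_sums_to_one_and_trace_conserved(self, rng):
        x = rng.normal(size=(7, 25))
        r = pearson_matrix(make_matrix(x))
        spec, h = system_entropy(r)
        assert spec.occupancy.sum() == pytest.approx(1, abs=1e-12)
        assert spec.eigenvalues.sum() == pytest.approx(7, abs=1e-9)
        assert 0 <= h <= math.log2(7)

    def test_equicorrelation_family_monotone_decline(self):
        """det and entropy both strictly decrease as coupling rises."""
        dets, ents = [], []
        for r in np.arange(0.0, 0.95, 0.1):
            m = equicorrelation(5, r)
            dets.append(system_determinant(m))
            ents.append(system_entropy(m)[1])
        assert all(a > b for a, b in zip(dets, dets[1:]))
        assert all(a > b for a, b in zip(ents, ents[1:]))


def brute_force_subset_dets(x, dim):
    """Independent enumeration oracle using numpy's corrcoef."""
    from itertools import combinations
    out = []
    for cols in combinations(range(x.shape[1]), dim):
        sub = x[:, cols]
        if (sub.std(axis=1) == 0).any():
            out.append(None)
            continue
        out.append(float(np.linalg.det(np.corrcoef(sub))))
    return out


class TestSubsetDeterminants:
    def test_subset_count_is_binomial(self, rng):
        m = staged_random_matrix(rng, n_genes=3, sizes=(5, 4, 4, 4))
        s = subset_determinants(m, dim=4, stage="CON")
        assert s.n_subsets == 5 == math.comb(5, 4)

    def test_dim_equal_to_gene_count_forces_singularity(self, rng):
        m = staged_random_matrix(rng, n_genes=3, sizes=(6, 4, 4, 4))
        s = subset_determinants(m, dim=3, stage="CON")
        assert np.all(np.abs(s.values) <= 1e-9)

    def test_matches_brute_force_oracle(self, rng):
        m = staged_random_matrix(rng, n_genes=3, sizes=(6, 4, 4, 4))
        s = subset_determinants(m, dim=4, stage="CON")
        expected = [v for v in brute_force_subset_dets(
            m.restrict_stage("CON").values, 4) if v is not None]
        clipped = [0.0 if -1e-9 < v < 0 else v for v in expected]
        np.testing.assert_allclose(s.values, clipped, atol=1e-12)

    def test_zero_variance_subsets_reported_undefined(self):
        values = np.array([[1.0, 1.0, 1.0, 2.0, 3.0],
                           [1.0, 2.0, 3.0, 4.0, 5.0],
                           [2.0, 1.0, 3.0, 5.0, 4.0]])
        m = make_matrix(values)
        s = subset_determinants(m, dim=3)
        assert s.n_undefined >= 1
        assert s.values.size + s.n_undefined == math.comb(5, 3)

    def test_dim_larger_than_group_rejected(self, rng):
        m = staged_random_matrix(rng, n_genes=3, sizes=(4, 4, 4, 4))
        with pytest.raises(ValueError, match="exceeds"):
            subset_determinants(m, dim=5, stage="CON")


def dset(values, group="CON", dim=4):
    values = np.asarray(values, dtype=float)
    return SubsetDeterminantSet(group=group, dim=dim, values=values,
                                n_subsets=values.size)


class TestDeterminantEntropy:
    def test_two_equal_bins_give_one_bit(self):
        hists = determinant_entropy({"CON": dset([0, 0, 1, 1])},
                                    bin_width_override=0.5)
        assert hists["CON"].entropy == pytest.approx(1.0)

    def test_constant_group_has_zero_entropy(self):
        hists = determinant_entropy({"CON": dset([0.4, 0.4, 0.4])},
                                    bin_width_override=0.1)
        assert hists["CON"].entropy == 0.0

    def test_uniform_occupancy_gives_log2_k(self):
        values = [0.1, 0.2, 1.1, 1.2, 2.1, 2.2]  # three bins of width 1, two each
        hists = determinant_entropy({"CON": dset(values)}, bin_width_override=1.0)
        assert hists["CON"].entropy == pytest.approx(math.log2(3), abs=1e-12)

    def test_bin_width_is_pooled_sigma_over_ten(self, rng):
        groups = {s: dset(rng.uniform(size=30), group=s)
                  for s in ("CON", "INC", "MOD", "SEV")}
        pooled = np.concatenate([g.values for g in groups.values()])
        hists = determinant_entropy(groups)
        assert hists["CON"].bin_width == pytest.approx(pooled.std() / 10)

    def test_affine_invariance_under_shared_transform(self, rng):
        groups = {s: dset(rng.uniform(size=25), group=s)
                  for s in ("CON", "INC", "MOD", "SEV")}
        base = determinant_entropy(groups)
        moved = {s: dset(2.5 * g.values + 7.0, group=s) for s, g in groups.items()}
        after = determinant_entropy(moved)
        for s in groups:
            assert after[s].entropy == base[s].entropy

    def test_identical_constant_groups_degenerate(self):
        groups = {s: dset([0.2, 0.2], group=s) for s in ("CON", "INC")}
        hists = determinant_entropy(groups)
        assert all(h.entropy == 0.0 and h.degenerate for h in hists.values())

    def test_mismatched_dims_rejected(self):
        with pytest.raises(ValueError, match="share"):
            determinant_entropy({"CON": dset([0.1], dim=3), "INC": dset([0.2], dim=4)})


class TestDisorderSummary:
    def test_summary_fields_and_ranges(self, default_cohort):
        expr, _, truth = default_cohort
        ds = disorder_summary(expr, truth.hub_genes, dims=(3, 5))
        for stage in ("CON", "INC", "MOD", "SEV"):
            assert 0 <= ds.determinant[stage] <= 1
            assert 0 <= ds.system_entropy[stage] <= math.log2(3) + 1e-12
            assert ds.determinant_entropy[5][stage] >= 0
        # dim == hub size: all subset determinants are 0, entropy degenerate at 0
        assert all(h == 0 for h in ds.determinant_entropy[3].values())
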