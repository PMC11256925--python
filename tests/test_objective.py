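import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossbic import Params, select_genes
from crossbic.objective import (
    delta,
    evaluate,
    gene_contribution,
    negative_fraction,
    omega,
)
from _helpers import brute_force_gene_selection, make_expression, random_instance


class TestOmega:
    def test_direct_evaluation(self):
        # in-cluster (2.0, 1.5), out-of-cluster (0.5, -1.0), kappa 0.1
        m, _ = make_expression([[2.0, 1.5, 0.5, -1.0]], ["A"] * 4)
        assert omega(m, 0, [0, 1, 2, 3], [0, 1], kappa=0.1) == pytest.approx(3.45)

    def test_disjoint_sample_and_negative_outside(self):
        m, _ = make_expression([[-1.0, -2.0]], ["A"] * 2)
        assert omega(m, 0, [0, 1], [], kappa=1.0) == 0.0

    def test_symmetric_cancellation(self):
        m, _ = make_expression([[1.0, 1.0]], ["A"] * 2)
        assert omega(m, 0, [0, 1], [0], kappa=1.0) == 0.0


class TestDelta:
    def test_equal_values_give_one(self):
        assert delta([3.0, 3.0, 3.0]) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert delta([4.0, 0.1]) == pytest.approx(math.sqrt(0.4) / 2.05)

    def test_negative_values_clipped(self):
        assert delta([-2.0, 5.0]) == pytest.approx(math.sqrt(0.5) / 2.55)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            delta([])

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=6),
        st.floats(0.01, 1.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_am_gm_bound(self, omegas, eps):
        """delta in (0, 1], equal to 1 iff all clipped values coincide."""
        d = delta(omegas, eps)
        assert 0 < d <= 1 + 1e-12
        clipped = np.maximum(omegas, eps)
        if np.allclose(clipped, clipped[0]):
            assert d == pytest.approx(1.0)
        elif np.max(clipped) / np.min(clipped) > 1.001:
            assert d < 1.0


class TestGeneContribution:
    def test_single_sample_reduces_to_whole_dataset_omega(self):
        m, sm = make_expression([[2.0, -1.0, 0.5, 1.0]], ["A"] * 4)
        gs = gene_contribution(m, 0, [0, 3], sm, Params(kappa=0.5))
        assert gs.delta == 1.0
        assert gs.contribution == pytest.approx(omega(m, 0, range(4), [0, 3], 0.5))

    def test_sample_specific_gene_downweighted(self):
        # omega = (10, -1, -1) across three samples
        m, sm = make_expression(
            [[10.0, -1.0, -1.0]], ["A", "B", "C"]
        )
        gs = gene_contribution(m, 0, [0, 1, 2], sm, Params(kappa=1.0))
        assert gs.omega_per_sample == {"A": 10.0, "B": -1.0, "C": -1.0}
        expected = ((0.1 * 0.1 * 10.0) ** (1 / 3)) / (10.2 / 3) * 8.0
        assert gs.contribution == pytest.approx(expected)  # ~1.0922, not 8

    def test_all_clipped_equal_gives_delta_one(self):
        m, sm = make_expression([[0.05, 0.05]], ["A", "B"])
        gs = gene_contribution(m, 0, [0, 1], sm, Params(kappa=1.0))
        assert gs.delta == pytest.approx(1.0)
        assert gs.contribution == pytest.approx(0.1)


class TestNegativeFraction:
    def test_counting(self):
        m, _ = make_expression([[1, 1, -1], [1, 1, 1]], ["A"] * 3)
        assert negative_fraction(m, [0, 1], [0, 1, 2]) == pytest.approx(1 / 6)

    @pytest.mark.parametrize("sign,expected", [(1.0, 0.0), (-1.0, 1.0)])
    def test_extremes(self, sign, expected):
        m, _ = make_expression(np.full((2, 3), sign), ["A"] * 3)
        assert negative_fraction(m, [0, 1], [0, 1, 2]) == expected

    def test_empty_rejected(self):
        m, _ = make_expression([[1.0]], ["A"])
        with pytest.raises(ValueError):
            negative_fraction(m, [], [0])


class TestSelectGenes:
    def test_no_negatives_keeps_all_positive_contributions(self):
        m, sm = make_expression(
            [[2.0, 2.0], [1.0, 1.0], [-1.0, -1.0]], ["A", "B"]
        )
        b = select_genes(m, [0, 1], sm, Params(kappa=1.0))
        assert b.genes.tolist() == [0, 1]

    def test_mu_zero_excludes_any_negative(self):
        m, sm = make_expression(
            [[2.0, 2.0], [3.0, -0.5]], ["A", "B"]
        )
        b = select_genes(m, [0, 1], sm, Params(kappa=1.0, mu=0.0))
        assert b.genes.tolist() == [0]

    def test_no_positive_contribution_returns_empty(self):
        m, sm = make_expression(np.full((3, 4), -1.0), ["A", "A", "B", "B"])
        b = select_genes(m, [0, 2], sm, Params(kappa=1.0))
        assert b.is_empty and b.objective == 0.0

    def test_matches_brute_force_enumeration(self):
        """Exact DP equals exhaustive gene-subset enumeration (100 instances)."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            m, sm, params = random_instance(rng, max_cells=8, max_genes=8)
            J = sorted(
                rng.choice(m.n_cells, size=int(rng.integers(1, m.n_cells + 1)), replace=False)
            )
            oracle_obj, _ = brute_force_gene_selection(m, J, sm, params)
            b = select_genes(m, J, sm, params)
            assert b.objective == pytest.approx(oracle_obj, abs=1e-9)
            if not b.is_empty:
                assert b.neg_fraction <= params.mu + 1e-12

    def test_positive_gene_count_non_increasing_in_kappa(self):
        """Raising the out-of-cluster penalty can only retire genes."""
        rng = np.random.default_rng(12)
        for _ in range(10):
            m, sm, _ = random_instance(rng, max_cells=10, max_genes=10)
            J = [0, 1, m.n_cells - 1]
            counts = []
            for k in (0.05, 0.2, 0.5, 1.0, 2.0, 5.0):
                params = Params(kappa=k)
                counts.append(
                    sum(
                        gene_contribution(m, i, J, sm, params).contribution > 0
                        for i in range(m.n_genes)
                    )
                )
            assert counts == sorted(counts, reverse=True)

    def test_single_sample_equals_delta_one_on_merged_samples(self):
        """|S|=1 and the delta==1 override both give the single-sample objective."""
        rng = np.random.default_rng(13)
        values = rng.normal(0, 1.5, size=(6, 8))
        m, sm2 = make_expression(values, ["A"] * 4 + ["B"] * 4)
        m1, sm1 = make_expression(values, ["all"] * 8)
        params = Params(kappa=0.5)
        J = [1, 2, 5, 6]
        single = select_genes(m1, J, sm1, params)
        merged = select_genes(m, J, sm2, Params(kappa=0.5, delta_one=True))
        assert merged.objective == pytest.approx(single.objective)

    def test_permutation_equivariance(self):
        """Relabeling cells within samples or reordering samples changes nothing."""
        rng = np.random.default_rng(14)
        values = rng.normal(0, 1.5, size=(6, 8))
        labels = ["A"] * 4 + ["B"] * 4
        m, sm = make_expression(values, labels)
        params = Params(kappa=0.5)
        J = [0, 2, 4, 6]
        base = select_genes(m, J, sm, params).objective
        # permute cells within each sample
        perm = np.array([1, 0, 3, 2, 7, 6, 5, 4])
        mp, smp = make_expression(values[:, perm], [labels[j] for j in perm])
        Jp = [int(np.flatnonzero(perm == j)[0]) for j in J]
        assert select_genes(mp, Jp, smp, params).objective == pytest.approx(base)
        # reorder samples (swap blocks)
        swap = np.r_[4:8, 0:4]
        ms, sms = make_expression(values[:, swap], [labels[j] for j in swap])
        Js = [int(np.flatnonzero(swap == j)[0]) for j in J]
        assert select_genes(ms, Js, sms, params).objective == pytest.approx(base)


class TestEvaluate:
    def test_reports_user_bicluster(self):
        m, sm = make_expression([[2.0, 2.0], [-1.0, 3.0]], ["A", "B"])
        b = evaluate(m, [0, 1], [0, 1], sm, Params(kappa=1.0))
        assert b.genes.tolist() == [0, 1]
        assert b.neg_fraction == pytest.approx(0.25)
        assert b.objective == pytest.approx(sum(g.contribution for g in b.gene_stats))

    def test_out_of_range_indices_rejected(self):
        m, sm = make_expression([[1.0, 1.0]], ["A", "B"])
        with pytest.raises(IndexError):
            evaluate(m, [5], [0], sm)
        with pytest.raises(IndexError):
            evaluate(m, [0], [7], sm)
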