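import math

import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

from dmvg import (
    LN2,
    IrreversibilityReport,
    TimeSeriesPanel,
    annotate_significance,
    degree_table,
    estimate_joint_distribution,
    jsd,
    kld,
    korder_irreversibility,
    reverse_panel,
    sweep_level,
    unique_contributions,
)


@pytest.fixture
def tables(rng):
    panels = [TimeSeriesPanel(rng.standard_normal((4, 80))) for _ in range(5)]
    return [degree_table(p) for p in panels]


class TestKld:
    def test_identity_is_zero(self):
        assert kld([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_hand_value(self):
        expected = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)
        assert kld([0.5, 0.5], [0.25, 0.75]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.14384, abs=5e-6)

    def test_asymmetry(self):
        assert kld([0.5, 0.5], [0.25, 0.75]) != kld([0.25, 0.75], [0.5, 0.5])

    def test_zero_q_bin_named(self):
        with pytest.raises(ValueError, match="bin"):
            kld([0.5, 0.5], [1.0, 0.0])

    def test_zero_p_bin_contributes_nothing(self):
        assert kld([1.0, 0.0], [0.5, 0.5]) == pytest.approx(math.log(2))

    def test_mismatched_support_error(self):
        with pytest.raises(ValueError):
            kld([0.5, 0.5], [0.2, 0.3, 0.5])

    def test_sparse_matches_dense(self, tables):
        p = estimate_joint_distribution(tables, (0,), "in", dmax=12)
        q = estimate_joint_distribution(tables, (0,), "out", dmax=12)
        dense_p = np.array([p.mass((d,)) for d in range(1, 13)])
        dense_q = np.array([q.mass((d,)) for d in range(1, 13)])
        assert kld(p, q) == pytest.approx(kld(dense_p, dense_q), abs=1e-12)

    def test_sparse_support_mismatch(self, tables):
        p = estimate_joint_distribution(tables, (0,), "in", dmax=12)
        q = estimate_joint_distribution(tables, (0,), "out", dmax=10)
        with pytest.raises(ValueError, match="support"):
            kld(p, q)


class TestJsd:
    def test_identity_and_symmetry(self, rng):
        p = rng.dirichlet(np.ones(8))
        q = rng.dirichlet(np.ones(8))
        assert jsd(p, p) == 0.0
        assert jsd(p, q) == pytest.approx(jsd(q, p), abs=1e-15)

    def test_disjoint_point_masses_reach_ln2(self):
        assert jsd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(LN2, abs=1e-15)

    def test_bounded_by_ln2(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            assert 0.0 <= jsd(p, q) <= LN2 + 1e-12

    def test_matches_scipy_on_dense(self, rng):
        p = rng.dirichlet(np.ones(10))
        q = rng.dirichlet(np.ones(10))
        assert jsd(p, q) == pytest.approx(jensenshannon(p, q) ** 2, abs=1e-10)

    def test_sparse_matches_dense_joint(self, tables):
        dmax = 9
        p = estimate_joint_distribution(tables, (0, 1), "in", dmax=dmax)
        q = estimate_joint_distribution(tables, (0, 1), "out", dmax=dmax)
        grid = [(a, b) for a in range(1, dmax + 1) for b in range(1, dmax + 1)]
        dense_p = np.array([p.mass(b) for b in grid])
        dense_q = np.array([q.mass(b) for b in grid])
        assert jsd(p, q) == pytest.approx(jsd(dense_p, dense_q), abs=1e-12)


class TestKOrderIrreversibility:
    def test_time_symmetric_panel_is_exactly_zero(self):
        panel = TimeSeriesPanel(np.array([[1.0, 3, 2, 3, 1], [0.0, 2, 5, 2, 0]]))
        for layers in [(0,), (1,), (0, 1)]:
            assert korder_irreversibility([degree_table(panel)], layers) == 0.0

    def test_reversal_invariance(self, rng):
        panels = [TimeSeriesPanel(rng.standard_normal((3, 100))) for _ in range(3)]
        fwd = [degree_table(p) for p in panels]
        bwd = [degree_table(reverse_panel(p)) for p in panels]
        for layers in [(0,), (1, 2), (0, 1, 2)]:
            assert korder_irreversibility(fwd, layers) == pytest.approx(
                korder_irreversibility(bwd, layers), abs=1e-12
            )

    def test_tuple_order_invariance(self, tables):
        assert korder_irreversibility(tables, (0, 2)) == pytest.approx(
            korder_irreversibility(tables, (2, 0)), abs=1e-15
        )

    def test_bounds(self, tables):
        s = korder_irreversibility(tables, (0, 1, 2, 3))
        assert 0.0 <= s <= LN2

    def test_independent_layers_joint_factorises(self, rng):
        # independent variables: the unsmoothed joint approaches the product
        # of its marginals as the pooled sample grows
        def tv_from_product(n_samples):
            panels = [TimeSeriesPanel(rng.standard_normal((2, 150)))
                      for _ in range(n_samples)]
            tabs = [degree_table(p) for p in panels]
            dmax = 8
            joint = estimate_joint_distribution(tabs, (0, 1), "in", dmax=dmax,
                                                smoothing=False)
            m0 = estimate_joint_distribution(tabs, (0,), "in", dmax=dmax,
                                             smoothing=False)
            m1 = estimate_joint_distribution(tabs, (1,), "in", dmax=dmax,
                                             smoothing=False)
            tv = 0.0
            for a in range(1, dmax + 1):
                for b in range(1, dmax + 1):
                    tv += abs(joint.mass((a, b)) - m0.mass((a,)) * m1.mass((b,)))
            return 0.5 * tv

        assert tv_from_product(60) < tv_from_product(4)
        assert tv_from_product(60) < 0.1


class TestSweepAndAnnotations:
    def test_tuple_counts(self, rng):
        panels = [TimeSeriesPanel(rng.standard_normal((6, 60))) for _ in range(2)]
        tabs = [degree_table(p) for p in panels]
        assert len(sweep_level(tabs, 2).entries) == 15
        assert len(sweep_level(tabs, 3).entries) == 20

    def test_level_one_matches_single_calls(self, tables):
        rep = sweep_level(tables, 1)
        for (layers, s) in rep.entries:
            direct = korder_irreversibility(tables, layers, dmax=rep.dmax_used)
            assert s == pytest.approx(direct, abs=1e-15)

    def test_level_mean_and_sd(self, tables):
        rep = sweep_level(tables, 2)
        sigmas = [s for _, s in rep.entries]
        assert rep.level_mean == pytest.approx(np.mean(sigmas))
        assert rep.level_sd == pytest.approx(np.std(sigmas, ddof=0))

    def test_k_out_of_range(self, tables):
        with pytest.raises(ValueError):
            sweep_level(tables, 0)
        with pytest.raises(ValueError):
            sweep_level(tables, 9)

    def _report(self, sigmas):
        entries = [((i,), float(s)) for i, s in enumerate(sigmas)]
        return IrreversibilityReport(
            level_k=1, entries=entries, level_mean=0.0, level_sd=0.0,
            annotations={}, dmax_used=10, n_samples=1,
        )

    def test_equal_sigmas_get_no_annotations(self):
        rep = annotate_significance(self._report([0.2] * 5))
        assert rep.sd_is_zero
        assert set(rep.annotations.values()) == {0}

    def test_floor_rule(self):
        # outlier at +2.236 SD -> 2 stars; the rest at -0.447 SD -> none
        rep = annotate_significance(self._report([1, 1, 1, 1, 1, 2]))
        assert rep.annotations[(5,)] == 2
        assert all(rep.annotations[(i,)] == 0 for i in range(5))

    def test_exactly_one_sd_below_gets_one_dagger(self):
        # values {1, 3}: mean 2, sd 1 -> z = -1 and +1 exactly
        rep = annotate_significance(self._report([1.0, 3.0]))
        assert rep.annotations[(0,)] == -1
        assert rep.annotations[(1,)] == 1


class TestUniqueContributions:
    def test_singletons_equal_sigma(self):
        table = unique_contributions({(0,): 0.3, (1,): 0.1})
        assert table.eta[(0,)] == 0.3 and table.eta[(1,)] == 0.1

    def test_pair_formula(self):
        sig = {(0,): 0.2, (1,): 0.3, (0, 1): 0.7}
        table = unique_contributions(sig)
        assert table.eta[(0, 1)] == pytest.approx(0.7 - 0.2 - 0.3)

    def test_reconstruction_identity_random_table(self, rng):
        from itertools import combinations

        sig = {}
        for k in range(1, 7):
            for c in combinations(range(6), k):
                sig[c] = float(rng.uniform(0, LN2))
        assert len(sig) == 62 + 1  # all nonempty tuples of 6 elements: 63
        table = unique_contributions(sig)
        for c in sig:
            assert table.reconstruct(c) == pytest.approx(sig[c], abs=1e-10)

    def test_missing_subset_named(self):
        with pytest.raises(ValueError, match=r"\(1,\)"):
            unique_contributions({(0,): 0.1, (0, 1): 0.5})
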