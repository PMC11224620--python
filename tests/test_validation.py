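"""Validation statistics: BH, rank-sum, Fisher overlaps, enrichment curve."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from modhub import (
    DEGTable,
    FunctionalNetwork,
    bh_adjust,
    deg_connectivity_test,
    fisher_overlap,
    rank_enrichment_curve,
    signed_overlap,
)
from modhub.validation import _exact_ranksum_p_greater

from conftest import (
    deg_frame,
    enumerate_ranksum_p_greater,
    hypergeom_tail_by_enumeration,
    random_network,
)


class TestBHAdjust:
    def test_step_up_enumeration(self):
        # p(i)*n/i = (0.04, 0.04, 0.04, 0.04); cumulative min keeps 0.04
        assert list(bh_adjust([0.01, 0.02, 0.03, 0.04])) == pytest.approx([0.04] * 4)

    def test_single_and_constant(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert list(bh_adjust([0.5] * 7)) == pytest.approx([0.5] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_properties(self, pvals, rnd):
        adj = bh_adjust(pvals)
        # adjusted p in [p, 1]
        assert all(a >= p - 1e-12 and a <= 1.0 for a, p in zip(adj, pvals))
        # monotone in the p-value ranks
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()
        # permutation equivariance: adjusted values travel with their inputs
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        adj_perm = bh_adjust([pvals[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm])


class TestDEGConnectivityTest:
    @staticmethod
    def _net_with_hub_weights(weights: dict[str, float]) -> FunctionalNetwork:
        genes = ("HUB", *weights)
        n = len(genes)
        W = np.zeros((n, n))
        for i, g in enumerate(weights, start=1):
            W[0, i] = W[i, 0] = weights[g]
        return FunctionalNetwork(genes, W)

    def test_exact_enumeration_example(self):
        # DEG connectivities {0.9, 0.8} vs non-DEG {0.1, 0.2}: p = 1/6
        net = self._net_with_hub_weights({"a": 0.9, "b": 0.8, "c": 0.1, "d": 0.2})
        degs = deg_frame(["a", "b", "c", "d"], [0.01, 0.01, 0.5, 0.5])
        res = deg_connectivity_test(net, "HUB", degs)
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(1 / 6)
        assert (res.n_deg, res.n_nondeg) == (2, 2)
        assert res.median_deg > res.median_nondeg

    def test_identical_groups_not_significant(self):
        net = self._net_with_hub_weights(
            {"a": 0.3, "b": 0.7, "c": 0.3, "d": 0.7}
        )
        degs = deg_frame(["a", "b", "c", "d"], [0.01, 0.01, 0.5, 0.5])
        assert deg_connectivity_test(net, "HUB", degs).pvalue >= 0.5

    def test_empty_group_errors(self):
        net = self._net_with_hub_weights({"a": 0.1, "b": 0.2, "c": 0.3})
        all_deg = deg_frame(["a", "b", "c"], [0.01] * 3)
        with pytest.raises(ValueError, match="empty comparison group"):
            deg_connectivity_test(net, "HUB", all_deg)
        none_deg = deg_frame(["a", "b", "c"], [0.9] * 3)
        with pytest.raises(ValueError, match="empty comparison group"):
            deg_connectivity_test(net, "HUB", none_deg)

    def test_no_overlap_errors(self):
        net = self._net_with_hub_weights({"a": 0.1, "b": 0.2})
        degs = deg_frame(["x", "y"], [0.01, 0.9])
        with pytest.raises(ValueError, match="no overlap"):
            deg_connectivity_test(net, "HUB", degs)

    def test_exact_equals_enumeration_with_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 12 - n1))
            # quantized weights force ties
            x = np.round(rng.uniform(size=n1), 1)
            y = np.round(rng.uniform(size=n2), 1)
            assert _exact_ranksum_p_greater(x, y) == pytest.approx(
                enumerate_ranksum_p_greater(x, y), abs=1e-12
            )

    def test_normal_approximation_tracks_exact(self):
        # the approximation is accurate at moderate group sizes...
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(12)
        for _ in range(10):
            n1 = int(rng.integers(10, 26))
            n2 = int(rng.integers(10, 26))
            x = np.round(rng.uniform(size=n1), 2)
            y = np.round(rng.uniform(size=n2), 2)
            exact = _exact_ranksum_p_greater(x, y)
            approx = mannwhitneyu(
                x, y, alternative="greater", method="asymptotic", use_continuity=True
            ).pvalue
            assert approx == pytest.approx(exact, abs=0.01)
        # ...and a coarser envelope holds at the very smallest sizes
        for _ in range(10):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 12 - n1 + 1))
            x, y = rng.uniform(size=n1), rng.uniform(size=n2)
            exact = _exact_ranksum_p_greater(x, y)
            approx = mannwhitneyu(
                x, y, alternative="greater", method="asymptotic", use_continuity=True
            ).pvalue
            assert approx == pytest.approx(exact, abs=0.06)

    def test_method_switch_recorded(self):
        rng = np.random.default_rng(3)
        net = random_network(rng, 60)
        padj = np.where(np.arange(59) < 25, 0.01, 0.5)  # 25 DEGs > max_exact
        degs = deg_frame(list(net.genes[1:]), padj)
        res = deg_connectivity_test(net, net.genes[0], degs)
        assert res.method == "normal_approx"


class TestFisherOverlap:
    def test_single_tail_value_example(self):
        # |U|=20, |A|=5, |B|=8, overlap 5: p = C(15,3)/C(20,8)
        universe = [f"u{i}" for i in range(20)]
        A = universe[:5]
        B = universe[:5] + universe[5:8]
        res = fisher_overlap(A, B, universe)
        from math import comb

        assert res.pvalue == pytest.approx(comb(15, 3) / comb(20, 8), rel=1e-12)
        assert res.pvalue == pytest.approx(3.61e-3, rel=0.01)
        assert res.in_both == 5 and res.universe_size == 20

    def test_zero_overlap_full_tail(self):
        universe = [f"u{i}" for i in range(10)]
        res = fisher_overlap(universe[:3], universe[3:6], universe)
        assert res.pvalue == pytest.approx(1.0)
        assert res.haldane  # a zero cell triggers the flagged OR correction

    def test_degenerate_margins(self):
        universe = [f"u{i}" for i in range(6)]
        res = fisher_overlap(universe, universe, universe)
        assert res.in_both == 6
        assert res.pvalue == pytest.approx(1.0)

    def test_outside_universe_dropped_with_warning(self):
        universe = [f"u{i}" for i in range(8)]
        with pytest.warns(UserWarning, match="dropped"):
            res = fisher_overlap(universe[:3] + ["alien"], universe[2:5], universe)
        assert res.in_both == 1

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 4"):
            fisher_overlap(["a"], ["a"], ["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            fisher_overlap(["zz"], ["u0"], [f"u{i}" for i in range(5)])

    def test_exhaustive_hypergeometric_agreement(self):
        # every 2x2 configuration with universe size up to 30
        for N in range(4, 31):
            universe = [f"u{i}" for i in range(N)]
            for nA in range(1, N + 1):
                for nB in range(1, N + 1):
                    for k in range(max(0, nA + nB - N), min(nA, nB) + 1):
                        A = universe[:nA]
                        B = universe[nA - k : nA - k + nB]
                        res = fisher_overlap(A, B, universe)
                        assert res.in_both == k
                        expected = hypergeom_tail_by_enumeration(k, N, nA, nB)
                        assert res.pvalue == pytest.approx(expected, abs=1e-12)


class TestSignedOverlap:
    @staticmethod
    def _table(genes, padj, lfc):
        return DEGTable(
            pd.DataFrame(
                {"gene": genes, "log2fc": lfc, "pvalue": padj, "padj": padj}
            )
        )

    def test_identical_calls_maximal_concordance(self):
        genes = [f"g{i}" for i in range(20)]
        padj = [0.01] * 6 + [0.5] * 14
        lfc = [1, 1, 1, -1, -1, -1] + [0.1] * 14
        a = self._table(genes, padj, lfc)
        b = self._table(genes, padj, lfc)
        res = signed_overlap(a, b)
        assert res.concordant.in_both == 6
        assert res.n_discordant == 0
        assert res.up.in_both == 3 and res.down.in_both == 3

    def test_flipped_signs_are_discordant(self):
        genes = [f"g{i}" for i in range(20)]
        padj = [0.01] * 6 + [0.5] * 14
        lfc_a = [1, 1, 1, -1, -1, -1] + [0.1] * 14
        lfc_b = [-x for x in lfc_a]
        res = signed_overlap(self._table(genes, padj, lfc_a), self._table(genes, padj, lfc_b))
        assert res.up.in_both == 0
        assert res.concordant.in_both == 0
        assert res.n_discordant == 6

    def test_counts_sum_to_universe(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(50)]
        for _ in range(5):
            a = self._table(
                genes, rng.uniform(size=50), rng.normal(size=50)
            )
            b = self._table(
                genes, rng.uniform(size=50), rng.normal(size=50)
            )
            res = signed_overlap(a, b, cutoff=0.3)
            for t in (res.up, res.down, res.concordant):
                assert (
                    t.in_both + t.in_a_only + t.in_b_only + t.in_neither
                    == t.universe_size
                )


class TestRankEnrichmentCurve:
    @staticmethod
    def _setup(n=10, deg_top=2):
        genes = tuple(["HUB"] + [f"g{i}" for i in range(n)])
        W = np.zeros((n + 1, n + 1))
        w = np.linspace(0.9, 0.1, n)
        W[0, 1:] = w
        W[1:, 0] = w
        net = FunctionalNetwork(genes, W)
        padj = [0.01] * deg_top + [0.5] * (n - deg_top)
        degs = deg_frame(list(genes[1:]), padj)
        return net, degs

    def test_top_ranked_degs_fold(self):
        net, degs = self._setup(n=10, deg_top=2)
        curve = rank_enrichment_curve(net, "HUB", degs)
        k2 = np.where(curve.cutoffs == 2)[0][0]
        assert curve.fold[k2] == pytest.approx(5.0)  # (2/2)/(2/10)
        assert list(curve.rug) == [1, 2]

    def test_closure_at_full_universe(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            net = random_network(rng, 30)
            padj = rng.uniform(size=29)
            degs = deg_frame(list(net.genes[1:]), padj)
            curve = rank_enrichment_curve(net, net.genes[0], degs, cutoff=0.4)
            assert curve.fold[-1] == 1.0  # exact closure
            assert (np.diff(curve.hits) >= 0).all()
            assert (curve.hits <= np.minimum(curve.cutoffs, curve.n_deg)).all()
            assert (curve.fold >= 0).all()

    def test_log_grid(self):
        net, degs = self._setup(n=50, deg_top=5)
        curve = rank_enrichment_curve(
            net, "HUB", degs, cutoff_grid="log", n_log_cutoffs=10
        )
        assert curve.cutoffs[-1] == curve.universe_size
        assert curve.fold[-1] == 1.0
        assert len(curve.cutoffs) <= 11

    def test_no_degs_errors(self):
        net, _ = self._setup()
        degs = deg_frame([f"g{i}" for i in range(10)], [0.9] * 10)
        with pytest.raises(ValueError, match="no DEGs"):
            rank_enrichment_curve(net, "HUB", degs)
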