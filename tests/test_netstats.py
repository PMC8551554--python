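"""Permutation tests, FDR, the network-based statistic and summaries."""

from __future__ import annotations

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from plvnet.netstats import (NBSResult, StatSpec, edge_count_summary, fdr_bh,
                             graph_metric_group_tests, nbs, permutation_test,
                             t_statistic, updrs_improvement)


def _matrix_stack(rng, n_subj, n_nodes=20, base=0.3, sd=0.05):
    """Stack of symmetric noisy connectivity-like matrices."""
    stack = np.empty((n_subj, n_nodes, n_nodes))
    for s in range(n_subj):
        m = base + rng.normal(0, sd, size=(n_nodes, n_nodes))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        stack[s] = m
    return stack


class TestPermutationTest:
    def test_identical_groups_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert permutation_test(a, a.copy(), n_perm=500) == 1.0

    def test_separated_groups_attain_minimum_p(self, rng):
        a = rng.normal(10, 0.1, 10)
        b = rng.normal(0, 0.1, 10)
        p = permutation_test(a, b, n_perm=1000, seed=0)
        assert p == pytest.approx(1 / 1001)

    def test_paired_detects_consistent_shift(self, rng):
        base = rng.normal(0, 1, 12)
        a = base + 0.8 + rng.normal(0, 0.1, 12)
        p = permutation_test(a, base, paired=True, n_perm=1000, seed=1)
        assert p < 0.01

    def test_p_never_zero_and_bounded(self, rng):
        for _ in range(5):
            p = permutation_test(rng.normal(size=6), rng.normal(size=6),
                                 n_perm=200, seed=2)
            assert 1 / 201 <= p <= 1.0

    def test_group_size_guards(self):
        with pytest.raises(ValueError):
            permutation_test([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match="equal group sizes"):
            permutation_test([1, 2, 3], [1, 2], paired=True)


class TestTStatistic:
    def test_equal_means_give_zero(self):
        assert t_statistic([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(0.0)

    def test_hand_computed_pooled_value(self):
        """{1,2,3} vs {4,5,6}: pooled s = 1, se = sqrt(2/3), t = -3.674."""
        assert t_statistic([1, 2, 3], [4, 5, 6]) == pytest.approx(-3.674, abs=1e-3)

    def test_constant_paired_difference_guard(self):
        with pytest.raises(ZeroDivisionError):
            t_statistic([2.0, 3.0, 4.0], [1.0, 2.0, 3.0], paired=True)

    def test_zero_variance_guard(self):
        with pytest.raises(ZeroDivisionError):
            t_statistic([1.0, 1.0], [2.0, 2.0])


class TestFdrBH:
    def test_all_tiny_p_all_rejected(self):
        assert fdr_bh(np.full(40, 0.001), 0.05).all()

    def test_stepup_hand_case_all_rejected(self):
        """p = {.01,.02,.03,.04}: k* = 4 since 0.04 <= 4*0.05/4."""
        assert fdr_bh([0.01, 0.02, 0.03, 0.04], 0.05).all()

    def test_stepup_hand_case_none_rejected(self):
        """p = {.04,.9,.9,.9}: 0.04 > 1*0.05/4 = 0.0125, so nothing."""
        assert not fdr_bh([0.04, 0.9, 0.9, 0.9], 0.05).any()

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(3, 30)) ** 2
            ours = fdr_bh(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(ours, ref)

    def test_monotone_in_q(self, rng):
        p = rng.uniform(size=25) ** 2
        low = fdr_bh(p, 0.01)
        high = fdr_bh(p, 0.10)
        assert np.all(high[low])  # lowering q never adds rejections

    def test_empty_and_invalid_input(self):
        with pytest.raises(ValueError):
            fdr_bh([])
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])


class TestNBS:
    def test_identical_stacks_find_nothing(self, rng):
        stack = _matrix_stack(rng, 8)
        inc, dec = nbs(stack, stack.copy(),
                       StatSpec(n_perm_nbs=200, seed=0))
        assert not inc.components and not dec.components

    def test_planted_clique_recovered(self, rng):
        """A 10-edge clique shifted by +0.2 (noise SD 0.05, n = 15/15) is
        found as a significant component containing the planted edges.

        Uses the intensity component statistic: at edge p = 0.05 the
        supra-threshold background percolates into a giant component
        whose extent swamps a 10-edge plant, while intensity weights
        the plant's extreme t-values."""
        clique = [2, 3, 4, 5, 6]
        planted = {(a, b) for i, a in enumerate(clique) for b in clique[i + 1:]}
        a = _matrix_stack(rng, 15)
        b = _matrix_stack(rng, 15)
        for e in planted:
            a[:, e[0], e[1]] += 0.2
            a[:, e[1], e[0]] += 0.2
        inc, dec = nbs(a, b, StatSpec(n_perm_nbs=500, seed=1,
                                      component_statistic="intensity"))
        assert inc.significant  # at least one significant component
        found = inc.significant_edges()
        assert len(planted & found) >= 9
        assert inc.p_values[0] < 0.01
        # the reverse direction is quiet
        assert not dec.significant

    def test_paired_design_uses_sign_flips(self, rng):
        base = _matrix_stack(rng, 10)
        shifted = base.copy()
        shifted[:, 1, 2] += 0.3
        shifted[:, 2, 1] += 0.3
        shifted += rng.normal(0, 0.01, size=shifted.shape)
        shifted = (shifted + shifted.transpose(0, 2, 1)) / 2
        inc, dec = nbs(shifted, base,
                       StatSpec(paired=True, n_perm_nbs=500, seed=3,
                                component_statistic="intensity"))
        assert (1, 2) in inc.significant_edges()

    def test_p_value_floor_and_reproducibility(self, rng):
        a = _matrix_stack(rng, 6)
        b = _matrix_stack(rng, 6)
        spec = StatSpec(n_perm_nbs=100, seed=9)
        r1 = nbs(a, b, spec)
        r2 = nbs(a, b, spec)
        assert r1[0].p_values == r2[0].p_values
        assert all(p >= 1 / 101 for p in r1[0].p_values + r1[1].p_values)

    def test_tiny_edge_alpha_yields_empty_results(self, rng):
        a = _matrix_stack(rng, 6)
        b = _matrix_stack(rng, 6)
        inc, dec = nbs(a, b, StatSpec(n_perm_nbs=100, edge_alpha=1e-9, seed=4))
        assert not inc.components and not dec.components

    def test_node_count_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            nbs(_matrix_stack(rng, 5, n_nodes=10), _matrix_stack(rng, 5, n_nodes=12),
                StatSpec(n_perm_nbs=100))


class TestEdgeCountSummary:
    COUNTS = {"theta": (207, 85), "alpha": (91, 88),
              "beta1": (156, 112), "beta2": (168, 84)}

    def test_published_band_counts_reproduce_summary(self):
        """Per-band counts {85,88,112,84} / {207,91,156,168} summarize to
        92.25 +- 13.28 vs 155.50 +- 48.20 with Welch p ~ 0.074."""
        s = edge_count_summary(self.COUNTS)
        assert s["decrease_mean"] == pytest.approx(92.25)
        assert s["decrease_sd"] == pytest.approx(13.28, abs=0.005)
        assert s["increase_mean"] == pytest.approx(155.50)
        assert s["increase_sd"] == pytest.approx(48.20, abs=0.005)
        assert s["welch_p"] == pytest.approx(0.074, abs=0.001)

    def test_identical_counts_zero_sd(self):
        s = edge_count_summary({"theta": (5, 3), "alpha": (5, 3)})
        assert s["increase_sd"] == 0.0 and s["decrease_sd"] == 0.0

    def test_accepts_nbs_results(self, rng):
        res = NBSResult(direction="increase", components=[[(0, 1), (1, 2)]],
                        extents=[2], p_values=[0.001], observed_t=np.zeros((4, 4)),
                        threshold=2.0)
        empty = NBSResult(direction="decrease", components=[], extents=[],
                          p_values=[], observed_t=np.zeros((4, 4)), threshold=2.0)
        s = edge_count_summary({"theta": (res, empty), "alpha": (0, 0)})
        assert s["per_band"]["theta"]["increase_edges"] == 2
        assert s["per_band"]["theta"]["increase_nodes"] == 3

    def test_needs_two_bands(self):
        with pytest.raises(ValueError):
            edge_count_summary({"theta": (1, 1)})


class TestUpdrsImprovement:
    def test_published_group_means_round_to_063(self):
        assert round(updrs_improvement(46.5, 17.1), 2) == 0.63

    def test_limits(self):
        assert updrs_improvement(30.0, 30.0) == 0.0
        assert updrs_improvement(30.0, 0.0) == 1.0
        with pytest.raises(ValueError):
            updrs_improvement(0.0, 10.0)


class TestGraphMetricGroupTests:
    def test_planted_metric_shift_survives_fdr(self, rng):
        import pandas as pd
        rows_a, rows_b = [], []
        for subj in range(12):
            for sparsity in (0.1, 0.2):
                for metric in ("C", "Eglob"):
                    base = rng.normal(0.5, 0.02)
                    shift = 0.2 if metric == "C" else 0.0
                    rows_a.append({"subject": f"a{subj}", "band": "alpha",
                                   "sparsity": sparsity, "metric": metric,
                                   "value": base + shift})
                    rows_b.append({"subject": f"b{subj}", "band": "alpha",
                                   "sparsity": sparsity, "metric": metric,
                                   "value": rng.normal(0.5, 0.02)})
        out = graph_metric_group_tests(pd.DataFrame(rows_a), pd.DataFrame(rows_b))
        sig = out[out.significant_fdr]
        assert set(sig.metric) == {"C"}
        assert len(sig) == 2
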