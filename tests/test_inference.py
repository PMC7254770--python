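"""Group inference: t-test tables, FDR, NBS permutation test, correlations."""

import numpy as np
import pandas as pd
import pytest

from funconn.construction import WeightedNetwork
from funconn.inference import (chi_square, compare_connection_classes,
                               compare_global, compare_nodal,
                               correlate_metrics, mann_whitney, nbs)
from funconn.metrics import GlobalMetrics, NodalMetrics

from oracles import brute_pooled_t


def make_global(values: dict) -> GlobalMetrics:
    defaults = dict(network_strength=1.0, clustering_coefficient=0.5,
                    shortest_path_length=2.0, small_worldness=1.1, gamma=1.1,
                    lambda_=1.0, global_efficiency=0.4, local_efficiency=0.5,
                    hierarchy=0.1, assortativity=-0.05)
    defaults.update(values)
    return GlobalMetrics(**defaults)


def make_nodal(strengths, labels=None) -> NodalMetrics:
    strengths = np.asarray(strengths, float)
    labels = labels or tuple(f"R{k}" for k in range(strengths.size))
    zeros = np.zeros_like(strengths)
    return NodalMetrics(labels, strengths, zeros + 0.3, zeros + 2.0,
                        zeros + 0.4, zeros + 0.5)


def planted_networks(n_per_group, n_regions=12, delta=0.0, seed=0,
                     clique=range(6)):
    """Gaussian-weight networks with a planted clique shift in group B."""
    rng = np.random.default_rng(seed)
    labels = tuple(f"R{k:02d}" for k in range(n_regions))
    clique = list(clique)
    groups = []
    for group, shift in (("A", 0.0), ("B", delta)):
        nets = []
        for _ in range(n_per_group):
            w = np.abs(rng.normal(0.4, 0.05, (n_regions, n_regions)))
            w = (w + w.T) / 2
            for a_idx, a in enumerate(clique):
                for b in clique[a_idx + 1:]:
                    w[a, b] += shift
                    w[b, a] += shift
            np.fill_diagonal(w, 0.0)
            nets.append(WeightedNetwork(w, labels))
        groups.append(nets)
    return groups


class TestCompareGlobal:
    def test_identical_groups_give_zero_t_unit_p(self):
        group = [make_global({"network_strength": v}) for v in (1.0, 2.0, 3.0)]
        table = compare_global(group, list(group))
        assert table.loc["network_strength", "t"] == pytest.approx(0.0)
        assert table.loc["network_strength", "p"] == pytest.approx(1.0)
        assert not table["significant"].any()

    def test_matches_textbook_pooled_t(self):
        a_values = [13.1, 12.7, 14.0, 13.5, 12.9]
        b_values = [14.9, 15.2, 14.4, 15.0, 14.6]
        a = [make_global({"network_strength": v}) for v in a_values]
        b = [make_global({"network_strength": v}) for v in b_values]
        table = compare_global(a, b)
        t_expected, p_expected = brute_pooled_t(a_values, b_values)
        assert table.loc["network_strength", "t"] == pytest.approx(t_expected)
        assert table.loc["network_strength", "p"] == pytest.approx(p_expected)

    def test_swapping_groups_negates_t_preserves_p(self):
        a = [make_global({"global_efficiency": v}) for v in (0.30, 0.32, 0.29)]
        b = [make_global({"global_efficiency": v}) for v in (0.35, 0.36, 0.33)]
        forward = compare_global(a, b)
        backward = compare_global(b, a)
        assert forward.loc["global_efficiency", "t"] == pytest.approx(
            -backward.loc["global_efficiency", "t"])
        assert forward.loc["global_efficiency", "p"] == pytest.approx(
            backward.loc["global_efficiency", "p"])

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            compare_global([make_global({})], [make_global({})] * 3)


class TestCompareNodal:
    def test_identical_groups_nothing_significant(self, rng):
        group = [make_nodal(rng.uniform(1, 3, 8)) for _ in range(5)]
        table = compare_nodal(group, list(group))
        assert not table["significant"].any()

    def test_planted_regional_difference_detected(self, rng):
        a = [make_nodal(10 + rng.standard_normal(8) * 0.5) for _ in range(15)]
        b = []
        for _ in range(15):
            s = 10 + rng.standard_normal(8) * 0.5
            s[2] += 5.0
            b.append(make_nodal(s))
        table = compare_nodal(a, b, q=0.05)
        assert bool(table.loc[("strength", "R2"), "significant"])
        assert table.attrs["adjustment"] == "fdr_bh"

    def test_bh_adjustment_is_monotone_in_raw_p(self, rng):
        a = [make_nodal(rng.uniform(1, 3, 10)) for _ in range(6)]
        b = [make_nodal(rng.uniform(1, 3.5, 10)) for _ in range(6)]
        table = compare_nodal(a, b).loc["strength"].dropna(subset=["p"])
        ordered = table.sort_values("p")
        assert ordered["p_adjusted"].is_monotonic_increasing
        assert (ordered["p_adjusted"] >= ordered["p"] - 1e-15).all()


class TestNBS:
    def test_no_suprathreshold_edges_gives_empty_result(self):
        groups = planted_networks(6, delta=0.0, seed=1)
        # identical networks within each group: zero variance, t undefined
        nets_a = [groups[0][0]] * 6
        nets_b = [groups[0][0]] * 6
        result = nbs(nets_a, nets_b, n_permutations=20, seed=0)
        assert result.components == ()

    def test_planted_clique_found_and_significant(self):
        group_a, group_b = planted_networks(15, delta=0.4, seed=2)
        result = nbs(group_a, group_b, primary_alpha=0.001,
                     n_permutations=200, seed=3, tail="b_greater")
        assert result.significant_components
        top = result.significant_components[0]
        expected = {frozenset((f"R{a:02d}", f"R{b:02d}"))
                    for a in range(6) for b in range(a + 1, 6)}
        found = {frozenset(e) for e in top.edges}
        assert len(found & expected) / len(found | expected) >= 0.6

    def test_label_swap_symmetry(self):
        group_a, group_b = planted_networks(10, delta=0.3, seed=5)
        forward = nbs(group_a, group_b, n_permutations=100, seed=7,
                      tail="b_greater")
        backward = nbs(group_b, group_a, n_permutations=100, seed=7,
                       tail="a_greater")
        fw = [(sorted(c.nodes), c.size_in_links, c.corrected_p)
              for c in forward.components]
        bw = [(sorted(c.nodes), c.size_in_links, c.corrected_p)
              for c in backward.components]
        assert fw == bw
        np.testing.assert_allclose(forward.t_matrix, -backward.t_matrix)

    def test_permutation_count_stability(self):
        group_a, group_b = planted_networks(12, delta=0.25, seed=11)
        p_small = nbs(group_a, group_b, n_permutations=500, seed=1,
                      primary_alpha=0.01).components[0].corrected_p
        p_large = nbs(group_a, group_b, n_permutations=1000, seed=2,
                      primary_alpha=0.01).components[0].corrected_p
        assert abs(p_small - p_large) < 0.02

    def test_seed_reproducibility(self):
        group_a, group_b = planted_networks(8, delta=0.3, seed=4)
        first = nbs(group_a, group_b, n_permutations=100, seed=42)
        second = nbs(group_a, group_b, n_permutations=100, seed=42)
        assert np.array_equal(first.null_max_sizes, second.null_max_sizes)
        assert [c.corrected_p for c in first.components] == \
            [c.corrected_p for c in second.components]

    def test_edgewise_t_matches_per_edge_oracle(self):
        group_a, group_b = planted_networks(7, delta=0.2, seed=9,
                                            n_regions=8)
        result = nbs(group_a, group_b, n_permutations=10, seed=0)
        for i in range(8):
            for j in range(i + 1, 8):
                a = [net.weights[i, j] for net in group_a]
                b = [net.weights[i, j] for net in group_b]
                t_expected, _ = brute_pooled_t(b, a)
                assert result.t_matrix[i, j] == pytest.approx(
                    t_expected, abs=1e-9)

    def test_corrected_p_in_unit_interval(self):
        group_a, group_b = planted_networks(10, delta=0.35, seed=13)
        result = nbs(group_a, group_b, n_permutations=50, seed=5)
        for component in result.components:
            assert 0.0 < component.corrected_p <= 1.0
            assert component.size_in_links == len(component.edges)


class TestCorrelateMetrics:
    def test_metric_with_itself_is_one(self):
        values = pd.DataFrame({"m": [1.0, 2.0, 5.0, 3.0]},
                              index=list("wxyz"))
        covs = pd.DataFrame({"c": [1.0, 2.0, 5.0, 3.0]}, index=list("wxyz"))
        table = correlate_metrics(values, covs, [("m", "c")])
        assert table.loc[0, "r"] == pytest.approx(1.0)
        assert table.loc[0, "n"] == 4

    def test_independent_covariate_near_zero(self, rng):
        idx = [f"s{k}" for k in range(1000)]
        values = pd.DataFrame({"m": rng.standard_normal(1000)}, index=idx)
        covs = pd.DataFrame({"c": rng.standard_normal(1000)}, index=idx)
        table = correlate_metrics(values, covs, [("m", "c")])
        assert abs(table.loc[0, "r"]) < 0.1

    def test_missing_values_reduce_n(self):
        idx = list("abcdef")
        values = pd.DataFrame({"m": [1, 2, 3, 4, 5, 6.0]}, index=idx)
        covs = pd.DataFrame({"c": [1, np.nan, 3, 4, np.nan, 6.0]}, index=idx)
        table = correlate_metrics(values, covs, [("m", "c")])
        assert table.loc[0, "n"] == 4

    def test_too_few_complete_pairs_flagged(self):
        values = pd.DataFrame({"m": [1, 2, 3.0]}, index=list("abc"))
        covs = pd.DataFrame({"c": [1.0, np.nan, np.nan]}, index=list("abc"))
        table = correlate_metrics(values, covs, [("m", "c")])
        assert np.isnan(table.loc[0, "r"])
        assert table.loc[0, "n"] == 1


class TestConnectionClassComparison:
    @staticmethod
    def summary(strength, degree):
        return {
            cls: {"strength": strength + k, "degree": degree,
                  "average_strength": (strength + k) / degree}
            for k, cls in enumerate(("rich_club", "feeder", "local"))
        }

    def test_identical_groups_not_significant(self):
        a = [self.summary(10 + 0.1 * k, 5) for k in range(6)]
        table = compare_connection_classes(a, list(a))
        assert not table["significant"].any()

    def test_matches_textbook_t(self):
        a_strengths = [10.0, 11.0, 10.5, 9.8]
        b_strengths = [12.0, 12.5, 11.9, 12.2]
        a = [self.summary(s, 5) for s in a_strengths]
        b = [self.summary(s, 5) for s in b_strengths]
        table = compare_connection_classes(a, b)
        t_expected, p_expected = brute_pooled_t(a_strengths, b_strengths)
        assert table.loc[("rich_club", "strength"), "t"] == pytest.approx(
            t_expected)
        assert table.loc[("rich_club", "strength"), "p"] == pytest.approx(
            p_expected)


class TestDemographicsUtilities:
    def test_shifted_samples_detected(self, rng):
        a = rng.standard_normal(40)
        _, p = mann_whitney(a, a + 2.0)
        assert p < 1e-6
        stat, p = chi_square([[30, 10], [10, 30]])
        assert p < 1e-3
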