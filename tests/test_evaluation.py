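"""Enrichment, lethality, betweenness, hub partition, prediction."""

import math
from math import comb

import networkx as nx
import numpy as np
import pytest

from adhocnet.clustering import cluster_graph
from adhocnet.evaluation import (
    betweenness,
    classify_hubs,
    compare_hub_groups,
    discard_rate,
    enrich_group,
    hypergeom_enrichment,
    lethal_fraction,
    lethality_pvalue,
    mean_cluster_enrichment,
    predict_functions,
)
from adhocnet.graph_io import AnnotationTable
from adhocnet.synthetic import (
    annotation_fixture,
    default_spec,
    figure2_style_fixture,
    planted_module_graph,
)
from conftest import random_graph
from oracles import (
    betweenness_by_path_enumeration,
    exact_binomial_tail,
    exact_hypergeom_tail,
)


def _go_table(mapping):
    return AnnotationTable(category="biological_process",
                           terms={k: set(v) for k, v in mapping.items()})


class TestDiscardRate:
    def test_demo_fixture_ratio(self):
        result = cluster_graph(figure2_style_fixture(), k=3)
        assert discard_rate(result) == pytest.approx(100 * 5 / 21)

    def test_all_clustered_is_zero(self):
        result = cluster_graph(nx.complete_graph(6), k=3)
        assert discard_rate(result) == 0.0

    def test_no_clusters_is_hundred(self):
        result = cluster_graph(nx.cycle_graph(6), k=3)
        assert discard_rate(result) == 100.0


class TestHypergeomEnrichment:
    BACKGROUND = {f"P{i}" for i in range(20)}

    def test_universal_term_not_enriched(self):
        table = _go_table({p: {"GO:x"} for p in self.BACKGROUND})
        r = hypergeom_enrichment(set(list(self.BACKGROUND)[:5]), "GO:x", table,
                                 self.BACKGROUND)
        assert r.p_raw == pytest.approx(1.0)

    def test_absent_term_in_group_is_one(self):
        table = _go_table({"P0": {"GO:x"}})
        r = hypergeom_enrichment({"P1", "P2"}, "GO:x", table, self.BACKGROUND)
        assert r.p_raw == 1.0 and r.m == 0

    def test_perfect_enrichment_matches_enumeration(self):
        group = {f"P{i}" for i in range(5)}
        table = _go_table({p: {"GO:x"} for p in group})
        r = hypergeom_enrichment(group, "GO:x", table, self.BACKGROUND)
        assert r.p_raw == pytest.approx(1 / comb(20, 5), rel=1e-12)
        assert r.p_raw == pytest.approx(exact_hypergeom_tail(20, 5, 5, 5), rel=1e-12)

    @pytest.mark.parametrize("N,n,M,m", [(20, 5, 8, 3), (15, 6, 6, 2), (30, 10, 12, 9)])
    def test_tail_matches_exact_summation(self, N, n, M, m):
        background = {f"P{i}" for i in range(N)}
        group = {f"P{i}" for i in range(n)}
        annotated = {f"P{i}" for i in range(m)} | {f"P{i}" for i in range(n, n + M - m)}
        table = _go_table({p: {"GO:x"} for p in annotated})
        r = hypergeom_enrichment(group, "GO:x", table, background)
        assert r.p_raw == pytest.approx(exact_hypergeom_tail(N, n, M, m), rel=1e-10)

    def test_bonferroni_counts_group_terms(self):
        table = _go_table({"P0": {"GO:a", "GO:b"}, "P1": {"GO:c"}})
        results = enrich_group({"P0", "P1"}, table, self.BACKGROUND)
        assert len(results) == 3
        for r in results:
            assert r.p_corrected == pytest.approx(min(1.0, r.p_raw * 3))
            assert r.neg_log10_p == pytest.approx(-math.log10(r.p_corrected))

    def test_group_outside_background_rejected(self):
        table = _go_table({})
        with pytest.raises(ValueError):
            hypergeom_enrichment({"Q999"}, "GO:x", table, self.BACKGROUND)


class TestMeanClusterEnrichment:
    def test_single_cluster_is_its_best_term(self):
        g = nx.complete_graph([f"P{i}" for i in range(5)])
        result = cluster_graph(g, k=3)
        table = _go_table({f"P{i}": {"GO:x"} for i in range(4)})
        best = enrich_group(result.clusters[0].members, table, set(g.nodes))[0]
        assert mean_cluster_enrichment(result, table) == pytest.approx(best.neg_log10_p)

    def test_unannotated_cluster_contributes_zero(self):
        g = nx.disjoint_union_all([nx.complete_graph(5), nx.complete_graph(5)])
        result = cluster_graph(g, k=3, p=0.5)
        assert len(result.clusters) == 2
        table = _go_table({0: {"GO:x"}, 1: {"GO:x"}, 2: {"GO:x"}})
        per_cluster = []
        for c in result.clusters:
            r = enrich_group(c.members, table, set(g.nodes))
            per_cluster.append(r[0].neg_log10_p if r else 0.0)
        assert mean_cluster_enrichment(result, table) == pytest.approx(
            sum(per_cluster) / 2)
        assert 0.0 in per_cluster  # the unannotated clique

    def test_no_clusters_is_error(self):
        result = cluster_graph(nx.cycle_graph(5), k=3)
        with pytest.raises(ValueError):
            mean_cluster_enrichment(result, _go_table({}))


class TestLethality:
    TABLE = AnnotationTable(
        category="lethality",
        terms={**{f"L{i}": {"lethal"} for i in range(7)},
               **{f"V{i}": {"viable"} for i in range(10)},
               "U0": {"unknown"}},
    )

    def test_no_lethals_is_one(self):
        assert lethality_pvalue({"V0", "V1"}, self.TABLE, 0.3) == 1.0

    def test_single_lethal_singleton_is_p(self):
        assert lethality_pvalue({"L0"}, self.TABLE, 0.3) == pytest.approx(0.3)

    def test_matches_exact_tail(self):
        group = {f"L{i}" for i in range(7)} | {f"V{i}" for i in range(3)}
        assert lethality_pvalue(group, self.TABLE, 0.3) == pytest.approx(
            exact_binomial_tail(10, 7, 0.3), rel=1e-10)

    def test_monotone_in_lethal_count(self):
        groups = [{f"L{i}" for i in range(k)} | {f"V{i}" for i in range(5 - k)}
                  for k in range(6)]
        values = [lethality_pvalue(g, self.TABLE, 0.3) for g in groups]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_background_fraction_excludes_unknown(self):
        nodes = {f"L{i}" for i in range(7)} | {f"V{i}" for i in range(10)} | {"U0", "X9"}
        # X9 not listed -> unknown; 7 lethal / 17 known
        assert lethal_fraction(nodes, self.TABLE) == pytest.approx(7 / 17)


class TestBetweenness:
    def test_path_center(self):
        b = betweenness(nx.path_graph(3))
        assert b[1] == pytest.approx(1.0) and b[0] == b[2] == 0.0

    def test_star_center_closed_form(self):
        L = 6
        b = betweenness(nx.star_graph(L))
        assert b[0] == pytest.approx(L * (L - 1) / 2)

    def test_four_cycle_split_geodesics(self):
        b = betweenness(nx.cycle_graph(4))
        assert all(v == pytest.approx(0.5) for v in b.values())

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_path_enumeration_oracle(self, seed):
        g = random_graph(seed, n_max=10, p=0.35)
        expected = betweenness_by_path_enumeration(g)
        actual = betweenness(g)
        for v in g:
            assert actual[v] == pytest.approx(expected[v], abs=1e-9)


class TestHubPartition:
    def _hub_setting(self):
        spec = default_spec(seed=3)
        graph, _ = planted_module_graph(spec)
        result = cluster_graph(graph, k=3)
        return graph, result

    def test_strict_degree_threshold(self):
        g = nx.star_graph(10)  # center degree exactly 10
        result = cluster_graph(g, k=3, p=0.5)
        partition = classify_hubs(g, result, threshold=10)
        assert partition.hubs == set()
        partition9 = classify_hubs(g, result, threshold=9)
        assert partition9.hubs == {0}

    def test_partition_sums_and_location(self):
        graph, result = self._hub_setting()
        partition = classify_hubs(graph, result, threshold=7)
        assert partition.module_hubs | partition.inter_module_hubs == partition.hubs
        assert not partition.module_hubs & partition.inter_module_hubs
        clustered = result.clustered_nodes()
        for v in partition.module_hubs:
            assert v in clustered
        for v in partition.inter_module_hubs:
            assert v in result.inter_module

    def test_intra_group_interaction_counts(self):
        graph, result = self._hub_setting()
        partition = classify_hubs(graph, result, threshold=7)
        group = partition.module_hubs
        stats = partition.group_stats["module_hubs"]
        counts = [sum(1 for u in graph[v] if u in group) for v in group]
        assert stats["intra_group_interactions_mean"] == pytest.approx(np.mean(counts))

    def test_mismatched_result_rejected(self):
        graph, result = self._hub_setting()
        other = nx.complete_graph(4)
        with pytest.raises(ValueError):
            classify_hubs(other, result)

    def test_compare_groups_report_schema(self):
        graph, result = self._hub_setting()
        partition = classify_hubs(graph, result, threshold=7)
        report = compare_hub_groups(partition)
        if report["empty_group"]:
            assert report["ks_tests"] is None
        else:
            assert set(report["ks_tests"]) == {"degrees", "betweenness"}
            for test in report["ks_tests"].values():
                assert 0 <= test["pvalue"] <= 1
        for key in ("intra_group_interactions_mean", "intra_group_interactions_sd",
                    "clustering_coefficient_mean", "clustering_coefficient_sd"):
            assert key in report["module_hubs"]

    def test_identical_groups_ks_statistic_zero(self):
        from scipy import stats
        stat, p = stats.ks_2samp([1, 2, 3, 4], [1, 2, 3, 4])
        assert stat == 0.0 and p == pytest.approx(1.0)


class TestPredictFunctions:
    def _enriched_cluster(self):
        g = nx.complete_graph([f"P{i}" for i in range(10)])
        g.add_nodes_from(f"B{i}" for i in range(40))
        result = cluster_graph(g, k=3, p=0.3)
        assert len(result.clusters) == 1
        return g, result

    def test_unannotated_members_receive_best_term(self):
        g, result = self._enriched_cluster()
        table = _go_table({f"P{i}": {"GO:x"} for i in range(8)})
        preds = predict_functions(result, table, neg_log_p_threshold=5,
                                  background=set(g.nodes))
        assert sorted(preds["protein"]) == ["P8", "P9"]
        assert set(preds["predicted_term"]) == {"GO:x"}

    def test_cluster_below_threshold_predicts_nothing(self):
        g, result = self._enriched_cluster()
        table = _go_table({f"P{i}": {"GO:x"} for i in range(8)})
        preds = predict_functions(result, table, neg_log_p_threshold=1e6,
                                  background=set(g.nodes))
        assert preds.empty

    def test_fully_annotated_cluster_predicts_nothing(self):
        g, result = self._enriched_cluster()
        table = _go_table({f"P{i}": {"GO:x"} for i in range(10)})
        preds = predict_functions(result, table, neg_log_p_threshold=5,
                                  background=set(g.nodes))
        assert preds.empty

    def test_planted_annotations_drive_predictions(self):
        spec = default_spec(seed=5)
        graph, truth = planted_module_graph(spec)
        result = cluster_graph(graph, k=3)
        table = annotation_fixture(truth, term_purity=1.0,
                                   unannotated_fraction=0.2, seed=5)
        preds = predict_functions(result, table, neg_log_p_threshold=3)
        assert not preds.empty
        for _, row in preds.iterrows():
            assert table.terms_for(row.protein) == set()
            module = int(row.predicted_term.removeprefix("GO:MOD"))
            assert module in truth[row.protein]
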