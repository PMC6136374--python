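"""Enrichment statistics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from abacross import (
    ExpressionSimSpec,
    InteractionNetwork,
    NetworkSpec,
    build_ensemble,
    coexpression_enrichment,
    compare_zscores,
    cross_edge_count,
    extract_core_subnetwork,
    generate_expression_matrix,
    generate_network,
    generate_contrast_table,
    global_enrichment,
    per_gene_enrichment,
    select_core_components,
)
from abacross.stats import z_score
from conftest import brute_force_cross_counts


class TestCrossEdgeCount:
    def test_toy_enumeration(self, toy_cross_net):
        assert cross_edge_count(toy_cross_net, "a1", {"b1", "b2", "b3"}) == 2
        assert cross_edge_count(toy_cross_net, "b3", {"a1", "a2", "a3"}) == 0

    def test_empty_opposing_set(self, toy_cross_net):
        assert cross_edge_count(toy_cross_net, "a1", set()) == 0

    def test_isolated_gene(self):
        net = InteractionNetwork.from_gene_pairs([("a", "b")], nodes=["a", "b", "c"])
        assert cross_edge_count(net, "c", {"a", "b"}) == 0

    def test_unknown_gene_is_unscorable(self, toy_cross_net):
        with pytest.raises(ValueError, match="unscorable"):
            cross_edge_count(toy_cross_net, "zz", {"b1"})


class TestPerGeneEnrichment:
    def test_empirical_p_rule_against_brute_force(self):
        # small graph, tiny ensemble: recompute every null count by
        # edge-by-edge enumeration and apply the tie-inclusive proportion
        net = generate_network(NetworkSpec(n_nodes=30, mean_degree=4, seed=1))
        genes = [str(g) for g in net.nodes]
        A, B = set(genes[:5]), set(genes[5:15])
        ens = build_ensemble(net, R=7, master_seed=2)
        records = per_gene_enrichment(net, ens, A, B)

        obs_pg, _ = brute_force_cross_counts(net.edge_gene_pairs(), A, B)
        null_pg = [
            brute_force_cross_counts(ens.replicate(r).edge_gene_pairs(), A, B)[0]
            for r in range(ens.R)
        ]
        for row in records.itertuples():
            assert row.observed_cross == obs_pg[row.gene_id]
            nulls = np.array([null_pg[r][row.gene_id] for r in range(ens.R)])
            assert row.empirical_p == pytest.approx((nulls >= row.observed_cross).mean())
            assert row.null_mean == pytest.approx(nulls.mean())

    def test_zero_observed_has_p_one_and_floor_reported(self, toy_cross_net):
        ens = build_ensemble(toy_cross_net, R=5, master_seed=3)
        records = per_gene_enrichment(
            toy_cross_net, ens, {"a1", "a2", "a3"}, {"b1", "b2", "b3"}
        )
        rec = records.set_index("gene_id")
        assert rec.loc["a2", "empirical_p"] == 1.0  # no cross edges ever
        assert (records["min_resolvable_p"] == 1 / 5).all()

    def test_pseudocount_variant_never_zero(self, toy_cross_net):
        ens = build_ensemble(toy_cross_net, R=5, master_seed=3)
        records = per_gene_enrichment(
            toy_cross_net, ens, {"a1"}, {"b1", "b2"}, pseudocount=True
        )
        assert (records["empirical_p"] > 0).all()
        assert (records["empirical_p"] <= 1).all()

    def test_overlapping_sets_rejected(self, toy_cross_net):
        ens = build_ensemble(toy_cross_net, R=2, master_seed=1)
        with pytest.raises(ValueError, match="overlap"):
            per_gene_enrichment(toy_cross_net, ens, {"a1"}, {"a1", "b1"})

    def test_genes_absent_from_network_are_excluded_and_logged(self, toy_cross_net, caplog):
        ens = build_ensemble(toy_cross_net, R=2, master_seed=1)
        with caplog.at_level("WARNING"):
            records = per_gene_enrichment(
                toy_cross_net, ens, {"a1", "ghost"}, {"b1"}
            )
        assert "unscorable" in caplog.text
        assert set(records["gene_id"]) == {"a1", "b1"}

    def test_monotonicity_adding_cross_edge_never_raises_p(self):
        net = generate_network(NetworkSpec(n_nodes=40, mean_degree=4, seed=4))
        genes = [str(g) for g in net.nodes]
        A, B = set(genes[:6]), set(genes[6:18])
        ens = build_ensemble(net, R=50, master_seed=5)
        before = per_gene_enrichment(net, ens, A, B).set_index("gene_id")
        # add one new A-B edge against the same (fixed) null distributions
        a, b = sorted(A)[0], sorted(B)[0]
        ia, ib = net.node_index[a], net.node_index[b]
        pairs = net.edge_gene_pairs()
        if not net.has_edge(a, b):
            pairs.append((a, b))
        net2 = InteractionNetwork.from_gene_pairs(pairs, nodes=[str(g) for g in net.nodes])
        after = per_gene_enrichment(net2, ens, A, B).set_index("gene_id")
        assert (after["empirical_p"] <= before["empirical_p"] + 1e-12).all()


class TestGlobalEnrichment:
    @pytest.mark.parametrize(
        "obs,mu,sd,expected",
        [(10, 4, 2, 3.0), (4, 4, 2, 0.0), (0, 5, 2.5, -2.0)],
    )
    def test_z_closed_form(self, obs, mu, sd, expected):
        assert z_score(obs, mu, sd) == pytest.approx(expected)

    def test_zero_sd_is_flagged_not_raised(self):
        assert np.isnan(z_score(3, 3, 0.0))

    def test_matches_brute_force_and_is_symmetric(self):
        net = generate_network(NetworkSpec(n_nodes=30, mean_degree=4, seed=6))
        genes = [str(g) for g in net.nodes]
        A, B = set(genes[:6]), set(genes[6:16])
        ens = build_ensemble(net, R=9, master_seed=7)
        g_ab = global_enrichment(net, ens, A, B)
        g_ba = global_enrichment(net, ens, B, A)
        _, obs = brute_force_cross_counts(net.edge_gene_pairs(), A, B)
        nulls = np.array([
            brute_force_cross_counts(ens.replicate(r).edge_gene_pairs(), A, B)[1]
            for r in range(ens.R)
        ])
        assert g_ab.n_observed == obs == g_ba.n_observed
        assert g_ab.mu_null == pytest.approx(nulls.mean()) == g_ba.mu_null
        assert g_ab.sd_null == pytest.approx(nulls.std(ddof=1))
        assert g_ab.z_score == pytest.approx(z_score(obs, nulls.mean(), nulls.std(ddof=1)))


class TestSelectCore:
    def _records(self, ps):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(ps))],
            "source_set": ["A_ABA_dependent", "B_ABA_independent"] * (len(ps) // 2),
            "empirical_p": ps,
        })

    def test_all_p_one_gives_empty_cores(self):
        core_A, core_B = select_core_components(self._records([1.0] * 6))
        assert core_A == [] and core_B == []

    def test_alpha_one_selects_every_scorable_gene(self):
        records = self._records([0.2, 0.9, 0.5, 0.04, 1.0, 0.0])
        core_A, core_B = select_core_components(records, alpha=1.0)
        assert len(core_A) + len(core_B) == 5  # p == 1.0 is not < 1.0
        core_A, core_B = select_core_components(records, alpha=0.05)
        assert core_A + core_B == ["g5", "g3"] or set(core_A + core_B) == {"g3", "g5"}


@pytest.fixture(scope="module")
def net_ens():
    net = generate_network(NetworkSpec(n_nodes=400, mean_degree=8, seed=8))
    ens = build_ensemble(net, R=60, master_seed=9)
    return net, ens


class TestCompareZscores:

    def test_full_subsample_singleton_equals_global_z(self, net_ens):
        net, ens = net_ens
        genes = [str(g) for g in net.nodes]
        A, B = set(genes[:20]), set(genes[20:80])
        pool = set(genes[80:])
        zc = compare_zscores(
            net, ens, A, B, pool, n_resamples=1, seed=1,
            deg_resample="subsample", subsample_fraction=1.0,
        )
        g = global_enrichment(net, ens, A, B)
        assert len(zc.z_deg) == 1
        assert zc.z_deg[0] == pytest.approx(g.z_score)

    def test_split_mode_sizes_and_welch_output(self, net_ens):
        net, ens = net_ens
        genes = [str(g) for g in net.nodes]
        A, B = set(genes[:20]), set(genes[20:80])
        pool = set(genes[80:])
        zc = compare_zscores(net, ens, A, B, pool, n_resamples=25, seed=2, n_splits=4)
        assert len(zc.z_deg) == 4
        assert len(zc.z_nondeg) == 25
        assert 0 <= zc.p_value <= 1

    def test_pool_too_small_or_overlapping_rejected(self, net_ens):
        net, ens = net_ens
        genes = [str(g) for g in net.nodes]
        A, B = set(genes[:20]), set(genes[20:80])
        with pytest.raises(ValueError, match="pool too small"):
            compare_zscores(net, ens, A, B, set(genes[80:85]),
                            n_resamples=3, seed=3, n_splits=1)
        with pytest.raises(ValueError, match="disjoint"):
            compare_zscores(net, ens, A, B, {sorted(A)[0]}, seed=3)


class TestCoexpression:
    def _fixture(self, shared, within=0.6, seed=13):
        spec = ExpressionSimSpec(
            n_genes=300,
            class_counts={"ABA_DEPENDENT": 25, "ABA_INDEPENDENT": 50,
                          "NOT_RECOVERED": 0, "NON_DEG": 225},
            within_class_corr=within, drought_shared_corr=shared, seed=seed,
        )
        truth = pd.Series(generate_contrast_table(spec)[1].gene_classes)
        expr = generate_expression_matrix(spec, n_samples=60)
        A = sorted(truth.index[truth == "ABA_DEPENDENT"])
        B = sorted(truth.index[truth == "ABA_INDEPENDENT"])
        pool = sorted(truth.index[truth == "NON_DEG"])
        return expr, A, B, pool

    def test_top_fraction_one_gives_fold_one(self):
        expr, A, B, pool = self._fixture(shared=0.0)
        res = coexpression_enrichment(expr, A, B, pool, top_fraction=1.0,
                                      n_resamples=10, seed=1)
        assert res.n_links_observed == len(A) * len(B)
        assert res.fold_enrichment == pytest.approx(1.0)

    def test_null_fixture_fold_near_one(self):
        # within- and between-class correlation planted equal (both zero):
        # A-B pairs and non-DEG pairs share one correlation distribution
        expr, A, B, pool = self._fixture(shared=0.0, within=0.0)
        res = coexpression_enrichment(expr, A, B, pool, top_fraction=0.05,
                                      n_resamples=60, seed=2)
        assert 0.6 < res.fold_enrichment < 1.6

    def test_planted_shared_factor_enriches_links(self):
        expr, A, B, pool = self._fixture(shared=0.45)
        res = coexpression_enrichment(expr, A, B, pool, top_fraction=0.01,
                                      n_resamples=60, seed=3)
        assert res.fold_enrichment > 1.5

    def test_zero_variance_genes_dropped_with_warning(self, caplog):
        expr, A, B, pool = self._fixture(shared=0.0)
        expr.loc[pool[0]] = 1.0
        with caplog.at_level("WARNING"):
            coexpression_enrichment(expr, A, B, pool, top_fraction=0.5,
                                    n_resamples=5, seed=4)
        assert "zero-variance" in caplog.text


class TestExtractCore:
    def _records(self):
        return pd.DataFrame({
            "gene_id": ["a1", "b1", "b2"],
            "source_set": ["A_ABA_dependent", "B_ABA_independent", "B_ABA_independent"],
            "empirical_p": [0.01, 0.02, 0.03],
        })

    def test_toy_edge_selection(self):
        net = InteractionNetwork.from_gene_pairs(
            [("a1", "b1"), ("a1", "x"), ("b1", "b2")],
            nodes=["a1", "b1", "b2", "x"],
        )
        core = extract_core_subnetwork(net, ["a1"], ["b1", "b2"], self._records())
        assert {tuple(sorted(e)) for e in core.graph.edges()} == {("a1", "b1"), ("b1", "b2")}
        assert core.n_cross_edges == 1
        assert core.n_total_edges == 2
        assert core.graph.nodes["a1"]["source_set"] == "A_ABA_dependent"
        assert core.graph.nodes["b2"]["empirical_p"] == pytest.approx(0.03)

    def test_empty_cores_give_empty_subnetwork(self, toy_cross_net):
        core = extract_core_subnetwork(toy_cross_net, [], [], self._records().iloc[0:0])
        assert core.n_nodes == 0
        assert core.n_total_edges == 0

    def test_graphml_round_trip_preserves_annotations(self, tmp_path):
        import networkx as nx
        net = InteractionNetwork.from_gene_pairs(
            [("a1", "b1"), ("b1", "b2")], nodes=["a1", "b1", "b2"],
        )
        net.weights = np.array([0.9, 0.7])
        net.verified = np.array([True, False])
        core = extract_core_subnetwork(net, ["a1"], ["b1", "b2"], self._records())
        path = tmp_path / "core.graphml"
        nx.write_graphml(core.graph, path)
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(core.graph.nodes)
        for n in core.graph.nodes:
            assert back.nodes[n]["source_set"] == core.graph.nodes[n]["source_set"]
            assert back.nodes[n]["empirical_p"] == pytest.approx(
                core.graph.nodes[n]["empirical_p"]
            )
        assert back["a1"]["b1"]["weight"] == pytest.approx(0.9)
        assert back["a1"]["b1"]["verified"] is True
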