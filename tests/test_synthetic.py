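"""Generators: networks, planted crosstalk, contrast tables, expression."""

import numpy as np
import pandas as pd
import pytest

from abacross import (
    ExpressionSimSpec,
    NetworkSpec,
    PlantedCrosstalkSpec,
    classify_degs,
    generate_contrast_table,
    generate_expression_matrix,
    generate_network,
    plant_crosstalk,
)
from abacross.io import write_contrast_table
from conftest import brute_force_cross_counts

SMALL_CLASS_COUNTS = {
    "ABA_DEPENDENT": 10,
    "ABA_INDEPENDENT": 40,
    "NOT_RECOVERED": 10,
    "NON_DEG": 140,
}


class TestGenerateNetwork:
    def test_saturated_erdos_renyi_is_complete(self):
        net = generate_network(
            NetworkSpec(n_nodes=4, mean_degree=3, model="erdos_renyi", seed=1)
        )
        assert net.n_edges == 6  # K4

    def test_mean_degree_near_target(self):
        net = generate_network(NetworkSpec(n_nodes=1000, mean_degree=8, seed=7))
        assert abs(net.mean_degree() - 8) / 8 < 0.10

    def test_seed_sensitivity_and_determinism(self):
        a = generate_network(NetworkSpec(n_nodes=1000, mean_degree=8, seed=7))
        b = generate_network(NetworkSpec(n_nodes=1000, mean_degree=8, seed=8))
        a2 = generate_network(NetworkSpec(n_nodes=1000, mean_degree=8, seed=7))
        assert not np.array_equal(a.edges, b.edges)
        assert np.array_equal(a.edges, a2.edges)
        assert np.array_equal(a.weights, a2.weights)

    def test_simple_graph_with_weights_in_range(self):
        spec = NetworkSpec(n_nodes=200, mean_degree=6, weight_range=(0.7, 0.9), seed=3)
        net = generate_network(spec)
        assert (net.edges[:, 0] < net.edges[:, 1]).all()
        assert ((net.weights >= 0.7) & (net.weights <= 0.9)).all()
        assert net.nodes[0] == "SYN00001"

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(n_nodes=3, mean_degree=1), "n_nodes"),
            (dict(n_nodes=10, mean_degree=9.5), "mean_degree"),
            (dict(n_nodes=10, mean_degree=2, weight_range=(0.0, 1.0)), "weight_range"),
            (dict(n_nodes=10, mean_degree=2, model="smallworld"), "model"),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            generate_network(NetworkSpec(seed=0, **kwargs))

    def test_powerlaw_model_runs(self):
        net = generate_network(
            NetworkSpec(n_nodes=300, mean_degree=6, model="powerlaw", seed=2)
        )
        assert abs(net.mean_degree() - 6) / 6 < 0.15


@pytest.fixture(scope="module")
def base_net():
    return generate_network(NetworkSpec(n_nodes=2000, mean_degree=8, seed=11))


class TestPlantCrosstalk:

    def test_null_spec_returns_identical_graph(self, base_net):
        spec = PlantedCrosstalkSpec(size_A=50, size_B=200, enrichment_factor=1.0, seed=4)
        out, manifest = plant_crosstalk(base_net, spec)
        assert np.array_equal(out.edges, base_net.edges)
        assert manifest.n_added_edges == 0

    def test_enrichment_factor_realized(self, base_net):
        spec = PlantedCrosstalkSpec(size_A=50, size_B=200, enrichment_factor=5.0, seed=5)
        out, manifest = plant_crosstalk(base_net, spec)
        expected = 5.0 * manifest.expected_background_cross
        # realized = planted 4x expectation + Poisson-noisy background
        assert manifest.global_cross_count == pytest.approx(expected, rel=0.15)

    def test_core_bookkeeping_and_manifest_recomputable(self, base_net):
        spec = PlantedCrosstalkSpec(
            size_A=50, size_B=200, enrichment_factor=3.0,
            n_core_A=5, n_core_B=7, seed=6,
        )
        out, manifest = plant_crosstalk(base_net, spec)
        assert len(manifest.core_A) == 5
        assert len(manifest.core_B) == 7
        assert set(manifest.core_A) <= set(manifest.set_A)
        # brute-force recount from the emitted network equals the manifest
        per_gene, total = brute_force_cross_counts(
            out.edge_gene_pairs(), set(manifest.set_A), set(manifest.set_B)
        )
        assert total == manifest.global_cross_count
        assert per_gene == manifest.per_gene_cross_counts

    def test_core_genes_exceed_background_cross_degree(self, base_net):
        spec = PlantedCrosstalkSpec(
            size_A=50, size_B=200, enrichment_factor=1.0,
            n_core_A=5, n_core_B=0, core_excess=10.0, seed=7,
        )
        out, manifest = plant_crosstalk(base_net, spec)
        target = round(10.0 * base_net.density() * 200)
        for g in manifest.core_A:
            assert manifest.per_gene_cross_counts[g] >= target

    def test_unreachable_enrichment_errors(self):
        net = generate_network(NetworkSpec(n_nodes=30, mean_degree=20, seed=8))
        spec = PlantedCrosstalkSpec(size_A=5, size_B=5, enrichment_factor=3.0, seed=9)
        with pytest.raises(ValueError, match="unreachable"):
            plant_crosstalk(net, spec)

    def test_explicit_sets_are_respected(self, base_net):
        A = [str(g) for g in base_net.nodes[:10]]
        B = [str(g) for g in base_net.nodes[10:40]]
        spec = PlantedCrosstalkSpec(size_A=0, size_B=0, enrichment_factor=2.0, seed=10)
        out, manifest = plant_crosstalk(base_net, spec, sets=(A, B))
        assert manifest.set_A == sorted(A)
        assert manifest.set_B == sorted(B)
        with pytest.raises(ValueError, match="disjoint"):
            plant_crosstalk(base_net, spec, sets=(A, A))


class TestGenerateContrastTable:
    def test_round_trip_recovers_every_class(self):
        spec = ExpressionSimSpec(n_genes=200, class_counts=SMALL_CLASS_COUNTS, seed=5)
        table, manifest = generate_contrast_table(spec)
        classes = classify_degs(table)
        truth = pd.Series(manifest.gene_classes)
        assert (classes == truth).all()
        counts = classes.value_counts().to_dict()
        assert counts == SMALL_CLASS_COUNTS

    def test_all_non_deg_table_has_no_drought_calls(self):
        spec = ExpressionSimSpec(
            n_genes=50, class_counts={"NON_DEG": 50}, seed=6
        )
        table, _ = generate_contrast_table(spec)
        for c in ("drought10", "drought12"):
            passing = (table[f"log2fc_{c}"].abs() >= 1) & (table[f"p_{c}"] < 0.05)
            assert not passing.any()

    def test_fixed_seed_gives_byte_identical_tsv(self, tmp_path):
        spec = ExpressionSimSpec(n_genes=80, class_counts={
            "ABA_DEPENDENT": 5, "ABA_INDEPENDENT": 20,
            "NOT_RECOVERED": 5, "NON_DEG": 50}, seed=7)
        paths = []
        for name in ("a.tsv", "b.tsv"):
            table, _ = generate_contrast_table(spec)
            write_contrast_table(table, tmp_path / name)
            paths.append((tmp_path / name).read_bytes())
        assert paths[0] == paths[1]

    def test_label_noise_breaks_some_classifications(self):
        spec = ExpressionSimSpec(n_genes=200, class_counts=SMALL_CLASS_COUNTS,
                                 label_noise=0.3, seed=8)
        table, manifest = generate_contrast_table(spec)
        truth = pd.Series(manifest.gene_classes)
        agreement = (classify_degs(table) == truth).mean()
        assert 0.5 < agreement < 1.0

    def test_class_counts_must_sum(self):
        with pytest.raises(ValueError, match="class_counts"):
            ExpressionSimSpec(n_genes=10, class_counts={"NON_DEG": 5})


class TestGenerateExpressionMatrix:
    def test_shape_and_determinism(self):
        spec = ExpressionSimSpec(n_genes=60, class_counts={
            "ABA_DEPENDENT": 10, "ABA_INDEPENDENT": 20,
            "NOT_RECOVERED": 0, "NON_DEG": 30}, seed=9)
        a = generate_expression_matrix(spec, n_samples=10)
        b = generate_expression_matrix(spec, n_samples=10)
        assert a.shape == (60, 10)
        assert a.equals(b)
        assert (a.to_numpy() > 0).all()

    def test_zero_correlation_gives_near_zero_pairwise_corr(self):
        spec = ExpressionSimSpec(n_genes=40, class_counts={
            "ABA_DEPENDENT": 10, "ABA_INDEPENDENT": 10,
            "NOT_RECOVERED": 0, "NON_DEG": 20},
            within_class_corr=0.0, seed=10)
        expr = generate_expression_matrix(spec, n_samples=100)
        corr = np.corrcoef(np.log(expr.to_numpy()))
        off = corr[np.triu_indices(40, k=1)]
        assert abs(off.mean()) < 3 / np.sqrt(100)

    def test_within_class_exceeds_between_class_correlation(self):
        spec = ExpressionSimSpec(n_genes=60, class_counts={
            "ABA_DEPENDENT": 20, "ABA_INDEPENDENT": 20,
            "NOT_RECOVERED": 0, "NON_DEG": 20},
            within_class_corr=0.9, seed=11)
        expr = generate_expression_matrix(spec, n_samples=200)
        truth = pd.Series(
            {g: c for g, c in zip(expr.index,
             pd.Series(generate_contrast_table(spec)[1].gene_classes)[expr.index])}
        )
        logx = np.log(expr.to_numpy())
        corr = np.corrcoef(logx)
        same = np.equal.outer(truth.to_numpy(), truth.to_numpy())
        iu = np.triu_indices(60, k=1)
        within = corr[iu][same[iu]]
        between = corr[iu][~same[iu]]
        assert within.mean() > between.mean() + 0.3

    def test_shared_drought_factor_plants_cross_class_correlation(self):
        kwargs = dict(n_genes=60, class_counts={
            "ABA_DEPENDENT": 20, "ABA_INDEPENDENT": 20,
            "NOT_RECOVERED": 0, "NON_DEG": 20},
            within_class_corr=0.6, seed=12)
        flat = ExpressionSimSpec(drought_shared_corr=0.0, **kwargs)
        shared = ExpressionSimSpec(drought_shared_corr=0.5, **kwargs)
        truth = pd.Series(generate_contrast_table(flat)[1].gene_classes)
        a_idx = truth.index[truth == "ABA_DEPENDENT"]
        b_idx = truth.index[truth == "ABA_INDEPENDENT"]

        def cross_corr(spec):
            expr = generate_expression_matrix(spec, n_samples=200)
            la = np.log(expr.loc[a_idx].to_numpy())
            lb = np.log(expr.loc[b_idx].to_numpy())
            c = np.corrcoef(np.vstack([la, lb]))[: len(a_idx), len(a_idx):]
            return c.mean()

        assert cross_corr(flat) < 0.15
        assert cross_corr(shared) > 0.3

    def test_too_few_samples_rejected(self):
        spec = ExpressionSimSpec(n_genes=10, class_counts={"NON_DEG": 10}, seed=1)
        with pytest.raises(ValueError, match="n_samples"):
            generate_expression_matrix(spec, n_samples=2)
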