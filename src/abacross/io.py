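"""File formats, configuration and the end-to-end pipeline.

Canonical tabular dialect: TSV with a header row and '.' decimals.
Networks are exchanged as edge-list TSV and exported as SIF
(``geneA<TAB>pp<TAB>geneB``) and GraphML for Cytoscape. All writers are
deterministic: rerunning the pipeline with the same config and inputs
reproduces byte-identical TSV/SIF/GraphML outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import deg as deg_mod
from . import stats as stats_mod
from . import synthetic as syn_mod
from .deg import CONTRASTS, DegClass, DegThresholds
from .netrand import build_ensemble
from .network import InteractionNetwork

__all__ = [
    "PipelineConfig",
    "read_edge_list",
    "write_edge_list",
    "read_contrast_table",
    "write_contrast_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_sif",
    "read_sif",
    "write_outputs",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


# ----------------------------------------------------------------------
# tabular readers / writers
# ----------------------------------------------------------------------
def read_contrast_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    table.index = table.index.astype(str).str.upper()
    if table.index.has_duplicates:
        raise ValueError(f"duplicate gene_ids in {path}")
    return table


def write_contrast_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_expression_matrix(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col="gene_id")
    expr.index = expr.index.astype(str).str.upper()
    return expr


def write_expression_matrix(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", float_format=FLOAT_FMT)


# ----------------------------------------------------------------------
# edge lists
# ----------------------------------------------------------------------
def _try_float(s: str):
    try:
        return float(s)
    except ValueError:
        return None


def read_edge_list(path, min_weight: float | None = None) -> InteractionNetwork:
    """Read a (gene_a, gene_b[, weight[, verified]]) TSV into a network.

    A header row is detected when the weight field of the first row is
    non-numeric (or, for two-column files, when the fields look like
    column names). Gene ids are uppercased for matching. Self-loops are
    dropped and duplicate rows (including reversed duplicates) collapsed
    keeping the maximum weight; both counts are logged. ``min_weight``
    optionally discards low-confidence interactions at load time.
    """
    path = Path(path)
    best: dict[tuple[str, str], tuple[float, bool]] = {}
    n_dup = n_self = n_filtered = n_rows = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1:
                looks_header = (
                    (len(fields) >= 3 and _try_float(fields[2]) is None)
                    or fields[0].strip().lower() in ("gene_a", "source", "protein_a")
                )
                if looks_header:
                    continue
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            a, b = fields[0].strip().upper(), fields[1].strip().upper()
            w = 1.0
            if len(fields) >= 3 and fields[2].strip():
                wv = _try_float(fields[2])
                if wv is None:
                    raise ValueError(
                        f"{path}: non-numeric weight at line {lineno}: {fields[2]!r}"
                    )
                w = wv
            ver = False
            if len(fields) >= 4 and fields[3].strip():
                ver = fields[3].strip() not in ("0", "false", "False")
            n_rows += 1
            if a == b:
                n_self += 1
                continue
            if min_weight is not None and w < min_weight:
                n_filtered += 1
                continue
            key = (a, b) if a < b else (b, a)
            if key in best:
                n_dup += 1
                w_old, v_old = best[key]
                best[key] = (max(w_old, w), v_old or ver)
            else:
                best[key] = (w, ver)
    if n_rows == 0:
        raise ValueError(f"{path}: empty edge list")
    if n_self or n_dup or n_filtered:
        logger.info(
            "read_edge_list(%s): dropped %d self-loop(s), collapsed %d "
            "duplicate(s), filtered %d below min_weight",
            path, n_self, n_dup, n_filtered,
        )
    pairs = sorted(best)
    return InteractionNetwork.from_gene_pairs(
        pairs,
        weights=[best[k][0] for k in pairs],
        verified=[best[k][1] for k in pairs],
    )


def write_edge_list(net: InteractionNetwork, path) -> None:
    cols = {"gene_a": [str(net.nodes[u]) for u in net.edges[:, 0]],
            "gene_b": [str(net.nodes[v]) for v in net.edges[:, 1]]}
    cols["weight"] = net.weights if net.weights is not None else np.ones(net.n_edges)
    if net.verified is not None:
        cols["verified"] = net.verified.astype(int)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ----------------------------------------------------------------------
# network exports
# ----------------------------------------------------------------------
def write_sif(graph: nx.Graph, path) -> None:
    """Cytoscape SIF export (`pp` relation); isolated nodes as bare lines."""
    lines = []
    for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
        lines.append(f"{a}\tpp\t{b}")
    connected = {n for e in graph.edges() for n in e}
    for n in sorted(set(graph.nodes()) - connected):
        lines.append(str(n))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_sif(path) -> nx.Graph:
    g = nx.Graph()
    for line in Path(path).read_text().splitlines():
        fields = line.split("\t")
        if len(fields) >= 3:
            g.add_edge(fields[0], fields[2])
        elif len(fields) == 1 and fields[0]:
            g.add_node(fields[0])
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
@dataclass
class PipelineConfig:
    """Flat, fully serializable pipeline configuration.

    Paths left as None are simulated from the synthetic-data module
    using the ``sim_*`` parameters.
    """

    # inputs (None -> simulate)
    contrast_table: str | None = None
    edge_list: str | None = None
    expression_matrix: str | None = None
    out_dir: str = "abacross_out"
    # DEG thresholds
    min_fold_change: float = 2.0
    max_p: float = 0.05
    require_concordant_sign: bool = False
    # network / null model
    min_edge_weight: float | None = None
    replicates: int = 1000
    swap_multiplier: int = 10
    # enrichment
    alpha: float = 0.05
    pseudocount_p: bool = False
    n_resamples: int = 100
    top_fraction: float = 0.01
    # simulation parameters (used only when inputs are not provided)
    sim_n_nodes: int = 2000
    sim_mean_degree: float = syn_mod.DEFAULT_MEAN_DEGREE
    sim_model: str = "configuration_poisson"
    sim_size_a: int = 50
    sim_size_b: int = 200
    sim_enrichment_factor: float = 5.0
    sim_n_core_a: int = 10
    sim_n_core_b: int = 10
    sim_core_excess: float = 10.0
    sim_n_samples: int = 50
    sim_label_noise: float = 0.0
    # master seed for every stochastic stage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.swap_multiplier < 1:
            raise ValueError("swap_multiplier must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        DegThresholds(self.min_fold_change, self.max_p)  # range check

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    def thresholds(self) -> DegThresholds:
        return DegThresholds(self.min_fold_change, self.max_p)


# ----------------------------------------------------------------------
# outputs
# ----------------------------------------------------------------------
def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(results: dict, config: PipelineConfig, out_dir) -> dict:
    """Write all result tables/exports plus config echo, log and manifest.

    Returns the manifest: a mapping of file name to SHA-256 checksum.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    config.to_yaml(out / "config.yaml")

    if "contrast_table" in results:
        write_contrast_table(results["contrast_table"], out / "contrast_table.tsv")
    if "network" in results:
        write_edge_list(results["network"], out / "edge_list.tsv")
    if "expression" in results:
        write_expression_matrix(results["expression"], out / "expression_matrix.tsv")
    if "ground_truth" in results:
        results["ground_truth"].to_json(out / "ground_truth.json")

    classes = results["classes"]
    classes.rename("deg_class").to_csv(out / "deg_classes.tsv", sep="\t")
    for cls in DegClass:
        genes = sorted(classes.index[classes == cls.value])
        (out / f"genes_{cls.value}.txt").write_text(
            "\n".join(genes) + ("\n" if genes else "")
        )

    results["records"].to_csv(
        out / "per_gene_enrichment.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    glob = results["global"]
    zc = results.get("zscore_comparison")
    coex = results.get("coexpression")
    core = results["core_subnetwork"]
    summary = {
        "n_observed_cross_edges": glob.n_observed,
        "null_mean": glob.mu_null,
        "null_sd": glob.sd_null,
        "z_score": glob.z_score,
        "replicates": glob.R,
        "n_core_A": len(core.core_A),
        "n_core_B": len(core.core_B),
        "n_core_genes": len(core.core_A) + len(core.core_B),
        "n_core_cross_edges": core.n_cross_edges,
        "n_core_total_edges": core.n_total_edges,
    }
    if zc is not None:
        summary.update(
            zscore_ttest_t=zc.t_statistic,
            zscore_ttest_p=zc.p_value,
            mean_z_deg=float(np.mean(zc.z_deg)),
            mean_z_nondeg=float(np.mean(zc.z_nondeg)),
        )
    if coex is not None:
        summary.update(
            coexpression_threshold=coex.correlation_threshold,
            coexpression_links_observed=coex.n_links_observed,
            coexpression_links_null_mean=coex.mean_links_null,
            coexpression_fold_enrichment=coex.fold_enrichment,
        )
    pd.DataFrame([summary]).T.rename(columns={0: "value"}).to_csv(
        out / "global_summary.tsv", sep="\t", float_format=FLOAT_FMT,
        index_label="statistic",
    )

    if zc is not None:
        nmax = max(len(zc.z_deg), len(zc.z_nondeg))
        pd.DataFrame({
            "z_deg": np.pad(zc.z_deg, (0, nmax - len(zc.z_deg)),
                            constant_values=np.nan),
            "z_nondeg": np.pad(zc.z_nondeg, (0, nmax - len(zc.z_nondeg)),
                               constant_values=np.nan),
        }).to_csv(out / "zscore_comparison.tsv", sep="\t", index=False,
                  float_format=FLOAT_FMT)

    write_sif(core.graph, out / "core_subnetwork.sif")
    write_graphml(core.graph, out / "core_subnetwork.graphml")

    (out / "run.log").write_text("\n".join(results.get("log", [])) + "\n")

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------
def run_pipeline(config: PipelineConfig) -> dict:
    """classify -> randomize -> enrich -> report, on provided or simulated inputs.

    Returns the output-file manifest. Every stochastic stage is seeded
    from ``config.seed``, so a fixed config reproduces byte-identical
    TSV/SIF outputs.
    """
    log: list[str] = []

    def stage(msg: str) -> None:
        log.append(msg)
        logger.info(msg)

    results: dict = {"log": log}
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]
    stage(f"seed: master={config.seed} derived={seeds}")

    # ---- inputs -------------------------------------------------------
    simulate = config.contrast_table is None or config.edge_list is None
    if simulate:
        net_spec = syn_mod.NetworkSpec(
            n_nodes=config.sim_n_nodes, mean_degree=config.sim_mean_degree,
            model=config.sim_model, seed=seeds[0],
        )
        plant_spec = syn_mod.PlantedCrosstalkSpec(
            size_A=config.sim_size_a, size_B=config.sim_size_b,
            enrichment_factor=config.sim_enrichment_factor,
            n_core_A=config.sim_n_core_a, n_core_B=config.sim_n_core_b,
            core_excess=config.sim_core_excess, seed=seeds[1],
        )
        sim = syn_mod.simulate_study(
            net_spec, plant_spec, n_samples=config.sim_n_samples
        )
        table = sim["contrast_table"]
        net = sim["network"]
        results["contrast_table"] = table
        results["network"] = net
        results["ground_truth"] = sim["manifest"]
        if "expression" in sim:
            results["expression"] = sim["expression"]
        stage(
            f"simulate: {net.n_nodes} nodes, {net.n_edges} edges, "
            f"planted |A|={config.sim_size_a} |B|={config.sim_size_b} "
            f"enrichment x{config.sim_enrichment_factor}"
        )
    else:
        table = read_contrast_table(config.contrast_table)
        net = read_edge_list(config.edge_list, min_weight=config.min_edge_weight)
        stage(
            f"inputs: contrast table {table.shape[0]} genes; network "
            f"{net.n_nodes} nodes / {net.n_edges} edges"
        )
    expr = results.get("expression")
    if expr is None and config.expression_matrix is not None:
        expr = read_expression_matrix(config.expression_matrix)
        results["expression"] = expr

    # ---- classify -----------------------------------------------------
    classes = deg_mod.classify_degs(
        table, config.thresholds(),
        require_concordant_sign=config.require_concordant_sign,
    )
    results["classes"] = classes
    counts = deg_mod.class_counts(classes)
    stage(f"classify: {counts}")
    sets = deg_mod.class_gene_sets(classes)
    set_A = sets[DegClass.ABA_DEPENDENT.value]
    set_B = sets[DegClass.ABA_INDEPENDENT.value]
    pool = sets[DegClass.NON_DEG.value]
    if not set_A or not set_B:
        raise RuntimeError(
            "classify stage produced an empty ABA-dependent or "
            "ABA-independent set; nothing to enrich"
        )

    # ---- randomize ----------------------------------------------------
    ensemble = build_ensemble(
        net, R=config.replicates,
        swap_multiplier=config.swap_multiplier, master_seed=seeds[2],
    )
    stage(f"randomize: R={ensemble.R}, swap_multiplier={config.swap_multiplier}")

    # ---- enrich -------------------------------------------------------
    records = stats_mod.per_gene_enrichment(
        net, ensemble, set_A, set_B, pseudocount=config.pseudocount_p
    )
    results["records"] = records
    glob = stats_mod.global_enrichment(net, ensemble, set_A, set_B)
    results["global"] = glob
    stage(
        f"enrich: N_observed={glob.n_observed} mu_null={glob.mu_null:.2f} "
        f"sd_null={glob.sd_null:.2f} Z={glob.z_score:.2f}"
    )
    core_A, core_B = stats_mod.select_core_components(records, alpha=config.alpha)
    core = stats_mod.extract_core_subnetwork(net, core_A, core_B, records)
    results["core_subnetwork"] = core
    stage(
        f"core: |A|={len(core_A)} |B|={len(core_B)} "
        f"cross_edges={core.n_cross_edges} total_edges={core.n_total_edges}"
    )

    pool_in_net = {g for g in pool if g in net.node_index}
    try:
        zc = stats_mod.compare_zscores(
            net, ensemble, set_A, set_B, pool_in_net,
            n_resamples=config.n_resamples, seed=seeds[3],
        )
        results["zscore_comparison"] = zc
        stage(
            f"compare_zscores: mean z_deg={np.mean(zc.z_deg):.2f} "
            f"mean z_nondeg={np.mean(zc.z_nondeg):.2f} p={zc.p_value:.3g}"
        )
    except ValueError as exc:
        stage(f"compare_zscores skipped: {exc}")

    if expr is not None:
        try:
            coex = stats_mod.coexpression_enrichment(
                expr, set_A, set_B, pool,
                top_fraction=config.top_fraction,
                n_resamples=config.n_resamples, seed=seeds[3],
            )
            results["coexpression"] = coex
            stage(
                f"coexpression: links={coex.n_links_observed} "
                f"fold={coex.fold_enrichment:.2f}"
            )
        except ValueError as exc:
            stage(f"coexpression skipped: {exc}")

    # ---- report -------------------------------------------------------
    manifest = write_outputs(results, config, config.out_dir)
    stage(f"report: {len(manifest)} files written to {config.out_dir}")
    return manifest
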