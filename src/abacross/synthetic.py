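"""Synthetic data with known ground truth for the crosstalk pipeline.

Three generators emulate the pipeline's real inputs at reduced scale:

* a protein-protein interaction network (configuration model with
  Poisson degrees by default) with uniform edge confidences, optionally
  with *planted* cross-set edge enrichment between an "ABA-dependent"
  set A and an "ABA-independent" set B, plus designated core genes that
  receive a further cross-edge excess;
* a per-gene contrast table (log2 fold change and p-value for the four
  contrasts drought10 / drought12 / rewater2 / aba4) in which every gene
  is drawn from a known DEG class; with zero label noise the emitted
  values are guaranteed to classify back to the true class under the
  default thresholds (fold change >= 2, p < 0.05);
* a log-normal expression matrix in which genes of the same responsive
  class share a latent factor, so co-expression structure is plantable.

Every generator is a pure function of its spec (including the seed), and
the returned :class:`GroundTruthManifest` suffices to recompute every
planted quantity by brute force.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import networkx as nx

from .deg import CONTRASTS, DegClass
from .network import InteractionNetwork

__all__ = [
    "NetworkSpec",
    "PlantedCrosstalkSpec",
    "ExpressionSimSpec",
    "GroundTruthManifest",
    "generate_network",
    "plant_crosstalk",
    "generate_contrast_table",
    "generate_expression_matrix",
    "simulate_study",
]

NETWORK_MODELS = ("configuration_poisson", "erdos_renyi", "powerlaw")

#: Default mean degree. The real Arabidopsis PPI substrate has
#: 2 * 316,747 / 12,574 ~ 50.4 interactions per protein; scaled-down
#: networks keep the per-gene degree (the effective sample size of every
#: per-gene statistic) rather than the edge density.
DEFAULT_MEAN_DEGREE = 50.0


def _gene_ids(n: int) -> np.ndarray:
    return np.array([f"SYN{i + 1:05d}" for i in range(n)], dtype=object)


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of the synthetic PPI network."""

    n_nodes: int
    mean_degree: float = DEFAULT_MEAN_DEGREE
    model: str = "configuration_poisson"
    weight_range: tuple = (0.5, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValueError(f"n_nodes must be >= 4, got {self.n_nodes}")
        # equality allowed: mean_degree == n_nodes - 1 is the saturated graph
        if not 0 < self.mean_degree <= self.n_nodes - 1:
            raise ValueError(
                f"mean_degree must be in (0, n_nodes - 1]; got "
                f"mean_degree={self.mean_degree} with n_nodes={self.n_nodes}"
            )
        if self.model not in NETWORK_MODELS:
            raise ValueError(f"model must be one of {NETWORK_MODELS}, got '{self.model}'")
        lo, hi = self.weight_range
        if not 0 < lo <= hi <= 1:
            raise ValueError(f"weight_range must satisfy 0 < low <= high <= 1, got {self.weight_range}")


@dataclass(frozen=True)
class PlantedCrosstalkSpec:
    """Planted cross-set enrichment between gene sets A and B.

    ``enrichment_factor`` multiplies the background edge probability for
    A-B pairs; ``core_excess`` is the per-gene multiplier applied to the
    designated core genes' expected cross-edge count.
    """

    size_A: int
    size_B: int
    enrichment_factor: float = 1.0
    n_core_A: int = 0
    n_core_B: int = 0
    core_excess: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_A < 0 or self.size_B < 0:
            raise ValueError("set sizes must be non-negative")
        if self.enrichment_factor < 1:
            raise ValueError(f"enrichment_factor must be >= 1, got {self.enrichment_factor}")
        if self.n_core_A > self.size_A or self.n_core_B > self.size_B:
            raise ValueError("core counts cannot exceed set sizes")
        if self.n_core_A < 0 or self.n_core_B < 0:
            raise ValueError("core counts must be non-negative")


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Parameters of the simulated contrast table / expression matrix.

    ``class_counts`` maps DEG class name to gene count and must sum to
    ``n_genes``. True DEGs get ``|log2FC| = 1 + Exp(effect_log2fc - 1)``
    (mean ``effect_log2fc``, always past the two-fold boundary) and
    p-values from a Beta(0.5, 20) truncated below the 0.05 calling
    threshold; non-responsive contrasts get uniform p-values and small
    fold changes, rejection-sampled to fail the thresholds. With
    ``label_noise`` > 0, that fraction of genes emits data drawn from a
    random *other* class while the manifest keeps the true label.
    """

    n_genes: int
    class_counts: dict = field(
        default_factory=lambda: {
            "ABA_DEPENDENT": 50,
            "ABA_INDEPENDENT": 200,
            "NOT_RECOVERED": 50,
            "NON_DEG": 1700,
        }
    )
    effect_log2fc: float = 2.5
    de_p_beta: tuple = (0.5, 20.0)
    label_noise: float = 0.0
    within_class_corr: float = 0.6
    drought_shared_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_log2fc <= 1:
            raise ValueError(f"effect_log2fc must be > 1, got {self.effect_log2fc}")
        total = sum(self.class_counts.values())
        if total != self.n_genes:
            raise ValueError(
                f"class_counts sum to {total}, expected n_genes={self.n_genes}"
            )
        unknown = set(self.class_counts) - {c.value for c in DegClass}
        if unknown:
            raise ValueError(f"unknown DEG classes in class_counts: {sorted(unknown)}")
        if not 0 <= self.label_noise < 1:
            raise ValueError(f"label_noise must be in [0, 1), got {self.label_noise}")
        if not 0 <= self.within_class_corr < 1:
            raise ValueError("within_class_corr must be in [0, 1)")
        if not 0 <= self.drought_shared_corr <= self.within_class_corr:
            raise ValueError("drought_shared_corr must be in [0, within_class_corr]")


@dataclass
class GroundTruthManifest:
    """Everything needed to recompute planted quantities by brute force."""

    gene_classes: dict | None = None          # gene_id -> true DEG class
    set_A: list | None = None                 # planted "ABA-dependent" genes
    set_B: list | None = None                 # planted "ABA-independent" genes
    core_A: list | None = None
    core_B: list | None = None
    per_gene_cross_counts: dict | None = None # realized cross-set edges per gene
    global_cross_count: int | None = None     # realized A-B edge total
    expected_background_cross: float | None = None  # |A|*|B|*density
    n_added_edges: int | None = None
    enrichment_factor: float | None = None
    core_excess: float | None = None
    seeds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def merged_with(self, other: "GroundTruthManifest") -> "GroundTruthManifest":
        out = GroundTruthManifest(**asdict(self))
        for k, v in asdict(other).items():
            if v not in (None, {}, []):
                if k == "seeds":
                    out.seeds = {**out.seeds, **v}
                else:
                    setattr(out, k, v)
        return out


# ----------------------------------------------------------------------
# network generation
# ----------------------------------------------------------------------
def generate_network(spec: NetworkSpec) -> InteractionNetwork:
    """Generate a simple undirected network per the spec.

    Node labels are synthetic AGI-like identifiers (``SYN00001`` ...);
    every edge carries a confidence weight sampled uniformly from
    ``spec.weight_range``. Identical spec (including seed) yields an
    identical graph.
    """
    ss = np.random.SeedSequence(spec.seed)
    s_graph, s_weight = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]
    n = spec.n_nodes
    if spec.model == "erdos_renyi":
        p = min(1.0, spec.mean_degree / (n - 1))
        g = nx.gnp_random_graph(n, p, seed=s_graph)
    elif spec.model == "configuration_poisson":
        rng = np.random.default_rng(s_graph)
        deg = np.minimum(rng.poisson(spec.mean_degree, size=n), n - 1)
        if deg.sum() % 2 == 1:  # parity fix: one extra stub on a random node
            candidates = np.flatnonzero(deg < n - 1)
            deg[rng.choice(candidates)] += 1
        try:
            mg = nx.configuration_model(deg.tolist(), seed=s_graph)
        except nx.NetworkXError as exc:  # pragma: no cover - defensive
            raise ValueError(
                f"infeasible degree sequence for configuration model "
                f"(n_nodes={n}, mean_degree={spec.mean_degree}): {exc}"
            ) from exc
        g = nx.Graph(mg)  # collapse parallel edges
        g.remove_edges_from(nx.selfloop_edges(g))
    else:  # powerlaw via preferential attachment
        m = max(1, round(spec.mean_degree / 2))
        if m >= n:
            raise ValueError(
                f"infeasible powerlaw parameters (n_nodes={n}, mean_degree={spec.mean_degree})"
            )
        g = nx.barabasi_albert_graph(n, m, seed=s_graph)

    ids = _gene_ids(n)
    edges = np.asarray(sorted((min(a, b), max(a, b)) for a, b in g.edges()), dtype=np.int64)
    net = InteractionNetwork(nodes=ids, edges=edges.reshape(-1, 2))
    rng_w = np.random.default_rng(s_weight)
    lo, hi = spec.weight_range
    net.weights = rng_w.uniform(lo, hi, size=net.n_edges)
    return net


def _realized_cross_counts(net: InteractionNetwork, idx_A, idx_B):
    """Per-gene and global cross-set edge counts on the final graph."""
    maskA = np.zeros(net.n_nodes, dtype=bool)
    maskB = np.zeros(net.n_nodes, dtype=bool)
    maskA[idx_A] = True
    maskB[idx_B] = True
    u, v = net.edges[:, 0], net.edges[:, 1]
    cross = (maskA[u] & maskB[v]) | (maskB[u] & maskA[v])
    per_gene = np.zeros(net.n_nodes, dtype=np.int64)
    np.add.at(per_gene, u[cross], 1)
    np.add.at(per_gene, v[cross], 1)
    counts = {
        str(net.nodes[i]): int(per_gene[i])
        for i in np.concatenate([idx_A, idx_B])
    }
    return counts, int(cross.sum())


def plant_crosstalk(
    net: InteractionNetwork,
    spec: PlantedCrosstalkSpec,
    sets: tuple | None = None,
) -> tuple[InteractionNetwork, GroundTruthManifest]:
    """Add cross-set edges so the A-B edge probability is enriched.

    ``enrichment_factor - 1`` times the expected background cross-edge
    count (``|A| * |B| * density``) is added between A and B; each core
    gene is then topped up to ``core_excess`` times its expected
    background cross-edge count. Planting adds edges (it never rewires),
    so the background degree statistics stay interpretable; the manifest
    records the realized counts.

    ``sets`` optionally fixes the gene-id membership of A and B (e.g. the
    classes called from a simulated contrast table); otherwise the sets
    are drawn at random from the network's nodes using ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = net.n_nodes
    if sets is not None:
        gene_A, gene_B = sets
        idx = net.node_index
        missing = [g for g in list(gene_A) + list(gene_B) if g not in idx]
        if missing:
            raise ValueError(f"genes not in network: {missing[:5]}")
        idx_A = np.array(sorted(idx[g] for g in gene_A), dtype=np.int64)
        idx_B = np.array(sorted(idx[g] for g in gene_B), dtype=np.int64)
        if np.intersect1d(idx_A, idx_B).size:
            raise ValueError("sets A and B must be disjoint")
    else:
        if spec.size_A + spec.size_B > n:
            raise ValueError(
                f"size_A + size_B = {spec.size_A + spec.size_B} exceeds "
                f"n_nodes = {n}"
            )
        pick = rng.choice(n, size=spec.size_A + spec.size_B, replace=False)
        idx_A = np.sort(pick[: spec.size_A])
        idx_B = np.sort(pick[spec.size_A:])

    size_A, size_B = len(idx_A), len(idx_B)
    n_core_A = min(spec.n_core_A, size_A)
    n_core_B = min(spec.n_core_B, size_B)
    core_A = np.sort(rng.choice(idx_A, size=n_core_A, replace=False)) if n_core_A else np.array([], dtype=np.int64)
    core_B = np.sort(rng.choice(idx_B, size=n_core_B, replace=False)) if n_core_B else np.array([], dtype=np.int64)

    p_bg = net.density()
    expected_bg = size_A * size_B * p_bg
    n_add_global = int(round((spec.enrichment_factor - 1.0) * expected_bg))

    edge_keys = net.edge_key_set()
    new_edges: list[tuple[int, int]] = []

    def try_add(a: int, b: int) -> bool:
        lo, hi = (a, b) if a < b else (b, a)
        k = lo * n + hi
        if k in edge_keys or lo == hi:
            return False
        edge_keys.add(k)
        new_edges.append((lo, hi))
        return True

    if n_add_global:
        mA = np.zeros(n, dtype=bool)
        mB = np.zeros(n, dtype=bool)
        mA[idx_A] = True
        mB[idx_B] = True
        eu, ev = net.edges[:, 0], net.edges[:, 1]
        existing_cross = int(((mA[eu] & mB[ev]) | (mB[eu] & mA[ev])).sum())
        capacity = size_A * size_B - existing_cross
        if n_add_global > capacity:
            raise ValueError(
                f"requested enrichment is unreachable: {n_add_global} new "
                f"cross edges needed but only {capacity} simple-graph slots remain"
            )
        added = 0
        while added < n_add_global:
            a = int(idx_A[rng.integers(size_A)])
            b = int(idx_B[rng.integers(size_B)])
            if try_add(a, b):
                added += 1

    # per-gene core excess: top each core gene up to its target cross count
    for core, own_size, opp_idx in (
        (core_A, size_A, idx_B),
        (core_B, size_B, idx_A),
    ):
        opp_size = len(opp_idx)
        target = int(round(spec.core_excess * p_bg * opp_size))
        if target > opp_size:
            raise ValueError(
                f"core_excess={spec.core_excess} needs {target} cross edges "
                f"per core gene but the opposing set has only {opp_size} genes"
            )
        opp_set = set(int(i) for i in opp_idx)
        for g in core:
            g = int(g)
            current = sum(
                1 for k in opp_set
                if (min(g, k) * n + max(g, k)) in edge_keys
            )
            shortfall = target - current
            candidates = [k for k in sorted(opp_set)
                          if (min(g, k) * n + max(g, k)) not in edge_keys]
            if shortfall > 0:
                chosen = rng.choice(len(candidates), size=shortfall, replace=False)
                for ci in chosen:
                    try_add(g, candidates[int(ci)])

    if not new_edges:
        out = net.copy()
    else:
        add = np.asarray(new_edges, dtype=np.int64)
        edges = np.vstack([net.edges, add])
        if net.weights is not None:
            wlo, whi = float(net.weights.min()), float(net.weights.max())
            add_w = rng.uniform(wlo, whi, size=len(add))
            weights = np.concatenate([net.weights, add_w])
        else:
            weights = None
        verified = None
        if net.verified is not None:
            verified = np.concatenate([net.verified, np.zeros(len(add), dtype=bool)])
        out = InteractionNetwork(nodes=net.nodes.copy(), edges=edges,
                                 weights=weights, verified=verified)

    per_gene, global_cross = _realized_cross_counts(out, idx_A, idx_B)
    manifest = GroundTruthManifest(
        set_A=[str(net.nodes[i]) for i in idx_A],
        set_B=[str(net.nodes[i]) for i in idx_B],
        core_A=[str(net.nodes[i]) for i in core_A],
        core_B=[str(net.nodes[i]) for i in core_B],
        per_gene_cross_counts=per_gene,
        global_cross_count=global_cross,
        expected_background_cross=expected_bg,
        n_added_edges=len(new_edges),
        enrichment_factor=spec.enrichment_factor,
        core_excess=spec.core_excess,
        seeds={"plant": spec.seed},
    )
    return out, manifest


# ----------------------------------------------------------------------
# contrast table generation
# ----------------------------------------------------------------------
def _assign_classes(spec: ExpressionSimSpec) -> pd.Series:
    """Deterministic gene -> true-class assignment shared by both generators."""
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    labels = []
    for cls in (c.value for c in DegClass):
        labels.extend([cls] * spec.class_counts.get(cls, 0))
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)
    return pd.Series(labels, index=_gene_ids(spec.n_genes), name="true_class")


def _draw_de(rng, spec: ExpressionSimSpec) -> tuple[float, float]:
    """(log2fc, p) guaranteed to pass |log2fc| >= 1 and p < 0.05."""
    sign = 1.0 if rng.random() < 0.5 else -1.0
    lfc = sign * (1.0 + rng.exponential(spec.effect_log2fc - 1.0))
    a, b = spec.de_p_beta
    p = rng.beta(a, b)
    while not p < 0.05:
        p = rng.beta(a, b)
    return lfc, p


def _draw_non_de(rng) -> tuple[float, float]:
    """(log2fc, p) guaranteed to fail the DEG rule."""
    while True:
        lfc = rng.normal(0.0, 0.35)
        p = rng.random()
        if not (abs(lfc) >= 1.0 and p < 0.05):
            return lfc, p


def _emit_gene_row(rng, spec: ExpressionSimSpec, cls: str) -> dict:
    """Contrast values consistent with a DEG class."""
    row = {}
    if cls == DegClass.NON_DEG.value:
        pattern: tuple = ()
    else:
        pattern = ("drought10", "drought12", "both")[rng.integers(3)]
        pattern = ("drought10", "drought12") if pattern == "both" else (pattern,)
    for c in ("drought10", "drought12"):
        lfc, p = _draw_de(rng, spec) if c in pattern else _draw_non_de(rng)
        row[f"log2fc_{c}"], row[f"p_{c}"] = lfc, p
    # rewatering: responsive classes recover except NOT_RECOVERED
    if cls == DegClass.NOT_RECOVERED.value:
        row["log2fc_rewater2"], row["p_rewater2"] = _draw_de(rng, spec)
    else:
        row["log2fc_rewater2"], row["p_rewater2"] = _draw_non_de(rng)
    # ABA response
    if cls == DegClass.ABA_DEPENDENT.value:
        aba_de = True
    elif cls == DegClass.ABA_INDEPENDENT.value:
        aba_de = False
    elif cls == DegClass.NOT_RECOVERED.value:
        aba_de = bool(rng.random() < 0.5)  # irrelevant to the class call
    else:
        aba_de = bool(rng.random() < 0.05)  # occasional ABA-only responder
    lfc, p = _draw_de(rng, spec) if aba_de else _draw_non_de(rng)
    row["log2fc_aba4"], row["p_aba4"] = lfc, p
    return row


def generate_contrast_table(
    spec: ExpressionSimSpec,
) -> tuple[pd.DataFrame, GroundTruthManifest]:
    """Simulate the per-gene, per-contrast fold-change / p-value table.

    With ``label_noise == 0`` the default classification rules recover
    every gene's true class exactly.
    """
    classes = _assign_classes(spec)
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(3)[1])
    all_classes = [c.value for c in DegClass]
    rows = []
    for gene in classes.index:
        cls = classes[gene]
        emit_cls = cls
        if spec.label_noise and rng.random() < spec.label_noise:
            others = [c for c in all_classes if c != cls]
            emit_cls = others[rng.integers(len(others))]
        rows.append(_emit_gene_row(rng, spec, emit_cls))
    table = pd.DataFrame(rows, index=classes.index)
    table.index.name = "gene_id"
    cols = [f"{kind}_{c}" for c in CONTRASTS for kind in ("log2fc", "p")]
    table = table[cols]
    manifest = GroundTruthManifest(
        gene_classes=classes.to_dict(),
        seeds={"expression_sim": spec.seed},
    )
    return table, manifest


# ----------------------------------------------------------------------
# expression matrix generation
# ----------------------------------------------------------------------
_FACTOR_CLASSES = (
    DegClass.ABA_DEPENDENT.value,
    DegClass.ABA_INDEPENDENT.value,
    DegClass.NOT_RECOVERED.value,
)


def generate_expression_matrix(spec: ExpressionSimSpec, n_samples: int) -> pd.DataFrame:
    """Log-normal abundance matrix (genes x samples) with latent factors.

    Genes of the same *responsive* class share a latent factor giving a
    within-class log-scale Pearson correlation of ``within_class_corr``;
    ``drought_shared_corr`` adds a factor common to the ABA-dependent and
    ABA-independent classes (their shared drought response), planting
    cross-class co-expression. NON_DEG genes are mutually independent.
    Class assignment matches :func:`generate_contrast_table` for the
    same spec.
    """
    if n_samples < 3:
        raise ValueError(f"n_samples must be >= 3, got {n_samples}")
    classes = _assign_classes(spec)
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(3)[2])

    r_w = spec.within_class_corr
    r_s = spec.drought_shared_corr
    shared = rng.standard_normal(n_samples)  # drought factor
    factors = {c: rng.standard_normal(n_samples) for c in _FACTOR_CLASSES}
    mu = rng.normal(3.0, 1.5, size=spec.n_genes)

    z = np.empty((spec.n_genes, n_samples))
    for i, gene in enumerate(classes.index):
        cls = classes[gene]
        a2 = r_s if cls in (DegClass.ABA_DEPENDENT.value, DegClass.ABA_INDEPENDENT.value) else 0.0
        b2 = (r_w - a2) if cls in _FACTOR_CLASSES else 0.0
        eps = rng.standard_normal(n_samples)
        z[i] = (
            np.sqrt(a2) * shared
            + np.sqrt(b2) * factors.get(cls, 0.0)
            + np.sqrt(1.0 - a2 - b2) * eps
        )
    expr = np.exp(mu[:, None] + z)
    out = pd.DataFrame(
        expr,
        index=classes.index,
        columns=[f"sample{j + 1:03d}" for j in range(n_samples)],
    )
    out.index.name = "gene_id"
    return out


# ----------------------------------------------------------------------
# joint study simulation
# ----------------------------------------------------------------------
def simulate_study(
    network_spec: NetworkSpec,
    crosstalk_spec: PlantedCrosstalkSpec,
    expression_spec: ExpressionSimSpec | None = None,
    n_samples: int = 0,
):
    """Simulate a full study: contrast table, PPI network, ground truth.

    The contrast table's gene universe coincides with the network's node
    set; the planted sets A and B are the true ABA-dependent and
    ABA-independent genes, so classification and network enrichment see
    one consistent ground truth. Returns a dict with keys
    ``contrast_table``, ``network``, ``manifest`` and (when requested)
    ``expression``.
    """
    if expression_spec is None:
        expression_spec = ExpressionSimSpec(
            n_genes=network_spec.n_nodes,
            class_counts={
                "ABA_DEPENDENT": crosstalk_spec.size_A,
                "ABA_INDEPENDENT": crosstalk_spec.size_B,
                "NOT_RECOVERED": max(0, network_spec.n_nodes // 40),
                "NON_DEG": network_spec.n_nodes
                - crosstalk_spec.size_A
                - crosstalk_spec.size_B
                - max(0, network_spec.n_nodes // 40),
            },
            seed=network_spec.seed + 1,
        )
    if expression_spec.n_genes != network_spec.n_nodes:
        raise ValueError("expression spec gene count must match network node count")
    table, m_expr = generate_contrast_table(expression_spec)
    net = generate_network(network_spec)
    classes = pd.Series(m_expr.gene_classes)
    gene_A = sorted(classes.index[classes == DegClass.ABA_DEPENDENT.value])
    gene_B = sorted(classes.index[classes == DegClass.ABA_INDEPENDENT.value])
    planted, m_net = plant_crosstalk(net, crosstalk_spec, sets=(gene_A, gene_B))
    manifest = m_expr.merged_with(m_net)
    manifest.seeds["network"] = network_spec.seed
    out = {
        "contrast_table": table,
        "network": planted,
        "manifest": manifest,
        "expression_spec": expression_spec,
    }
    if n_samples:
        out["expression"] = generate_expression_matrix(expression_spec, n_samples)
    return out
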