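"""Cross-set interaction enrichment against the randomized ensemble.

Statistics quantifying crosstalk between two disjoint gene sets A
(ABA-dependent DEGs) and B (ABA-independent DEGs) on a PPI network:

* per-gene empirical p-values — for each gene, the fraction of null
  replicates whose cross-set edge count is greater than or equal to the
  observed count (ties in the numerator); genes with empirical p below
  alpha are the "core interacting components";
* the global Z-score, ``(N_obs - mu_null) / sd_null``, where ``N_obs``
  is the number of distinct A-B edges in the real network and the null
  moments come from the degree-preserving ensemble (sample SD, R - 1);
* a Welch t-test comparing Z-scores of the DEG set pair with Z-scores
  of size-matched gene-set pairs drawn from the non-DEG pool;
* co-expression link enrichment: A-B gene pairs in the top fraction of
  the pooled pair-correlation distribution, relative to size-matched
  non-DEG set pairs;
* extraction of the core subnetwork for export (Cytoscape SIF/GraphML).

All counts are unweighted: an interaction either exists or it does not.
Confidence weights are carried through to exports only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import _kernels
from .netrand import RandomEnsemble
from .network import InteractionNetwork

__all__ = [
    "GlobalEnrichment",
    "ZscoreComparison",
    "CoexpressionEnrichment",
    "CoreSubnetwork",
    "cross_edge_count",
    "per_gene_enrichment",
    "select_core_components",
    "global_enrichment",
    "compare_zscores",
    "coexpression_enrichment",
    "extract_core_subnetwork",
]

logger = logging.getLogger(__name__)

SET_A_LABEL = "A_ABA_dependent"
SET_B_LABEL = "B_ABA_independent"


@dataclass(frozen=True)
class GlobalEnrichment:
    """Network-level cross-set interaction enrichment."""

    n_observed: int
    mu_null: float
    sd_null: float
    z_score: float   # NaN when sd_null == 0 (flagged, never a ZeroDivisionError)
    R: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.z_score)


@dataclass(frozen=True)
class ZscoreComparison:
    """Welch t-test between DEG-pair and non-DEG-pair Z-scores."""

    z_deg: np.ndarray
    z_nondeg: np.ndarray
    t_statistic: float
    p_value: float
    n_resamples: int


@dataclass(frozen=True)
class CoexpressionEnrichment:
    """Top-correlated link enrichment between sets A and B."""

    correlation_threshold: float
    top_fraction: float
    n_links_observed: int
    mean_links_null: float
    fold_enrichment: float
    n_nondeg_resamples: int


@dataclass
class CoreSubnetwork:
    """Core interacting components and the edges among them."""

    graph: nx.Graph
    core_A: list
    core_B: list
    n_cross_edges: int    # edges with one endpoint per set
    n_total_edges: int    # all edges among core genes (incl. within-set)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------
def _resolve_sets(net: InteractionNetwork, set_A, set_B):
    """Map gene-id sets to node indices, logging genes absent from the net."""
    set_A, set_B = set(set_A), set(set_B)
    overlap = set_A & set_B
    if overlap:
        raise ValueError(f"sets A and B overlap: {sorted(overlap)[:5]}")
    idx = net.node_index
    missing = sorted(g for g in set_A | set_B if g not in idx)
    if missing:
        logger.warning(
            "%d gene(s) absent from the network are unscorable and excluded: %s%s",
            len(missing), missing[:5], "..." if len(missing) > 5 else "",
        )
    idx_A = np.array(sorted(idx[g] for g in set_A if g in idx), dtype=np.int64)
    idx_B = np.array(sorted(idx[g] for g in set_B if g in idx), dtype=np.int64)
    return idx_A, idx_B, missing


def _masks(n: int, idx_A, idx_B):
    mA = np.zeros(n, dtype=bool)
    mB = np.zeros(n, dtype=bool)
    mA[idx_A] = True
    mB[idx_B] = True
    return mA, mB


def _observed_pair_count(net: InteractionNetwork, mA, mB) -> int:
    u, v = net.edges[:, 0], net.edges[:, 1]
    return int(((mA[u] & mB[v]) | (mB[u] & mA[v])).sum())


def cross_edge_count(net: InteractionNetwork, gene: str, opposing_set) -> int:
    """Distinct neighbors of ``gene`` that belong to ``opposing_set``."""
    if gene not in net.node_index:
        raise ValueError(f"gene '{gene}' is not in the network (unscorable)")
    g = net.node_index[gene]
    mask = net.node_mask(opposing_set)
    u, v = net.edges[:, 0], net.edges[:, 1]
    return int(((u == g) & mask[v]).sum() + ((v == g) & mask[u]).sum())


# ----------------------------------------------------------------------
# per-gene enrichment
# ----------------------------------------------------------------------
def empirical_p(observed, null_counts, pseudocount: bool = False):
    """Proportion of null values >= observed (ties in the numerator).

    ``null_counts`` has replicates on axis 0; ``observed`` may be a
    scalar or one value per column. With ``pseudocount`` the
    (r + 1)/(R + 1) variant is returned, which is never exactly zero.
    """
    null = np.asarray(null_counts)
    R = null.shape[0]
    ge = (null >= np.asarray(observed)).sum(axis=0)
    return (ge + 1) / (R + 1) if pseudocount else ge / R


def per_gene_enrichment(
    net: InteractionNetwork,
    ensemble: RandomEnsemble,
    set_A,
    set_B,
    pseudocount: bool = False,
) -> pd.DataFrame:
    """Empirical cross-set enrichment for every scorable gene in A and B.

    For each gene in A the statistic is its edge count into B (and
    symmetrically for B vs A), observed in the real network and in every
    ensemble replicate. The empirical p-value is the proportion of
    replicates with a null count >= the observed count; with
    ``pseudocount`` the (r+1)/(R+1) variant is used instead (never
    exactly zero). ``min_resolvable_p`` (1/R) accompanies every record so
    zero-count p-values can be read as "< 1/R".

    Returns a DataFrame with one row per scorable gene: gene_id, source
    set, degree, observed count, null moments, empirical_p and a
    Benjamini-Hochberg q-value column (emitted for the user; the
    paper-faithful core selection uses raw empirical p).
    """
    idx_A, idx_B, _ = _resolve_sets(net, set_A, set_B)
    n = net.n_nodes
    R = ensemble.R
    label = np.zeros(n, dtype=np.int8)
    label[idx_A] = 1
    label[idx_B] = 2
    order = np.concatenate([idx_A, idx_B])
    col = np.full(n, -1, dtype=np.int64)
    col[order] = np.arange(len(order))

    obs = _kernels.per_gene_null_counts(
        net.edges[:, 0][None, :].astype(np.int32),
        net.edges[:, 1][None, :].astype(np.int32),
        label, col, len(order),
    )[0]
    null = _kernels.per_gene_null_counts(ensemble.U, ensemble.V, label, col, len(order))
    emp_p = empirical_p(obs[None, :], null, pseudocount=pseudocount)
    degrees = net.degrees()[order]
    records = pd.DataFrame(
        {
            "gene_id": [str(net.nodes[i]) for i in order],
            "source_set": [SET_A_LABEL] * len(idx_A) + [SET_B_LABEL] * len(idx_B),
            "degree": degrees,
            "observed_cross": obs,
            "null_mean": null.mean(axis=0),
            "null_sd": null.std(axis=0, ddof=1) if R > 1 else np.zeros(len(order)),
            "empirical_p": emp_p,
            "min_resolvable_p": 1.0 / R,
        }
    )
    records["bh_q"] = (
        multipletests(records["empirical_p"].clip(upper=1.0), method="fdr_bh")[1]
        if len(records) else []
    )
    return records


def select_core_components(records: pd.DataFrame, alpha: float = 0.05):
    """Genes with empirical p < alpha, split by source set (sorted ids)."""
    sig = records[records["empirical_p"] < alpha]
    core_A = sorted(sig.loc[sig["source_set"] == SET_A_LABEL, "gene_id"])
    core_B = sorted(sig.loc[sig["source_set"] == SET_B_LABEL, "gene_id"])
    return core_A, core_B


# ----------------------------------------------------------------------
# global enrichment
# ----------------------------------------------------------------------
def z_score(n_observed: float, mu_null: float, sd_null: float) -> float:
    """Null-normalized enrichment: (observed - null mean) / null SD.

    Returns NaN when the null SD is zero (undefined, flagged upstream).
    """
    return (n_observed - mu_null) / sd_null if sd_null > 0 else float("nan")


def _pair_zscore(net, ensemble, idx_A, idx_B) -> tuple[int, float, float, float]:
    """Observed A-B edge count, null moments and Z for one set pair."""
    mA, mB = _masks(net.n_nodes, idx_A, idx_B)
    n_obs = _observed_pair_count(net, mA, mB)
    null = _kernels.pair_null_counts(
        ensemble.gene_grouped(), idx_A, mB, ensemble.R
    )
    mu = float(null.mean())
    sd = float(null.std(ddof=1)) if ensemble.R > 1 else 0.0
    return n_obs, mu, sd, z_score(n_obs, mu, sd)


def global_enrichment(
    net: InteractionNetwork,
    ensemble: RandomEnsemble,
    set_A,
    set_B,
) -> GlobalEnrichment:
    """Z-score of the total A-B interaction count against the ensemble.

    Each cross edge is counted once, so the count is symmetric in A and
    B. ``sd_null == 0`` yields a flagged result with ``z_score = NaN``.
    """
    idx_A, idx_B, _ = _resolve_sets(net, set_A, set_B)
    n_obs, mu, sd, z = _pair_zscore(net, ensemble, idx_A, idx_B)
    if not np.isfinite(z):
        logger.warning("global_enrichment: null SD is zero; Z-score undefined")
    return GlobalEnrichment(n_observed=n_obs, mu_null=mu, sd_null=sd,
                            z_score=z, R=ensemble.R)


# ----------------------------------------------------------------------
# DEG vs non-DEG Z-score comparison
# ----------------------------------------------------------------------
def compare_zscores(
    net: InteractionNetwork,
    ensemble: RandomEnsemble,
    set_A,
    set_B,
    nondeg_pool,
    n_resamples: int = 100,
    seed: int = 0,
    deg_resample: str = "split",
    n_splits: int = 5,
    subsample_fraction: float = 0.8,
) -> ZscoreComparison:
    """Welch t-test of DEG-pair Z-scores against non-DEG-pair Z-scores.

    The non-DEG side draws ``n_resamples`` size-matched disjoint set
    pairs from ``nondeg_pool`` and computes each pair's cross-interaction
    Z-score. The DEG side needs a distribution from a single observed
    pair; two constructions are provided:

    ``split`` (default)
        Randomly partition A and B into ``n_splits`` disjoint sub-pairs
        and compute one Z-score per sub-pair. Disjoint sub-pairs give
        nearly independent Z-scores, so under the null they are
        exchangeable with non-DEG pairs of the same (sub-pair) sizes and
        the t-test holds its nominal level. Non-DEG pairs are size-matched
        to the sub-pairs.
    ``subsample``
        Z-scores of ``n_resamples`` random subsets at
        ``subsample_fraction`` of each set (non-DEG pairs size-matched to
        the full sets). The subsample Z-scores all inherit the one
        observed pair's deviation, so the t-test treats one draw as many
        and rejects far above nominal level under the null; retained for
        comparison, not recommended for inference.
    """
    if deg_resample not in ("split", "subsample"):
        raise ValueError(f"unknown deg_resample mode '{deg_resample}'")
    idx_A, idx_B, _ = _resolve_sets(net, set_A, set_B)
    pool_idx = np.array(
        sorted(net.node_index[g] for g in set(nondeg_pool) if g in net.node_index),
        dtype=np.int64,
    )
    forbidden = set(idx_A.tolist()) | set(idx_B.tolist())
    bad = [i for i in pool_idx if i in forbidden]
    if bad:
        raise ValueError("nondeg_pool must be disjoint from A and B")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    if deg_resample == "split":
        n_splits = max(1, int(n_splits))
        a_sz, b_sz = len(idx_A) // n_splits, len(idx_B) // n_splits
        if a_sz < 1 or b_sz < 1:
            raise ValueError(
                f"cannot split sets of sizes {len(idx_A)}, {len(idx_B)} into "
                f"{n_splits} non-empty sub-pairs"
            )
        permA = rng.permutation(idx_A)
        permB = rng.permutation(idx_B)
        z_deg = []
        for k in range(n_splits):
            sub_A = np.sort(permA[k * a_sz:(k + 1) * a_sz])
            sub_B = np.sort(permB[k * b_sz:(k + 1) * b_sz])
            z_deg.append(_pair_zscore(net, ensemble, sub_A, sub_B)[3])
        match_a, match_b = a_sz, b_sz
    else:
        if not 0 < subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        a_sz = max(1, int(round(subsample_fraction * len(idx_A))))
        b_sz = max(1, int(round(subsample_fraction * len(idx_B))))
        z_deg = []
        for _ in range(n_resamples):
            sub_A = np.sort(rng.choice(idx_A, size=a_sz, replace=False))
            sub_B = np.sort(rng.choice(idx_B, size=b_sz, replace=False))
            z_deg.append(_pair_zscore(net, ensemble, sub_A, sub_B)[3])
        match_a, match_b = len(idx_A), len(idx_B)

    need = match_a + match_b
    if len(pool_idx) < need:
        raise ValueError(
            f"non-DEG pool too small: need {need} genes per resample, "
            f"have {len(pool_idx)}"
        )
    z_nondeg = []
    for _ in range(n_resamples):
        pick = rng.choice(pool_idx, size=need, replace=False)
        sub_A = np.sort(pick[:match_a])
        sub_B = np.sort(pick[match_a:])
        z_nondeg.append(_pair_zscore(net, ensemble, sub_A, sub_B)[3])

    z_deg = np.asarray(z_deg, dtype=float)
    z_nondeg = np.asarray(z_nondeg, dtype=float)
    if len(z_deg) > 1 and len(z_nondeg) > 1:
        t, p = sps.ttest_ind(z_deg, z_nondeg, equal_var=False)
    else:
        t, p = float("nan"), float("nan")
    return ZscoreComparison(
        z_deg=z_deg, z_nondeg=z_nondeg,
        t_statistic=float(t), p_value=float(p),
        n_resamples=int(n_resamples),
    )


# ----------------------------------------------------------------------
# co-expression link enrichment
# ----------------------------------------------------------------------
def coexpression_enrichment(
    expr: pd.DataFrame,
    set_A,
    set_B,
    nondeg_pool,
    top_fraction: float = 0.01,
    n_resamples: int = 100,
    seed: int = 0,
) -> CoexpressionEnrichment:
    """Enrichment of top-correlated gene pairs between sets A and B.

    Pearson correlations are computed on log-transformed abundances over
    all unordered pairs among A, B and the sampled non-DEG sets; the link
    threshold is the ``1 - top_fraction`` quantile of that pooled
    pair-correlation distribution (population-level, not per gene). The
    fold enrichment is the observed number of A-B links divided by the
    mean link count among ``n_resamples`` size-matched non-DEG set pairs.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    set_A, set_B = sorted(set(set_A)), sorted(set(set_B))
    pool = sorted(set(nondeg_pool) - set(set_A) - set(set_B))
    have = set(expr.index)
    for name, genes in (("A", set_A), ("B", set_B), ("pool", pool)):
        missing = [g for g in genes if g not in have]
        if missing:
            raise ValueError(f"genes of set {name} absent from expression matrix: {missing[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    if len(pool) < len(set_A) + len(set_B):
        raise ValueError(
            f"non-DEG pool too small: need {len(set_A) + len(set_B)} genes, "
            f"have {len(pool)}"
        )
    resamples = []
    for _ in range(n_resamples):
        pick = rng.choice(len(pool), size=len(set_A) + len(set_B), replace=False)
        resamples.append((
            [pool[i] for i in pick[: len(set_A)]],
            [pool[i] for i in pick[len(set_A):]],
        ))

    genes = sorted(set(set_A) | set(set_B) | {g for a, b in resamples for g in a + b})
    mat = np.log2(expr.loc[genes].to_numpy(dtype=float) + 1.0)
    sd = mat.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "coexpression_enrichment: dropping %d zero-variance gene(s)",
            int((~keep).sum()),
        )
        genes = [g for g, k in zip(genes, keep) if k]
        mat = mat[keep]
    pos = {g: i for i, g in enumerate(genes)}
    corr = np.corrcoef(mat)
    iu = np.triu_indices(len(genes), k=1)
    pooled = corr[iu]
    threshold = float(np.quantile(pooled, 1.0 - top_fraction))

    def links(ga, gb) -> int:
        ia = [pos[g] for g in ga if g in pos]
        ib = [pos[g] for g in gb if g in pos]
        sub = corr[np.ix_(ia, ib)]
        return int((sub >= threshold).sum())

    n_obs = links(set_A, set_B)
    null_counts = np.array([links(a, b) for a, b in resamples], dtype=float)
    mean_null = float(null_counts.mean())
    fold = n_obs / mean_null if mean_null > 0 else float("inf")
    return CoexpressionEnrichment(
        correlation_threshold=threshold,
        top_fraction=float(top_fraction),
        n_links_observed=n_obs,
        mean_links_null=mean_null,
        fold_enrichment=float(fold),
        n_nondeg_resamples=int(n_resamples),
    )


# ----------------------------------------------------------------------
# core subnetwork
# ----------------------------------------------------------------------
def extract_core_subnetwork(
    net: InteractionNetwork,
    core_A,
    core_B,
    records: pd.DataFrame,
) -> CoreSubnetwork:
    """Induced subgraph on the core genes, annotated for export.

    Keeps every edge among core genes (cross-set and within-core). Nodes
    carry their source set and empirical p; edges carry confidence weight
    and the experimental-verification flag when present in the input.
    """
    core_A, core_B = sorted(set(core_A)), sorted(set(core_B))
    pmap = dict(zip(records["gene_id"], records["empirical_p"]))
    g = nx.Graph()
    for gene in core_A:
        g.add_node(gene, source_set=SET_A_LABEL, empirical_p=float(pmap.get(gene, float("nan"))))
    for gene in core_B:
        g.add_node(gene, source_set=SET_B_LABEL, empirical_p=float(pmap.get(gene, float("nan"))))
    core = set(core_A) | set(core_B)
    inA = set(core_A)
    n_cross = n_total = 0
    for k, (u, v) in enumerate(net.edges):
        ga, gb = str(net.nodes[u]), str(net.nodes[v])
        if ga in core and gb in core:
            attrs = {}
            if net.weights is not None:
                attrs["weight"] = float(net.weights[k])
            if net.verified is not None:
                attrs["verified"] = bool(net.verified[k])
            g.add_edge(ga, gb, **attrs)
            n_total += 1
            if (ga in inA) != (gb in inA):
                n_cross += 1
    return CoreSubnetwork(
        graph=g, core_A=core_A, core_B=core_B,
        n_cross_edges=n_cross, n_total_edges=n_total,
    )
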