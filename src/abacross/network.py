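"""Undirected simple interaction network over gene identifiers.

The container is deliberately array-based: enrichment statistics and the
degree-preserving shuffle operate on integer edge arrays, while conversion
to :class:`networkx.Graph` is provided for export and subgraph extraction.
Edges are stored canonically with ``u < v`` (integer node indices), so an
edge set has a unique representation and byte-identical serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = ["InteractionNetwork"]


@dataclass
class InteractionNetwork:
    """Simple undirected graph with optional edge confidence weights.

    Parameters
    ----------
    nodes
        Array of gene identifiers (opaque strings; AGI locus codes pass
        through unmodified).
    edges
        ``(E, 2)`` integer array of node indices, canonicalized so that
        ``edges[:, 0] < edges[:, 1]`` and rows are unique.
    weights
        Optional ``(E,)`` float array of interaction confidences in (0, 1].
    verified
        Optional ``(E,)`` boolean array flagging experimentally verified
        interactions.
    """

    nodes: np.ndarray
    edges: np.ndarray
    weights: np.ndarray | None = None
    verified: np.ndarray | None = None
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=object)
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            lo = np.minimum(edges[:, 0], edges[:, 1])
            hi = np.maximum(edges[:, 0], edges[:, 1])
            if np.any(lo == hi):
                raise ValueError("self-loops are not allowed")
            order = np.lexsort((hi, lo))
            edges = np.column_stack([lo, hi])[order]
            if self.weights is not None:
                self.weights = np.asarray(self.weights, dtype=float)[order]
            if self.verified is not None:
                self.verified = np.asarray(self.verified, dtype=bool)[order]
            keys = edges[:, 0] * len(self.nodes) + edges[:, 1]
            if len(np.unique(keys)) != len(keys):
                raise ValueError("duplicate edges are not allowed")
        self.edges = edges
        self._index = None

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def node_index(self) -> dict:
        """Mapping gene_id -> integer node index (built lazily)."""
        if self._index is None:
            self._index = {g: i for i, g in enumerate(self.nodes)}
        return self._index

    def degrees(self) -> np.ndarray:
        """Degree of every node, aligned with ``self.nodes``."""
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes if self.n_nodes else 0.0

    def density(self) -> float:
        """Edge probability of the background: 2E / (n (n-1))."""
        n = self.n_nodes
        return 2.0 * self.n_edges / (n * (n - 1)) if n > 1 else 0.0

    def node_mask(self, genes: Iterable[str]) -> np.ndarray:
        """Boolean mask over node indices for a collection of gene ids.

        Unknown gene ids are silently ignored; callers that must report
        them use :meth:`missing_genes`.
        """
        mask = np.zeros(self.n_nodes, dtype=bool)
        idx = self.node_index
        for g in genes:
            i = idx.get(g)
            if i is not None:
                mask[i] = True
        return mask

    def missing_genes(self, genes: Iterable[str]) -> list[str]:
        idx = self.node_index
        return [g for g in genes if g not in idx]

    def edge_key_set(self) -> set:
        n = self.n_nodes
        return set((self.edges[:, 0] * n + self.edges[:, 1]).tolist())

    def has_edge(self, gene_a: str, gene_b: str) -> bool:
        ia, ib = self.node_index[gene_a], self.node_index[gene_b]
        lo, hi = (ia, ib) if ia < ib else (ib, ia)
        return (lo * self.n_nodes + hi) in self.edge_key_set()

    # ------------------------------------------------------------------
    # construction / conversion
    # ------------------------------------------------------------------
    @classmethod
    def from_gene_pairs(
        cls,
        pairs: Sequence[tuple[str, str]],
        weights: Sequence[float] | None = None,
        verified: Sequence[bool] | None = None,
        nodes: Sequence[str] | None = None,
    ) -> "InteractionNetwork":
        """Build a network from (gene_a, gene_b) pairs.

        The node universe is the union of endpoint ids unless ``nodes``
        is given explicitly (sorted for determinism in the former case).
        """
        if nodes is None:
            nodes = sorted({g for p in pairs for g in p})
        nodes = np.asarray(list(nodes), dtype=object)
        index = {g: i for i, g in enumerate(nodes)}
        edges = np.array(
            [[index[a], index[b]] for a, b in pairs], dtype=np.int64
        ).reshape(-1, 2)
        w = None if weights is None else np.asarray(weights, dtype=float)
        v = None if verified is None else np.asarray(verified, dtype=bool)
        return cls(nodes=nodes, edges=edges, weights=w, verified=v)

    def edge_gene_pairs(self) -> list[tuple[str, str]]:
        return [
            (self.nodes[u], self.nodes[v]) for u, v in self.edges
        ]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes.tolist())
        for k, (u, v) in enumerate(self.edges):
            attrs = {}
            if self.weights is not None:
                attrs["weight"] = float(self.weights[k])
            if self.verified is not None:
                attrs["verified"] = bool(self.verified[k])
            g.add_edge(self.nodes[u], self.nodes[v], **attrs)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "InteractionNetwork":
        nodes = sorted(g.nodes())
        index = {n: i for i, n in enumerate(nodes)}
        pairs, weights, verified = [], [], []
        has_w = has_v = False
        for a, b, data in g.edges(data=True):
            pairs.append([index[a], index[b]])
            weights.append(float(data.get("weight", 1.0)))
            verified.append(bool(data.get("verified", False)))
            has_w = has_w or "weight" in data
            has_v = has_v or "verified" in data
        return cls(
            nodes=np.asarray(nodes, dtype=object),
            edges=np.asarray(pairs, dtype=np.int64).reshape(-1, 2),
            weights=np.asarray(weights) if has_w else None,
            verified=np.asarray(verified) if has_v else None,
        )

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(
            nodes=self.nodes.copy(),
            edges=self.edges.copy(),
            weights=None if self.weights is None else self.weights.copy(),
            verified=None if self.verified is None else self.verified.copy(),
        )
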