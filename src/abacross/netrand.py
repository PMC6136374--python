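"""Degree-preserving network randomization (double-edge swap null model).

The null model for every enrichment statistic in this package: an ensemble
of R networks, each obtained from the observed network by repeated
double-edge swaps. A swap picks two edges ``(a,b)`` and ``(c,d)`` uniformly
at random and rewires them to ``(a,d), (c,b)`` (the alternate pairing is
selected with probability 1/2), rejecting any proposal that would create a
self-loop or duplicate edge. The swap chain is symmetric, so its stationary
distribution is uniform over all simple graphs realizing the observed
degree sequence; every node keeps its exact degree in every replicate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .network import InteractionNetwork

__all__ = ["RandomEnsemble", "degree_preserving_shuffle", "build_ensemble"]

logger = logging.getLogger(__name__)

DEFAULT_SWAP_MULTIPLIER = 10  # attempted swaps per edge, common practice


def _replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds derived from the master seed.

    Each replicate is replayable in isolation: seed i depends only on
    (master_seed, i).
    """
    ss = np.random.SeedSequence(master_seed)
    return np.array(
        [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)],
        dtype=np.int64,
    )


def degree_preserving_shuffle(
    net: InteractionNetwork,
    swap_multiplier: int = DEFAULT_SWAP_MULTIPLIER,
    seed: int = 0,
) -> InteractionNetwork:
    """Randomize a network by double-edge swaps, preserving every degree.

    Performs ``swap_multiplier * n_edges`` swap attempts. Edge weights
    travel with the first parent edge of each swap (the rewired edge
    keeps the array slot, hence the weight, of the edge contributing its
    first endpoint); weights never enter downstream counting statistics.

    Returns a new network; the input is untouched. A network with fewer
    than two edges cannot be rewired and is returned as an identical copy
    with a warning.
    """
    if net.n_edges < 2:
        warnings.warn(
            "network has fewer than 2 edges; no degree-preserving swap is "
            "possible, returning an identical copy",
            stacklevel=2,
        )
        return net.copy()
    u = net.edges[:, 0].astype(np.int64).copy()
    v = net.edges[:, 1].astype(np.int64).copy()
    attempts = int(swap_multiplier) * net.n_edges
    accepted = _kernels.swap_edges(u, v, net.n_nodes, attempts, int(seed))
    logger.debug(
        "degree_preserving_shuffle: %d/%d swap attempts accepted (%.1f%%)",
        accepted, attempts, 100.0 * accepted / attempts,
    )
    return InteractionNetwork(
        nodes=net.nodes.copy(),
        edges=np.column_stack([u, v]),
        weights=None if net.weights is None else net.weights.copy(),
        verified=None if net.verified is None else net.verified.copy(),
    )


@dataclass
class RandomEnsemble:
    """R degree-preserving randomizations of a source network.

    Replicate edge sets are stored as ``(R, E)`` node-index arrays; every
    replicate has the same node set, edge count, and per-node degree as
    the source.
    """

    source: InteractionNetwork
    U: np.ndarray  # (R, E) first endpoints
    V: np.ndarray  # (R, E) second endpoints
    swap_multiplier: int
    master_seed: int
    replicate_seeds: np.ndarray
    _grouped: tuple = field(default=None, repr=False, compare=False)

    @property
    def R(self) -> int:
        return self.U.shape[0]

    def replicate(self, i: int) -> InteractionNetwork:
        """Materialize replicate ``i`` as a network (weights per slot)."""
        return InteractionNetwork(
            nodes=self.source.nodes.copy(),
            edges=np.column_stack([self.U[i], self.V[i]]).astype(np.int64),
            weights=None if self.source.weights is None else self.source.weights.copy(),
        )

    def gene_grouped(self):
        """Ensemble adjacency grouped by gene (cached; see _kernels)."""
        if self._grouped is None:
            self._grouped = _kernels.build_gene_grouped(
                self.U, self.V, self.source.n_nodes
            )
        return self._grouped


def build_ensemble(
    net: InteractionNetwork,
    R: int = 1000,
    swap_multiplier: int = DEFAULT_SWAP_MULTIPLIER,
    master_seed: int = 0,
) -> RandomEnsemble:
    """Build an R-replicate degree-preserving randomized ensemble.

    Per-replicate seeds are derived deterministically from
    ``master_seed``, so the ensemble is reproducible as a whole and any
    single replicate is reproducible in isolation.
    """
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    seeds = _replicate_seeds(master_seed, R)
    E = net.n_edges
    U = np.empty((R, E), dtype=np.int32)
    V = np.empty((R, E), dtype=np.int32)
    small = E < 2
    if small:
        warnings.warn(
            "network has fewer than 2 edges; ensemble replicates are "
            "identical copies of the source",
            stacklevel=2,
        )
    attempts = int(swap_multiplier) * E
    total_accepted = 0
    for i in range(R):
        u = net.edges[:, 0].astype(np.int64).copy()
        v = net.edges[:, 1].astype(np.int64).copy()
        if not small:
            total_accepted += _kernels.swap_edges(
                u, v, net.n_nodes, attempts, int(seeds[i])
            )
        U[i] = u
        V[i] = v
    if not small and R * attempts:
        logger.info(
            "build_ensemble: R=%d, %d attempts/replicate, mean acceptance %.1f%%",
            R, attempts, 100.0 * total_accepted / (R * attempts),
        )
    return RandomEnsemble(
        source=net,
        U=U,
        V=V,
        swap_multiplier=int(swap_multiplier),
        master_seed=int(master_seed),
        replicate_seeds=seeds,
    )
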