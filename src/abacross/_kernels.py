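"""Numba kernels for edge shuffling and ensemble cross-edge counting.

These inner loops dominate the cost of building 1000-replicate null
ensembles on graphs with tens of thousands of edges, so they are compiled.
Edge presence is tracked with a hashed key ``u * n + v`` (``u < v``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "swap_edges",
    "per_gene_null_counts",
    "pair_null_counts",
    "build_gene_grouped",
]

# open-addressing hash set over int64 edge keys: EMPTY/TOMB are sentinels
# (edge keys u*n+v are always >= 0), _HASH_MULT is the Fibonacci multiplier
_EMPTY = np.int64(-1)
_TOMB = np.int64(-2)
_HASH_MULT = np.int64(np.uint64(0x9E3779B97F4A7C15))  # two's complement


@njit(cache=False)
def _swap_kernel(u, v, n, n_attempts, seed):
    """Attempt ``n_attempts`` double-edge swaps in place.

    ``u[i] < v[i]`` on entry and on exit. Returns the number of accepted
    swaps. A proposed swap is rejected when it would create a self-loop
    or a duplicate edge; rejected attempts are not retried.

    Edge presence is tracked in a linear-probing hash set; tombstones
    left by deletions trigger a periodic rebuild.
    """
    np.random.seed(seed)
    m = len(u)
    cap = 8
    while cap < 4 * m:
        cap <<= 1
    mask = np.int64(cap - 1)
    keys = np.full(cap, _EMPTY, dtype=np.int64)

    def _slot(k):
        return (k * _HASH_MULT) & mask

    def _contains(k):
        i = _slot(k)
        while True:
            s = keys[i]
            if s == k:
                return True
            if s == _EMPTY:
                return False
            i = (i + 1) & mask

    def _insert(k):
        i = _slot(k)
        free = np.int64(-1)
        while True:
            s = keys[i]
            if s == _EMPTY:
                if free < 0:
                    free = i
                break
            if s == _TOMB and free < 0:
                free = i
            i = (i + 1) & mask
        keys[free] = k

    def _remove(k):
        i = _slot(k)
        while keys[i] != k:
            i = (i + 1) & mask
        keys[i] = _TOMB

    for i in range(m):
        _insert(u[i] * n + v[i])

    accepted = 0
    tombs = 0
    rebuild_at = cap // 4
    for _ in range(n_attempts):
        i = np.random.randint(0, m)
        j = np.random.randint(0, m)
        if i == j:
            continue
        a, b = u[i], v[i]
        c, d = u[j], v[j]
        # random orientation of the second edge selects which of the two
        # possible endpoint pairings is proposed
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        # proposal: (a, b), (c, d) -> (a, d), (c, b)
        if a == d or c == b:
            continue
        p, q = (a, d) if a < d else (d, a)
        r, s = (c, b) if c < b else (b, c)
        k1 = p * n + q
        k2 = r * n + s
        if k1 == k2 or _contains(k1) or _contains(k2):
            continue
        _remove(u[i] * n + v[i])
        _remove(u[j] * n + v[j])
        _insert(k1)
        _insert(k2)
        u[i], v[i] = p, q
        u[j], v[j] = r, s
        accepted += 1
        tombs += 2
        if tombs >= rebuild_at:
            keys[:] = _EMPTY
            for e in range(m):
                _insert(u[e] * n + v[e])
            tombs = 0
    return accepted


def swap_edges(u: np.ndarray, v: np.ndarray, n_nodes: int, n_attempts: int, seed: int) -> int:
    """Python entry point for the swap kernel (arrays modified in place)."""
    return _swap_kernel(u, v, np.int64(n_nodes), np.int64(n_attempts), np.int64(seed))


@njit(cache=False)
def _pergene_counts_kernel(U, V, label, col, out):
    """Per-replicate cross-edge counts for every labelled gene.

    ``label[g]`` is 1 for set A, 2 for set B, 0 otherwise; ``col[g]`` is
    the output column of gene ``g`` (or -1). An A-B edge increments both
    endpoints' counts (each gene is scored against the opposing set).
    """
    R, E = U.shape
    for r in range(R):
        for e in range(E):
            x = U[r, e]
            y = V[r, e]
            lx = label[x]
            ly = label[y]
            if lx == 1 and ly == 2:
                out[r, col[x]] += 1
                out[r, col[y]] += 1
            elif lx == 2 and ly == 1:
                out[r, col[x]] += 1
                out[r, col[y]] += 1


def per_gene_null_counts(U: np.ndarray, V: np.ndarray, label: np.ndarray,
                         col: np.ndarray, n_cols: int) -> np.ndarray:
    """Cross-edge count of every labelled gene in every replicate.

    ``U``/``V`` are ``(R, E)`` node-index arrays (one row per replicate; a
    single real network is passed as ``(1, E)``).
    """
    R = U.shape[0]
    out = np.zeros((R, n_cols), dtype=np.int64)
    _pergene_counts_kernel(U, V, label.astype(np.int8), col.astype(np.int64), out)
    return out


@njit(cache=False)
def _group_fill_kernel(U, V, ptr, nbr, rep, cursor):
    R, E = U.shape
    for r in range(R):
        for e in range(E):
            x = U[r, e]
            y = V[r, e]
            k = cursor[x]
            nbr[k] = y
            rep[k] = r
            cursor[x] = k + 1
            k = cursor[y]
            nbr[k] = x
            rep[k] = r
            cursor[y] = k + 1


def build_gene_grouped(U: np.ndarray, V: np.ndarray, n_nodes: int):
    """Group the ensemble adjacency by gene.

    Returns ``(ptr, nbr, rep)`` where the entries for gene ``g`` are
    ``nbr[ptr[g]:ptr[g+1]]`` (neighbor index) and the matching replicate
    ids ``rep[ptr[g]:ptr[g+1]]``. Used to score many gene-set pairs
    against one ensemble while touching only incident edges.
    """
    deg = np.zeros(n_nodes, dtype=np.int64)
    np.add.at(deg, U.ravel(), 1)
    np.add.at(deg, V.ravel(), 1)
    ptr = np.zeros(n_nodes + 1, dtype=np.int64)
    np.cumsum(deg, out=ptr[1:])
    total = int(ptr[-1])
    nbr = np.empty(total, dtype=np.int32)
    rep = np.empty(total, dtype=np.int32)
    cursor = ptr[:-1].copy()
    _group_fill_kernel(U, V, ptr, nbr, rep, cursor)
    return ptr, nbr, rep


@njit(cache=False)
def _pair_counts_kernel(ptr, nbr, rep, genes, opp_mask, out):
    for gi in range(len(genes)):
        g = genes[gi]
        for k in range(ptr[g], ptr[g + 1]):
            if opp_mask[nbr[k]]:
                out[rep[k]] += 1


def pair_null_counts(grouped, genes: np.ndarray, opp_mask: np.ndarray,
                     n_replicates: int) -> np.ndarray:
    """Total cross edges between ``genes`` and ``opp_mask`` per replicate.

    ``genes`` and the opposing set must be disjoint so that each cross
    edge is counted exactly once (from its ``genes``-side endpoint).
    """
    ptr, nbr, rep = grouped
    out = np.zeros(n_replicates, dtype=np.int64)
    _pair_counts_kernel(ptr, nbr, rep, genes.astype(np.int64),
                        opp_mask.astype(np.bool_), out)
    return out
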