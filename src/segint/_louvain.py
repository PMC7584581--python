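"""Numba kernels for Louvain maximization of signed modularity.

The optimization works on a dense symmetric "gain" matrix ``B`` whose
block sums equal the quality function, so the same kernel serves both the
positive-only structural case and the signed functional-connectivity case.
Restart randomization is the node visiting order; ties break toward the
first encountered best community.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def _local_move_phase(B, labels, order):
    """One-level local moving; returns True if any node moved."""
    n = B.shape[0]
    improved = False
    moved = True
    while moved:
        moved = False
        for oi in range(n):
            i = order[oi]
            ci = labels[i]
            # accumulate row sums into each community
            gains = np.zeros(n)
            for j in range(n):
                if j != i:
                    gains[labels[j]] += B[i, j]
            best_c = ci
            best_gain = gains[ci]
            for c in range(n):
                if gains[c] > best_gain + 1e-14:
                    best_gain = gains[c]
                    best_c = c
            if best_c != ci:
                labels[i] = best_c
                moved = True
                improved = True
    return improved


@numba.njit(cache=True)
def _aggregate(B, labels):
    """Collapse B into community-level blocks; relabel 0..k-1."""
    n = B.shape[0]
    remap = -np.ones(n, dtype=np.int64)
    k = 0
    for i in range(n):
        if remap[labels[i]] < 0:
            remap[labels[i]] = k
            k += 1
    new_labels = np.empty(n, dtype=np.int64)
    for i in range(n):
        new_labels[i] = remap[labels[i]]
    B2 = np.zeros((k, k))
    for i in range(n):
        for j in range(n):
            B2[new_labels[i], new_labels[j]] += B[i, j]
    return B2, new_labels, k


@numba.njit(cache=True)
def louvain_dense(B, init_order):
    """Full hierarchical Louvain on a dense gain matrix.

    Returns node labels (0..k-1, consecutive) maximizing sum of
    within-community B entries, found greedily.
    """
    n = B.shape[0]
    node_labels = np.arange(n)
    cur_B = B.copy()
    cur_order = init_order.copy()
    while True:
        labels = np.arange(cur_B.shape[0])
        improved = _local_move_phase(cur_B, labels, cur_order)
        if not improved:
            break
        cur_B, new_labels, k = _aggregate(cur_B, labels)
        for i in range(n):
            node_labels[i] = new_labels[node_labels[i]]
        cur_order = np.arange(k)
    # make labels consecutive in order of first appearance
    remap = -np.ones(n, dtype=np.int64)
    k = 0
    for i in range(n):
        if remap[node_labels[i]] < 0:
            remap[node_labels[i]] = k
            k += 1
        node_labels[i] = remap[node_labels[i]]
    return node_labels


@numba.njit(cache=True)
def partition_quality(B, labels):
    """Sum of B over within-community ordered pairs."""
    n = B.shape[0]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += B[i, j]
    return q
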