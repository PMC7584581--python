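"""Shared fixtures: small synthetic connectomes and toy networks."""

from __future__ import annotations

import numpy as np
import pytest

from segint.connectome import Connectome, make_node_table
from segint.synthetic import make_default_connectome


@pytest.fixture(scope="session")
def desk_connectome() -> Connectome:
    """Reduced-size profile used throughout the fast tests."""
    return make_default_connectome(57, seed=1)


@pytest.fixture(scope="session")
def default_connectome() -> Connectome:
    """Full-size default profile (114 nodes, density 0.19)."""
    return make_default_connectome(114, seed=0)


def toy_connectome(W: np.ndarray, lengths: np.ndarray | None = None
                   ) -> Connectome:
    """Wrap an explicit weight matrix as a Connectome (unit lengths)."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if lengths is None:
        L = np.where(W > 0, 1.0, 0.0)
    else:
        L = np.asarray(lengths, dtype=float)
    coords = np.column_stack([np.arange(n), np.zeros(n), np.zeros(n)])
    return Connectome(W=W, L=L, nodes=make_node_table(coords))


def two_cliques(weak: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Two 4-cliques joined by one weak edge; returns (W, planted labels)."""
    W = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i < j:
                    W[i, j] = W[j, i] = 1.0
    W[3, 4] = W[4, 3] = weak
    labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    return W, labels


def set_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    def rec(prefix, k):
        i = len(prefix)
        if i == n:
            yield np.array(prefix)
            return
        for c in range(k + 1):
            yield from rec(prefix + [c], max(k, c + 1))
    yield from rec([], 0)


def qstar_reference(w: np.ndarray, labels: np.ndarray,
                    gamma: float = 1.0) -> float:
    """Independent direct-summation evaluation of the signed quality function."""
    n = w.shape[0]
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    sp = wp.sum(axis=1)
    sn = wn.sum(axis=1)
    vp, vn = sp.sum(), sn.sum()
    pos = neg = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                pos += wp[i, j] - gamma * sp[i] * sp[j] / vp
                if vn > 0:
                    neg += wn[i, j] - gamma * sn[i] * sn[j] / vn
    q = pos / vp
    if vn > 0:
        q -= neg / (vp + vn)
    return q
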