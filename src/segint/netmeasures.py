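"""Signed network measures of segregation and integration.

For a signed functional-connectivity matrix ``w`` (Fisher-z correlations)
the quality function is the signed modularity

    Q* = (1/v+) sum_ij (w+_ij - e+_ij) d(ci, cj)
       - (1/(v+ + v-)) sum_ij (w-_ij - e-_ij) d(ci, cj)

with e±_ij = s±_i s±_j / v± the strength-preserving null term, sums over
ordered node pairs. High Q* marks segregated connectivity patterns. The
participation coefficient PC_i = 1 - sum_c (kappa+_ic / kappa+_i)^2 uses
positive strengths only; its node average rises with integration. The
temporal participation coefficient averages the same sum over every
window's community partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._louvain import louvain_dense, partition_quality


def split_signs(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a signed matrix into non-negative positive/negative parts."""
    w = np.asarray(w, dtype=float)
    return np.where(w > 0, w, 0.0), np.where(w < 0, -w, 0.0)


def _gain_matrix(w: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """Dense matrix B whose within-community sum equals Q*."""
    wp, wn = split_signs(w)
    sp, sn = wp.sum(axis=1), wn.sum(axis=1)
    vp, vn = sp.sum(), sn.sum()
    if vp <= 0:
        raise ValueError("network has no positive weights; Q* undefined")
    B = (wp - gamma * np.outer(sp, sp) / vp) / vp
    if vn > 0:
        B = B - (wn - gamma * np.outer(sn, sn) / vn) / (vp + vn)
    return B


def qstar(w: np.ndarray, partition: np.ndarray, gamma: float = 1.0) -> float:
    """Signed modularity of a given partition.

    The negative-weight term is dropped when the matrix holds no negative
    weights. Sums run over ordered pairs including the diagonal null terms,
    so the single-community partition scores exactly zero.
    """
    partition = np.asarray(partition)
    w = np.asarray(w, dtype=float)
    if len(partition) != w.shape[0]:
        raise ValueError("partition length does not match matrix size")
    B = _gain_matrix(w, gamma)
    same = partition[:, None] == partition[None, :]
    return float(B[same].sum())


def louvain_qstar(w: np.ndarray, gamma: float = 1.0, n_restarts: int = 100,
                  seed: int = 0) -> tuple[np.ndarray, float]:
    """Maximize Q* by Louvain with randomized restarts.

    Each restart randomizes the node visiting order; the best partition
    over all restarts is returned together with its Q*.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    B = _gain_matrix(w, gamma)
    rng = np.random.default_rng(seed)
    best_q = -np.inf
    best_labels = np.arange(n)
    for _ in range(n_restarts):
        order = rng.permutation(n)
        labels = louvain_dense(B, order)
        q = partition_quality(B, labels)
        if q > best_q + 1e-15:
            best_q = q
            best_labels = labels
    return best_labels, float(best_q)


def participation(w: np.ndarray, partition: np.ndarray
                  ) -> tuple[np.ndarray, float]:
    """Per-node participation coefficient over positive weights, and its mean.

    Nodes with zero positive strength are assigned PC = 0 with a warning.
    """
    wp, _ = split_signs(w)
    partition = np.asarray(partition)
    comms = np.unique(partition)
    onehot = (partition[:, None] == comms[None, :]).astype(float)
    kappa_c = wp @ onehot                  # (n, n_comm) within-community strengths
    kappa = kappa_c.sum(axis=1)
    pc = np.zeros(len(partition))
    ok = kappa > 0
    if not np.all(ok):
        warnings.warn(f"{np.count_nonzero(~ok)} node(s) with zero positive "
                      "strength; PC set to 0", RuntimeWarning, stacklevel=2)
    pc[ok] = 1.0 - ((kappa_c[ok] / kappa[ok, None]) ** 2).sum(axis=1)
    return pc, float(pc.mean())


def temporal_participation(matrices: list[np.ndarray],
                           partitions: list[np.ndarray]
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Temporal participation coefficient across all windows' partitions.

    For window t and node i, the concentration sum of Eq.-(2) form is
    evaluated under every window's partition u and averaged over u, using
    window t's positive weights throughout. Returns the (T, n) TPC array
    and the length-T node-mean series.
    """
    T = len(matrices)
    if T != len(partitions):
        raise ValueError("need one partition per window")
    onehots = []
    for part in partitions:
        part = np.asarray(part)
        comms = np.unique(part)
        onehots.append((part[:, None] == comms[None, :]).astype(float))
    n = matrices[0].shape[0]
    tpc = np.zeros((T, n))
    for t in range(T):
        wp, _ = split_signs(matrices[t])
        kappa = wp.sum(axis=1)
        ok = kappa > 0
        if not np.all(ok):
            warnings.warn(f"window {t}: node(s) with zero positive strength; "
                          "TPC set to 0", RuntimeWarning, stacklevel=2)
        herf = np.zeros(n)
        for onehot in onehots:
            kappa_c = wp @ onehot
            herf[ok] += ((kappa_c[ok] / kappa[ok, None]) ** 2).sum(axis=1)
        tpc[t, ok] = 1.0 - herf[ok] / T
    return tpc, tpc.mean(axis=1)


@dataclass
class MeasureSeries:
    """Per-window global measures of a time-resolved FC series."""
    mean_pc: np.ndarray
    mean_tpc: np.ndarray
    qstar: np.ndarray
    partitions: list[np.ndarray]

    def __len__(self) -> int:
        return len(self.mean_pc)


@dataclass
class FluctuationMagnitude:
    """Across-window sample SDs: the magnitude of dynamic fluctuations."""
    sd_mean_pc: float
    sd_mean_tpc: float
    sd_qstar: float


def measure_series(matrices: list[np.ndarray], seed: int = 0,
                   gamma: float = 1.0, n_restarts: int = 100) -> MeasureSeries:
    """Track segregation-integration dynamics across FC windows.

    Per window: Louvain-maximized Q* and the mean PC under that window's
    partition; afterwards the mean TPC series over all windows' partitions.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 windows")
    rng = np.random.default_rng(seed)
    partitions, qs, pcs = [], [], []
    for w in matrices:
        labels, q = louvain_qstar(w, gamma=gamma, n_restarts=n_restarts,
                                  seed=int(rng.integers(2 ** 31)))
        partitions.append(labels)
        qs.append(q)
        pcs.append(participation(w, labels)[1])
    _, mean_tpc = temporal_participation(matrices, partitions)
    return MeasureSeries(mean_pc=np.array(pcs), mean_tpc=mean_tpc,
                         qstar=np.array(qs), partitions=partitions)


def fluctuation_magnitude(series: MeasureSeries) -> FluctuationMagnitude:
    """Sample SD across windows of each global measure."""
    if len(series) < 2:
        raise ValueError("need at least 2 windows")
    return FluctuationMagnitude(
        sd_mean_pc=float(np.std(series.mean_pc, ddof=1)),
        sd_mean_tpc=float(np.std(series.mean_tpc, ddof=1)),
        sd_qstar=float(np.std(series.qstar, ddof=1)),
    )
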