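"""Constrained weight-permutation surrogate connectomes.

Surrogates are built by permuting the non-zero structural weights of a
parent connectome on its fixed binary support. Constraints define disjoint
cells of edges within which permutation is allowed:

* ``R``  — no constraint: one cell holding every edge;
* ``G``  — geometry: equal-width streamline-length bins;
* ``T``  — topology: community blocks (within each structural community,
  or the single between-communities block) intersected with rich-club
  degree categories (edges joining a node of degree d to a node of
  degree >= d fall in category d = min of the endpoint degrees);
* ``GT`` — all three constraint families intersected.

RSN main/control pairs further restrict ``GT`` cells to edges incident
(main) or non-incident (control) to an RSN, with the control's permutable
edge count randomly downselected to match the main's.

After permutation, weights are iteratively adjusted to restore the
parent's strength sequence (a converged diagonal rescaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectome import Connectome
from .netmeasures import louvain_qstar

FAMILIES = ("R", "G", "T", "GT")


@dataclass(frozen=True)
class BinSpec:
    """Equal-width length bins over [min L, max L] of the non-zero edges."""
    n_bins: int
    boundaries: np.ndarray          # length n_bins + 1, strictly increasing
    edges_per_bin: np.ndarray       # occupancy counts, length n_bins

    @property
    def sparse_bin_percentage(self) -> float:
        """Percentage of bins holding three or fewer edges."""
        return 100.0 * np.count_nonzero(self.edges_per_bin <= 3) / self.n_bins


class BinSelectionError(RuntimeError):
    """No candidate bin count satisfies the selection criteria."""


def assign_length_bins(lengths: np.ndarray, n_bins: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Bin index per edge for equal-width bins; half-open, last bin closed."""
    lo, hi = lengths.min(), lengths.max()
    width = (hi - lo) / n_bins
    if width == 0:
        idx = np.zeros(len(lengths), dtype=int)
    else:
        idx = np.clip(np.floor((lengths - lo) / width).astype(int), 0, n_bins - 1)
    boundaries = lo + width * np.arange(n_bins + 1)
    return idx, boundaries


def select_length_bins(connectome: Connectome,
                       candidates: tuple[int, ...] = tuple(range(100, 0, -10)),
                       sparse_threshold: float = 10.0,
                       n_bins_override: int | None = None) -> BinSpec:
    """Select the number of equal-width length bins by descending scan.

    Candidate counts are scanned in the given order (100, 90, ..., 10 by
    default); the first count for which the percentage of bins with three
    or fewer edges is <= ``sparse_threshold`` *and* every bin holds more
    than one edge is accepted. ``n_bins_override`` bypasses the scan.
    """
    lengths = connectome.edge_lengths()
    if len(lengths) == 0:
        raise ValueError("connectome has no edges")
    if n_bins_override is not None:
        idx, boundaries = assign_length_bins(lengths, n_bins_override)
        counts = np.bincount(idx, minlength=n_bins_override)
        return BinSpec(n_bins_override, boundaries, counts)
    for n_bins in candidates:
        idx, boundaries = assign_length_bins(lengths, n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        sparse_pct = 100.0 * np.count_nonzero(counts <= 3) / n_bins
        if sparse_pct <= sparse_threshold and counts.min() > 1:
            return BinSpec(n_bins, boundaries, counts)
    raise BinSelectionError(
        "no candidate bin count met both criteria (sparse-bin percentage "
        f"<= {sparse_threshold}% and every bin holding more than one edge) "
        f"over candidates {candidates}")


def detect_structural_communities(connectome: Connectome, gamma: float = 1.0,
                                  n_restarts: int = 100, seed: int = 0
                                  ) -> np.ndarray:
    """Louvain communities of the (non-negative) structural network.

    The signed quality function reduces to ordinary modularity here since
    structural weights are non-negative. Returns the max-Q* partition over
    the randomized restarts.
    """
    if connectome.n_nodes == 0 or len(connectome.edge_weights()) == 0:
        raise ValueError("empty graph")
    labels, _ = louvain_qstar(connectome.W, gamma=gamma,
                              n_restarts=n_restarts, seed=seed)
    return labels


def richclub_categories(connectome: Connectome) -> np.ndarray:
    """Rich-club category per edge: min of the endpoint binary degrees.

    Permuting weights within categories leaves the weighted rich-club
    coefficient curve unchanged, since an edge of category m contributes to
    the rich-club numerator exactly for thresholds d < m.
    """
    deg = connectome.degrees()
    i, j = connectome.edge_index()
    return np.minimum(deg[i], deg[j])


@dataclass
class CellPartition:
    """Disjoint edge cells within which weight permutation is allowed."""
    cells: list[np.ndarray]                 # edge indices into the edge list
    n_edges: int
    constraint_tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        total = sum(len(c) for c in self.cells)
        if total != self.n_edges:
            raise ValueError(f"cells cover {total} edges, expected {self.n_edges}")
        seen = np.concatenate(self.cells) if self.cells else np.array([], int)
        if len(np.unique(seen)) != total:
            raise ValueError("cells are not disjoint")

    @property
    def permutable_edges(self) -> int:
        """Edges lying in cells of size >= 2 (the permutation pool)."""
        return sum(len(c) for c in self.cells if len(c) >= 2)

    @property
    def permutable_fraction(self) -> float:
        return self.permutable_edges / self.n_edges


def _group_cells(keys: np.ndarray) -> list[np.ndarray]:
    order = np.lexsort(keys.T[::-1]) if keys.ndim > 1 else np.argsort(keys, kind="stable")
    keys_sorted = keys[order]
    if keys.ndim == 1:
        change = np.flatnonzero(np.diff(keys_sorted)) + 1
    else:
        change = np.flatnonzero(np.any(np.diff(keys_sorted, axis=0) != 0, axis=1)) + 1
    return [np.sort(c) for c in np.split(order, change)]


def build_cells(connectome: Connectome, family: str,
                bins: BinSpec | None = None,
                partition: np.ndarray | None = None) -> CellPartition:
    """Cell partition of the edge set for one surrogate family."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    i, j = connectome.edge_index()
    m = len(i)
    if family == "R":
        return CellPartition([np.arange(m)], m, ("none",))

    keys = []
    tags = []
    if family in ("G", "GT"):
        if bins is None:
            raise ValueError("geometry-constrained family needs a BinSpec")
        lengths = connectome.edge_lengths()
        lo, hi = bins.boundaries[0], bins.boundaries[-1]
        if lengths.min() < lo - 1e-9 or lengths.max() > hi + 1e-9:
            raise ValueError("BinSpec does not cover this connectome's lengths")
        width = (hi - lo) / bins.n_bins
        bin_idx = (np.zeros(m, dtype=int) if width == 0 else
                   np.clip(np.floor((lengths - lo) / width).astype(int),
                           0, bins.n_bins - 1))
        keys.append(bin_idx)
        tags.append("geometry")
    if family in ("T", "GT"):
        if partition is None:
            raise ValueError("topology-constrained family needs a community partition")
        partition = np.asarray(partition)
        if len(partition) != connectome.n_nodes:
            raise ValueError("community partition does not match this connectome")
        same = partition[i] == partition[j]
        # block id: community c for within-community edges, -1 for the
        # single between-communities block
        block = np.where(same, partition[i], -1)
        keys.append(block)
        tags.append("community")
        keys.append(richclub_categories(connectome))
        tags.append("richclub")
    key_arr = np.stack(keys, axis=1)
    return CellPartition(_group_cells(key_arr), m, tuple(tags))


@dataclass
class SurrogateSample:
    """A permuted (optionally strength-adjusted) surrogate connectome."""
    connectome: Connectome
    family: str
    parent_seed: int
    permutable_fraction: float
    strength_error: float | None = None   # max relative error after adjustment


def permute_within_cells(connectome: Connectome, cells: CellPartition,
                         seed: int, family: str = "custom") -> SurrogateSample:
    """Uniformly permute weights within each cell of size >= 2.

    Lengths and binary support are untouched; the global weight multiset is
    conserved exactly, as is each cell's weight multiset.
    """
    i, j = connectome.edge_index()
    if cells.n_edges != len(i):
        raise ValueError("cell partition does not match this connectome")
    w = connectome.W[i, j].copy()
    rng = np.random.default_rng(seed)
    for cell in cells.cells:
        if len(cell) >= 2:
            w[cell] = w[cell][rng.permutation(len(cell))]
    W_new = np.zeros_like(connectome.W)
    W_new[i, j] = w
    W_new += W_new.T
    return SurrogateSample(connectome=connectome.with_weights(W_new),
                           family=family, parent_seed=seed,
                           permutable_fraction=cells.permutable_fraction)


def adjust_strength_sequence(sample: SurrogateSample,
                             target_strengths: np.ndarray,
                             tol: float = 1e-3,
                             max_iter: int = 100) -> SurrogateSample:
    """Restore the parent's strength sequence by iterative edge rescaling.

    Each iteration rescales every edge by the geometric mean of its
    endpoints' target/current strength ratios; the composition of the
    iterations is a diagonal scaling W -> F W F with positive node
    factors, so the permuted weights' cross-edge ratios within every node
    pair's neighbourhood shrink or grow smoothly. Stops when the maximum
    relative strength error drops below ``tol``; non-convergence warns
    and reports the achieved error.
    """
    target = np.asarray(target_strengths, dtype=float)
    if np.any(target <= 0):
        raise ValueError("target strengths must all be positive")
    conn = sample.connectome
    i, j = conn.edge_index()
    w = conn.W[i, j].copy()
    err = np.inf
    for it in range(max_iter + 1):
        W = np.zeros_like(conn.W)
        W[i, j] = w
        W += W.T
        s = W.sum(axis=1)
        err = float(np.max(np.abs(s - target) / target))
        if err < tol:
            break
        if it == max_iter:
            warnings.warn(f"strength adjustment did not converge: max "
                          f"relative error {err:.3e} after {max_iter} "
                          "iterations", RuntimeWarning, stacklevel=2)
            break
        ratio = target / s
        w = w * np.sqrt(ratio[i] * ratio[j])
    W = np.zeros_like(conn.W)
    W[i, j] = w
    W += W.T
    return SurrogateSample(connectome=conn.with_weights(W),
                           family=sample.family, parent_seed=sample.parent_seed,
                           permutable_fraction=sample.permutable_fraction,
                           strength_error=err)


def make_surrogate(connectome: Connectome, cells: CellPartition, seed: int,
                   family: str = "custom", adjust: bool = True,
                   tol: float = 1e-3, max_iter: int = 100) -> SurrogateSample:
    """Permute within cells and (by default) re-impose the strength sequence."""
    sample = permute_within_cells(connectome, cells, seed, family=family)
    if adjust:
        sample = adjust_strength_sequence(sample, connectome.strengths(),
                                          tol=tol, max_iter=max_iter)
    return sample


class RsnPairError(RuntimeError):
    """Main/control RSN surrogate pair could not be constructed."""


def _subcells(cells: CellPartition, keep_mask: np.ndarray) -> list[np.ndarray]:
    return [c[keep_mask[c]] for c in cells.cells if keep_mask[c].any()]


def make_rsn_pair(connectome: Connectome, gt_cells: CellPartition,
                  rsn: str, seed: int
                  ) -> tuple[CellPartition, CellPartition]:
    """Main/control cell partitions probing one RSN's local contribution.

    Main: GT cells restricted to edges incident to at least one node of the
    RSN; non-incident edges are frozen (singleton cells). Control: GT cells
    restricted to non-incident edges, randomly downselected so the control's
    permutable edge count matches the main's exactly whenever the cell-size
    arithmetic allows (otherwise as close as possible).
    """
    labels = connectome.nodes["rsn"].to_numpy()
    if rsn not in labels:
        raise RsnPairError(f"RSN {rsn!r} not present in node labels")
    i, j = connectome.edge_index()
    incident = (labels[i] == rsn) | (labels[j] == rsn)

    main_cells = _subcells(gt_cells, incident)
    frozen_main = np.flatnonzero(~incident)
    main = CellPartition(main_cells + [np.array([e]) for e in frozen_main],
                         gt_cells.n_edges,
                         gt_cells.constraint_tags + ("rsn_main",))
    if main.permutable_edges == 0:
        raise RsnPairError(f"RSN {rsn!r} has no incident permutable edges")

    ctrl_cells = [c for c in _subcells(gt_cells, ~incident)
                  if len(c) >= 2]
    pool = sum(len(c) for c in ctrl_cells)
    target = main.permutable_edges
    if pool == 0:
        raise RsnPairError(
            f"control for RSN {rsn!r} has no permutable edges before "
            "equalization (RSN covers the whole edge set)")
    if pool < target:
        raise RsnPairError(
            f"control pool for RSN {rsn!r} ({pool} edges) smaller than the "
            f"main permutable count ({target}); cannot equalize")

    rng = np.random.default_rng(seed)
    kept = _equalize_cells(ctrl_cells, target, rng)
    kept_ids = np.concatenate(kept) if kept else np.array([], int)
    frozen_ctrl = np.setdiff1d(np.arange(gt_cells.n_edges), kept_ids)
    control = CellPartition(kept + [np.array([e]) for e in frozen_ctrl],
                            gt_cells.n_edges,
                            gt_cells.constraint_tags + ("rsn_control",))
    return main, control


def _equalize_cells(cells: list[np.ndarray], target: int,
                    rng: np.random.Generator) -> list[np.ndarray]:
    """Keep whole or partial cells so kept permutable edges == target.

    A partial keep of size 1 contributes nothing permutable, so partial
    sizes are restricted to 0 or >= 2; when the remainder is 1 an edge is
    dropped from an earlier kept cell of size >= 3 to fix parity.
    """
    order = rng.permutation(len(cells))
    kept: list[np.ndarray] = []
    total = 0
    for ci in order:
        cell = cells[ci]
        if total >= target:
            break
        r = target - total
        if len(cell) <= r:
            kept.append(cell)
            total += len(cell)
        elif r >= 2:
            kept.append(rng.choice(cell, size=r, replace=False))
            total += r
        else:  # r == 1: take 2 here, then shave 1 from a big kept cell
            donor = next((k for k, c in enumerate(kept) if len(c) >= 3), None)
            if donor is not None:
                kept[donor] = rng.choice(kept[donor], size=len(kept[donor]) - 1,
                                         replace=False)
                kept.append(rng.choice(cell, size=2, replace=False))
                total += 1
            else:
                kept.append(rng.choice(cell, size=2, replace=False))
                total += 2  # parity unreachable; off by one
    return kept
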