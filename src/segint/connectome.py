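"""Structural connectome container and validation.

A connectome here is a weighted undirected network of cortical parcels:
``W`` holds dimensionless connection weights (streamline counts normalised
by parcel surface area in empirical data), ``L`` holds streamline lengths
in millimetres, and ``nodes`` carries parcel metadata (coordinates, a
structural-community label and a resting-state-network label).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

#: Canonical 7-network resting-state parcellation labels.
RSN_NAMES = ("CON", "DMN", "LIM", "DAN", "VAN", "SMN", "VIS")

NODE_COLUMNS = ("node_id", "x", "y", "z", "community", "rsn")


class ConnectomeValidationError(ValueError):
    """Raised when a weight/length/node triple violates the container contract."""


def make_node_table(coords: np.ndarray,
                    community: np.ndarray | None = None,
                    rsn: np.ndarray | None = None) -> pd.DataFrame:
    """Assemble a node metadata table from coordinates and optional labels."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if coords.shape != (n, 3):
        raise ValueError(f"coords must be (n, 3), got {coords.shape}")
    table = pd.DataFrame({
        "node_id": np.arange(n, dtype=int),
        "x": coords[:, 0],
        "y": coords[:, 1],
        "z": coords[:, 2],
        "community": (np.full(n, -1, dtype=int) if community is None
                      else np.asarray(community, dtype=int)),
        "rsn": (np.full(n, "UNASSIGNED", dtype=object) if rsn is None
                else np.asarray(rsn, dtype=object)),
    })
    return table


@dataclass
class Connectome:
    """Symmetric weighted structural network with streamline lengths.

    Attributes
    ----------
    W : (n, n) float array
        Non-negative connection weights, zero diagonal, symmetric.
    L : (n, n) float array
        Streamline lengths in mm; ``L > 0`` exactly where ``W > 0``.
    nodes : DataFrame
        One row per node with columns ``node_id, x, y, z, community, rsn``.
    """

    W: np.ndarray
    L: np.ndarray
    nodes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        validate_connectome(self.W, self.L, self.nodes)

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @property
    def density(self) -> float:
        """Fraction of non-zero entries in the upper triangle."""
        n = self.n_nodes
        iu = np.triu_indices(n, k=1)
        return float(np.count_nonzero(self.W[iu]) / len(iu[0]))

    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (i, j) indices of non-zero edges, i < j."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.W[iu, ju] > 0
        return iu[mask], ju[mask]

    def edge_weights(self) -> np.ndarray:
        i, j = self.edge_index()
        return self.W[i, j]

    def edge_lengths(self) -> np.ndarray:
        i, j = self.edge_index()
        return self.L[i, j]

    def degrees(self) -> np.ndarray:
        """Binary degrees of the unweighted support graph."""
        return (self.W > 0).sum(axis=1).astype(int)

    def strengths(self) -> np.ndarray:
        """Node strengths (weighted degrees)."""
        return self.W.sum(axis=1)

    def with_weights(self, W_new: np.ndarray) -> "Connectome":
        """Copy with replaced weights (support and lengths must be unchanged)."""
        return Connectome(W=np.asarray(W_new, dtype=float),
                          L=self.L.copy(), nodes=self.nodes.copy())


def validate_connectome(W: np.ndarray, L: np.ndarray, nodes: pd.DataFrame,
                        atol: float = 1e-12) -> None:
    """Check every container invariant; raise ConnectomeValidationError on failure."""
    n = W.shape[0]
    if W.shape != (n, n) or L.shape != (n, n):
        raise ConnectomeValidationError(
            f"W and L must be square and equal-sized, got {W.shape} and {L.shape}")
    if len(nodes) != n:
        raise ConnectomeValidationError(
            f"node table has {len(nodes)} rows for an n={n} matrix")
    for col in NODE_COLUMNS:
        if col not in nodes.columns:
            raise ConnectomeValidationError(f"node table missing column {col!r}")
    if not np.array_equal(nodes["node_id"].to_numpy(), np.arange(n)):
        raise ConnectomeValidationError("node_id must be 0..n-1 in order")
    if not np.all(np.isfinite(W)) or not np.all(np.isfinite(L)):
        raise ConnectomeValidationError("non-finite entries in W or L")
    if np.any(W < 0):
        raise ConnectomeValidationError("negative structural weights")
    if np.abs(W - W.T).max(initial=0.0) > atol:
        raise ConnectomeValidationError("W asymmetric beyond tolerance")
    if np.abs(L - L.T).max(initial=0.0) > atol:
        raise ConnectomeValidationError("L asymmetric beyond tolerance")
    if np.any(np.diag(W) != 0):
        raise ConnectomeValidationError("W diagonal must be zero")
    support = W > 0
    bad = support & ~(L > 0)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ConnectomeValidationError(
            f"W > 0 but L <= 0 at node pair ({i}, {j})")
    bad = (L > 0) & ~support
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ConnectomeValidationError(
            f"L > 0 but W = 0 at node pair ({i}, {j})")
    n_comp, _ = connected_components(csr_matrix(support), directed=False)
    if n > 0 and n_comp != 1:
        raise ConnectomeValidationError(
            f"binarized graph has {n_comp} connected components, expected 1")


def weighted_rich_club(connectome: Connectome,
                       degrees: np.ndarray | None = None) -> pd.DataFrame:
    """Weighted rich-club coefficient phi_w(d) over degree thresholds.

    phi_w(d) is the ratio of the summed weight of edges whose two endpoints
    both have binary degree > d to the total summed edge weight. Returned
    as a table with one row per threshold d = 0 .. max(degree) - 1.
    """
    if degrees is None:
        degrees = connectome.degrees()
    i, j = connectome.edge_index()
    w = connectome.W[i, j]
    total = w.sum()
    min_deg = np.minimum(degrees[i], degrees[j])
    ds = np.arange(0, degrees.max())
    phi = np.array([w[min_deg > d].sum() / total for d in ds])
    return pd.DataFrame({"d": ds, "phi_w": phi})


def rich_club_ratio(connectome: Connectome, n_perm: int = 50,
                    seed: int = 0) -> pd.DataFrame:
    """phi_w(d) normalized by its mean under random weight permutation.

    A ratio above one at high degree thresholds marks a weighted rich
    club: hub-hub connections carry more weight than the same topology
    with weights shuffled across the fixed support.
    """
    base = weighted_rich_club(connectome)
    i, j = connectome.edge_index()
    w = connectome.W[i, j]
    deg = connectome.degrees()
    min_deg = np.minimum(deg[i], deg[j])
    total = w.sum()
    rng = np.random.default_rng(seed)
    ds = base["d"].to_numpy()
    null = np.zeros(len(ds))
    for _ in range(n_perm):
        wp = w[rng.permutation(len(w))]
        null += np.array([wp[min_deg > d].sum() / total for d in ds])
    null /= n_perm
    out = base.assign(phi_null=null)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio"] = out["phi_w"] / out["phi_null"]
    return out


def rsn_densities(connectome: Connectome) -> pd.Series:
    """Edge density of the subgraph within each RSN (present labels only)."""
    labels = connectome.nodes["rsn"].to_numpy()
    out = {}
    for name in RSN_NAMES:
        idx = np.flatnonzero(labels == name)
        if len(idx) < 2:
            continue
        sub = connectome.W[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        out[name] = float(np.count_nonzero(sub[iu]) / len(iu[0]))
    return pd.Series(out, name="density")
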