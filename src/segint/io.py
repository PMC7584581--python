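"""Delimited-text readers/writers for connectomes, BOLD runs and results.

Matrices are written as TSV with a header row and index column of node
ids; node tables as TSV with the canonical columns; provenance as JSON
sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import (Connectome, ConnectomeValidationError,
                         validate_connectome)
from .surrogates import SurrogateSample


def write_matrix(path: str | Path, matrix: np.ndarray,
                 node_ids: np.ndarray | None = None) -> None:
    n = matrix.shape[0]
    ids = np.arange(n) if node_ids is None else node_ids
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)


def write_connectome(connectome: Connectome, outdir: str | Path,
                     prefix: str = "connectome") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = connectome.nodes["node_id"].to_numpy()
    paths = {
        "W": outdir / f"{prefix}_W.tsv",
        "L": outdir / f"{prefix}_L.tsv",
        "nodes": outdir / "nodes.tsv",
    }
    write_matrix(paths["W"], connectome.W, ids)
    write_matrix(paths["L"], connectome.L, ids)
    connectome.nodes.to_csv(paths["nodes"], sep="\t", index=False)
    return paths


def read_connectome(path_w: str | Path, path_l: str | Path,
                    path_nodes: str | Path,
                    asym_tol: float = 1e-12) -> Connectome:
    """Load and validate a connectome; small asymmetries are symmetrized.

    Asymmetry beyond ``asym_tol`` (absolute) raises a validation error, as
    do support mismatches between W and L and all other container
    invariant violations.
    """
    W = read_matrix(path_w)
    L = read_matrix(path_l)
    nodes = pd.read_csv(path_nodes, sep="\t")
    if W.shape != L.shape or W.shape[0] != W.shape[1]:
        raise ConnectomeValidationError(
            f"matrices must be square and equal-sized, got {W.shape} "
            f"and {L.shape}")
    for M, name in ((W, "W"), (L, "L")):
        if np.abs(M - M.T).max(initial=0.0) > asym_tol:
            raise ConnectomeValidationError(
                f"{name} asymmetric beyond tolerance {asym_tol}")
    W = (W + W.T) / 2.0
    L = (L + L.T) / 2.0
    validate_connectome(W, L, nodes)
    return Connectome(W=W, L=L, nodes=nodes)


def write_surrogate(sample: SurrogateSample, outdir: str | Path) -> Path:
    """Surrogate weights plus a JSON provenance record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"surr_{sample.family}_{sample.parent_seed}"
    write_matrix(outdir / f"{stem}_W.tsv", sample.connectome.W,
                 sample.connectome.nodes["node_id"].to_numpy())
    record = {
        "family": sample.family,
        "seed": sample.parent_seed,
        "permutable_fraction": sample.permutable_fraction,
        "strength_error": sample.strength_error,
    }
    with open(outdir / f"{stem}.json", "w") as fh:
        json.dump(record, fh, indent=1)
    return outdir / f"{stem}_W.tsv"


def write_bold(series: np.ndarray, tr: float, path: str | Path,
               sidecar: dict | None = None) -> None:
    pd.DataFrame(series).to_csv(path, sep="\t", index=False,
                                float_format="%.10g")
    meta = {"tr": tr, "n_nodes": int(series.shape[0]),
            "n_trs": int(series.shape[1])}
    meta.update(sidecar or {})
    with open(Path(path).with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
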