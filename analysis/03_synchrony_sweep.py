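"""Sweep the global coupling constant and map the synchrony transition.

On the desk-profile parent (57 nodes) the time-mean order parameter is
computed across the canonical coupling grid. The sweep locates the
intermediate-synchrony regime; the grid value whose synchrony lies
closest to 0.4 is reported as the reference coupling for the
fluctuation experiment (the desk-profile analogue of the full-size
regime the canonical parameters target). Writes results/sweep.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from segint.simulator import SimConfig, mean_synchrony
from segint.synthetic import make_default_connectome

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    parent = make_default_connectome(57, seed=1)
    rows = []
    for k in np.arange(2.5, 70.0 + 1e-9, 2.5):
        r = mean_synchrony(parent, SimConfig(k=float(k), duration=140.0,
                                             transient=20.0, seed=42))
        rows.append({"k": float(k), "mean_sync": r})
        print(f"k = {k:5.1f}: mean r = {r:.3f}")
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "sweep.tsv", sep="\t", index=False,
                 float_format="%.6g")
    best = table.iloc[(table["mean_sync"] - 0.4).abs().argmin()]
    print(f"\nintermediate-synchrony reference: k = {best['k']} "
          f"(mean r = {best['mean_sync']:.3f})")


if __name__ == "__main__":
    sys.exit(main())
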