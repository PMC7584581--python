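"""Generate the synthetic structural connectomes and report their profiles.

Writes the full-size (114-node) and reduced (57-node) parent connectomes
under results/connectome/ and prints the emulation checks: density near
0.19, negative weight-length correlation, within > between community
weights, rising rich-club ratio, and maximal within-RSN density for VIS.
"""

import sys
from pathlib import Path

import numpy as np
from scipy import stats as sps

from segint.connectome import rich_club_ratio, rsn_densities
from segint.io import write_connectome
from segint.synthetic import make_default_connectome

OUT = Path(__file__).resolve().parent.parent / "results" / "connectome"


def report(c, label):
    i, j = c.edge_index()
    rho = sps.spearmanr(c.edge_weights(), c.edge_lengths()).statistic
    comm = c.nodes["community"].to_numpy()
    within = comm[i] == comm[j]
    w = c.W[i, j]
    rc = rich_club_ratio(c, n_perm=30, seed=0).dropna()
    top = rc[rc["d"] >= np.median(c.degrees())]
    print(f"--- {label} ---")
    print(f"nodes {c.n_nodes}, edges {len(w)}, density {c.density:.3f}")
    print(f"spearman(weight, length) = {rho:.3f}")
    print(f"mean weight within/between communities: "
          f"{w[within].mean():.3f} / {w[~within].mean():.3f}")
    print(f"rich-club ratio at top degrees: {top['ratio'].iloc[-1]:.2f}")
    print("within-RSN densities:",
          rsn_densities(c).round(3).to_dict())


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    full = make_default_connectome(114, seed=0)
    desk = make_default_connectome(57, seed=1)
    write_connectome(full, OUT, prefix="connectome114")
    write_connectome(desk, OUT / "desk", prefix="connectome57")
    report(full, "full profile (n=114)")
    report(desk, "desk profile (n=57)")


if __name__ == "__main__":
    sys.exit(main())
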