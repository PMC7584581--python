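"""Group comparisons of fluctuation magnitudes.

Pairwise comparisons use the two-sided Mann-Whitney U test (exact
enumeration over labelings for small pooled samples, tie- and
continuity-corrected normal approximation otherwise), Cliff's delta as
the effect size, and Benjamini-Hochberg step-up adjustment across the
comparison plan.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x with midrank tie handling."""
    greater = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(greater + 0.5 * ties)


def mann_whitney_u(x, y, exact_limit: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test: returns (U of x, p).

    For pooled sizes up to ``exact_limit`` the p-value is computed by
    exhaustive enumeration of all C(n1+n2, n1) group labelings of the
    pooled values (valid under ties); larger samples use scipy's
    asymptotic method with tie-corrected variance and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    u_obs = _u_statistic(x, y)
    n1, n2 = len(x), len(y)
    if n1 + n2 <= exact_limit:
        pooled = np.concatenate([x, y])
        centre = n1 * n2 / 2.0
        dev_obs = abs(u_obs - centre)
        hits = 0
        total = comb(n1 + n2, n1)
        idx_all = np.arange(n1 + n2)
        for chosen in combinations(idx_all, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(chosen)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - centre) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic")
    return u_obs, float(res.pvalue)


def bh_fdr(pvals, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the number of comparisons the correction spans (defaults to
    the number of p-values); adjusted values are monotone in the sorted
    order and capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be at least the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def cliffs_delta(x, y) -> float:
    """All-pairs dominance effect size in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    gt = (x[:, None] > y[None, :]).sum()
    lt = (x[:, None] < y[None, :]).sum()
    return float((gt - lt) / (len(x) * len(y)))


def compare_conditions(magnitudes: dict[str, np.ndarray],
                       comparison_plan: list[tuple[str, str]],
                       alpha: float = 0.05,
                       m: int | None = None) -> pd.DataFrame:
    """Pairwise U / p / Cliff's delta table with BH adjustment over the plan.

    Significance is flagged at FDR ``alpha`` across the plan's comparisons
    (``m`` overrides the correction span, e.g. when the plan is a subset
    of a larger family of comparisons).
    """
    for a, b in comparison_plan:
        for name in (a, b):
            if name not in magnitudes:
                raise ValueError(f"family {name!r} missing from magnitudes")
    rows = []
    for a, b in comparison_plan:
        u, p = mann_whitney_u(magnitudes[a], magnitudes[b])
        rows.append({"a": a, "b": b, "n_a": len(magnitudes[a]),
                     "n_b": len(magnitudes[b]), "U": u, "p": p,
                     "cliffs_delta": cliffs_delta(magnitudes[a],
                                                  magnitudes[b])})
    table = pd.DataFrame(rows)
    table["p_fdr"] = bh_fdr(table["p"].to_numpy(), m=m)
    table["significant"] = table["p_fdr"] < alpha
    return table
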