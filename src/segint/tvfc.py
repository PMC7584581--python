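"""Time-resolved functional connectivity with tapered sliding windows.

The taper is a rectangle of width 66 TRs convolved with a Gaussian kernel
of sigma = 9 TRs (truncated at +/-3 sigma), normalized to unit sum, and
used as observation weights in a weighted Pearson correlation. Windows
advance from the start of the series in steps of 3 TRs; the final partial
window is dropped. Correlations are Fisher z-transformed with |r| clamped
just below 1, kept signed, and not thresholded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .hemodynamics import BoldRun


@dataclass(frozen=True)
class Taper:
    values: np.ndarray
    width_rect: int
    sigma: float

    @property
    def support(self) -> int:
        return len(self.values)


@dataclass
class TvFcSeries:
    """Sequence of symmetric signed Fisher-z FC matrices, one per window."""
    matrices: list[np.ndarray]
    window_starts: np.ndarray
    step: int
    taper: Taper

    def __len__(self) -> int:
        return len(self.matrices)


def build_taper(width_rect: int = 66, sigma: float = 9.0,
                kernel_halfwidth: int | None = None) -> Taper:
    """Rectangle-convolved-with-Gaussian taper, unit sum.

    ``kernel_halfwidth`` defaults to ceil(3 sigma); a halfwidth of 0
    degenerates the kernel to a unit impulse, recovering the plain
    rectangle window.
    """
    if width_rect < 2:
        raise ValueError("width_rect must be >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if kernel_halfwidth is None:
        kernel_halfwidth = math.ceil(3.0 * sigma)
    if kernel_halfwidth == 0:
        kernel = np.array([1.0])
    else:
        offsets = np.arange(-kernel_halfwidth, kernel_halfwidth + 1)
        kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    values = np.convolve(np.ones(width_rect), kernel, mode="full")
    values /= values.sum()
    return Taper(values=values, width_rect=width_rect, sigma=sigma)


def n_windows(n_samples: int, support: int, step: int) -> int:
    """Number of full window placements: floor((T - support)/step) + 1."""
    if n_samples < support:
        return 0
    return (n_samples - support) // step + 1


def weighted_correlation(x: np.ndarray, weights: np.ndarray,
                         clamp: float = 1e-15) -> np.ndarray:
    """Weighted Pearson correlation matrix with Fisher-z-safe clamping.

    Rows of ``x`` are variables; ``weights`` are non-negative, unit-sum
    observation weights. Zero-variance rows yield r = 0 against everything
    (reported via a warning by the caller).
    """
    mean = x @ weights
    xc = (x - mean[:, None]) * np.sqrt(weights)
    cov = xc @ xc.T
    var = np.diag(cov).copy()
    # scale-relative zero-variance detection (a constant row leaves
    # rounding residue of order eps * |mean|)
    bad = np.sqrt(np.maximum(var, 0.0)) \
        <= 1e-12 * np.maximum(1.0, np.abs(mean))
    denom = np.sqrt(np.where(bad, 1.0, var))
    r = cov / denom[:, None] / denom[None, :]
    r[bad, :] = 0.0
    r[:, bad] = 0.0
    np.fill_diagonal(r, 0.0)
    return np.clip(r, -1.0 + clamp, 1.0 - clamp)


def sliding_window_fc(bold: BoldRun, taper: Taper | None = None,
                      step: int = 3) -> TvFcSeries:
    """Tapered sliding-window FC series of a BOLD run.

    Each window's matrix is the Fisher z-transform of the taper-weighted
    Pearson correlation of every node pair, signed and unthresholded, with
    zero diagonal.
    """
    if taper is None:
        taper = build_taper()
    x = np.asarray(bold.series, dtype=float)
    support = taper.support
    if x.shape[1] < support:
        raise ValueError(f"series of {x.shape[1]} TRs shorter than the "
                         f"taper support ({support} TRs)")
    starts = np.arange(0, x.shape[1] - support + 1, step)
    mats = []
    for s in starts:
        seg = x[:, s:s + support]
        var_ok = seg.std(axis=1) > 1e-12 * np.maximum(
            1.0, np.abs(seg.mean(axis=1)))
        if not np.all(var_ok):
            warnings.warn(f"window at TR {s}: zero-variance node(s); their "
                          "correlations set to 0", RuntimeWarning,
                          stacklevel=2)
        r = weighted_correlation(seg, taper.values)
        mats.append(np.arctanh(r))
    return TvFcSeries(matrices=mats, window_starts=starts, step=step,
                      taper=taper)
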