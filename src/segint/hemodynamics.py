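"""Balloon/Windkessel hemodynamic forward model and BOLD post-processing.

Neural amplitude drives a vasodilatory signal s, which drives blood
inflow f; volume v and deoxyhemoglobin q follow Windkessel dynamics, and
the BOLD observation is the standard nonlinear combination

    y = V0 [ k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v) ],
    k1 = 7 rho, k2 = 2, k3 = 2 rho - 0.2.

Parameter defaults are the standard published set (kappa = 0.65 1/s,
gamma = 0.41 1/s, tau = 0.98 s, alpha = 0.32, rho = 0.34, V0 = 0.02).
Raw BOLD is band-pass filtered (zero-phase Butterworth, 0.021-0.1 Hz by
default), resampled onto the fMRI TR grid (0.72 s), and the node-mean
"global" signal is regressed out with an intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from ._balloon import integrate_balloon
from .simulator import NeuralSignal


@dataclass(frozen=True)
class HemoParams:
    kappa: float = 0.65     # signal decay rate, 1/s
    gamma_f: float = 0.41   # flow feedback rate, 1/s
    tau_h: float = 0.98     # hemodynamic transit time, s
    alpha: float = 0.32     # vessel stiffness exponent
    rho: float = 0.34       # resting oxygen extraction fraction
    v0: float = 0.02        # resting blood volume fraction
    input_gain: float = 1.0

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma_f", "tau_h", "v0", "input_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")


@dataclass
class BoldRun:
    """TR-sampled, band-limited, globally-regressed BOLD series."""
    series: np.ndarray      # (n_nodes, n_TRs)
    tr: float = 0.72


def balloon_windkessel(neural: NeuralSignal,
                       params: HemoParams = HemoParams()) -> np.ndarray:
    """Raw BOLD at the neural sampling rate (1 kHz) per node.

    All nodes start at the resting fixed point; zero input therefore yields
    an exactly constant (zero) output.
    """
    z = np.asarray(neural.series, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite neural input")
    dt = 1.0 / neural.fs
    bold, ok, bad_i, bad_t = integrate_balloon(
        z, dt, params.kappa, params.gamma_f, params.tau_h, params.alpha,
        params.rho, params.v0, params.input_gain)
    if not ok:
        raise FloatingPointError(
            f"hemodynamic state blow-up at node {bad_i}, sample {bad_t}")
    return bold


def bandpass_filter(x: np.ndarray, fs: float, band: tuple[float, float],
                    order: int = 2) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along axis -1."""
    low, high = band
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band {band} must lie inside (0, {nyq}) Hz")
    sos = signal.butter(order, [low / nyq, high / nyq], btype="band",
                        output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def regress_global_signal(x: np.ndarray) -> np.ndarray:
    """Residual of each node series after regressing out [1, global mean]."""
    g = x.mean(axis=0)
    design = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    return x - (design @ beta).T


def postprocess_bold(raw: np.ndarray, fs: float = 1000.0, tr: float = 0.72,
                     band: tuple[float, float] = (0.021, 0.1)) -> BoldRun:
    """Filter, resample to the TR grid, and regress out the global signal.

    The run must span at least ~3 time constants of the high-pass corner
    (3 / (2 pi f_low)) for the filter transient to be meaningful. The TR
    grid holds floor(duration / TR) samples at times i * TR; the band-pass
    at 0.1 Hz leaves no energy near the TR Nyquist, so grid sampling is
    alias-free.
    """
    raw = np.asarray(raw, dtype=float)
    duration = raw.shape[1] / fs
    if duration < 3.0 / (2.0 * np.pi * band[0]):
        raise ValueError(
            f"run of {duration:.1f} s is shorter than three time constants "
            f"of the {band[0]} Hz high-pass corner")
    filtered = bandpass_filter(raw, fs, band)
    n_trs = int(np.floor(duration / tr))
    idx = np.clip(np.rint(np.arange(n_trs) * tr * fs).astype(int),
                  0, raw.shape[1] - 1)
    sampled = filtered[:, idx]
    return BoldRun(series=regress_global_signal(sampled), tr=tr)


def neural_to_bold(neural: NeuralSignal,
                   params: HemoParams = HemoParams(),
                   tr: float = 0.72,
                   band: tuple[float, float] = (0.021, 0.1)) -> BoldRun:
    """Full hemodynamic conversion chain."""
    raw = balloon_windkessel(neural, params)
    return postprocess_bold(raw, fs=neural.fs, tr=tr, band=band)
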