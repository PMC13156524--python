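"""Independent oracles used by the test suite.

These deliberately avoid the package's own estimation code paths: the OLS
deconvolution oracle solves the lagged least-squares problem directly, and
the spectral helpers use plain periodograms.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import periodogram


def ols_deconvolve(x: np.ndarray, y: np.ndarray, lag_samples: np.ndarray) -> np.ndarray:
    """Least-squares FIR kernel h with y(k) ~ sum_l h_l x(k - l)."""
    n = x.size
    design = np.zeros((n, lag_samples.size))
    for j, lag in enumerate(lag_samples):
        lag = int(lag)
        if lag == 0:
            design[:, j] = x
        elif lag > 0:
            design[lag:, j] = x[:-lag]
        else:
            design[:lag, j] = x[-lag:]
    h, *_ = np.linalg.lstsq(design, y, rcond=None)
    return h


def ols_predict(x: np.ndarray, h: np.ndarray, lag_samples: np.ndarray) -> np.ndarray:
    n = x.size
    out = np.zeros(n)
    for j, lag in enumerate(lag_samples):
        lag = int(lag)
        if lag == 0:
            out += h[j] * x
        elif lag > 0:
            out[lag:] += h[j] * x[:-lag]
        else:
            out[:lag] += h[j] * x[-lag:]
    return out


def dominant_frequency(x: np.ndarray, fs: float, fmin: float = 0.5) -> float:
    """Frequency of the largest periodogram peak above ``fmin``."""
    f, p = periodogram(x, fs)
    keep = f >= fmin
    return float(f[keep][np.argmax(p[keep])])


def power_fraction_below(x: np.ndarray, fs: float, f_cut: float) -> float:
    f, p = periodogram(x, fs)
    total = p.sum()
    return float(p[f < f_cut].sum() / total) if total > 0 else 0.0


def binomial_band(n: int, p: float = 0.5, z: float = 1.96) -> tuple[float, float]:
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half
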