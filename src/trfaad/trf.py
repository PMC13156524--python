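"""Forward/backward temporal response functions estimated by sparse boosting.

The forward model predicts EEG channel ``i`` from a stimulus feature ``x``::

    yhat_i(k) = sum_l h_{l,i} x(k - l)

and the backward model reconstructs the feature from all EEG channels::

    xhat(k) = sum_i sum_l h_{l,i} y_i(k + l)

Kernels are parameterized as a weighted sum of Hamming-window basis
functions (50-ms width, one centered on every lag-grid element, 20-ms
spacing at the 50-Hz analysis rate).  Estimation is greedy coordinate
boosting: at every step the single basis weight whose +/- ``step``
increment most reduces the training mean absolute error is updated, with
early stopping on a held-out inner-validation partition.  The returned
kernel is the mean of the per-partition kernels, so it is exactly
representable in the basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import BasisSet, FeatureSignal, TimeSeriesBlock, TRFKernel
from .errors import InvalidArgumentError, ZeroVarianceError

__all__ = [
    "make_basis",
    "make_lag_grid",
    "predict_forward",
    "reconstruct_backward",
    "BoostingConfig",
    "boosting_fit",
    "pearson_r",
]

try:  # compiled inner loop; pure-numpy fallback below
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally available
    _HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# lag grid and basis

def make_lag_grid(lag_range: tuple[float, float], fs: float) -> np.ndarray:
    """Uniform lag grid (seconds) covering ``lag_range`` at spacing 1/fs."""
    t_min, t_max = lag_range
    if t_max < t_min:
        raise InvalidArgumentError(f"bad lag range {lag_range}")
    l1 = int(round(t_min * fs))
    l2 = int(round(t_max * fs))
    return np.arange(l1, l2 + 1) / fs


def make_basis(
    lag_count: int,
    width: float = 50.0,
    spacing: float | None = None,
    fs: float = 50.0,
) -> BasisSet:
    """Hamming-window basis: one unit-peak window per lag-grid element.

    ``width`` and ``spacing`` are in milliseconds; ``spacing`` defaults to
    the grid spacing ``1000 / fs``.  Windows at the grid edges are
    truncated.
    """
    if spacing is None:
        spacing = 1000.0 / fs
    if width < 1000.0 / fs:
        raise InvalidArgumentError(
            f"basis width {width} ms below one sample ({1000.0 / fs} ms)"
        )
    if lag_count < 1:
        raise InvalidArgumentError("lag_count must be >= 1")
    offsets = (np.arange(lag_count)[:, None] - np.arange(lag_count)[None, :]) * spacing
    half = width / 2.0
    inside = np.abs(offsets) <= half + 1e-9
    # Hamming profile over [-half, half]; peak is exactly 1 at the center
    mat = np.where(inside, 0.54 + 0.46 * np.cos(np.pi * offsets / half), 0.0)
    return BasisSet(mat, width, spacing, fs)


# ---------------------------------------------------------------------------
# kernel application

def _lagged_matrix(x: np.ndarray, lag_samples: np.ndarray, sign: int) -> np.ndarray:
    """Columns ``x(k - sign * l)`` for each lag ``l`` (zero padded)."""
    n = x.size
    out = np.zeros((n, lag_samples.size))
    for j, lag in enumerate(lag_samples):
        shift = sign * int(lag)
        if shift == 0:
            out[:, j] = x
        elif shift > 0:
            out[shift:, j] = x[:-shift]
        else:
            out[:shift, j] = x[-shift:]
    return out


def predict_forward(kernel: TRFKernel, feature: FeatureSignal) -> TimeSeriesBlock:
    """Forward prediction ``yhat_i(k) = sum_l h_{l,i} x(k-l)`` per channel."""
    if kernel.direction != "forward":
        raise InvalidArgumentError("kernel direction must be 'forward'")
    if not np.isclose(kernel.fs, feature.fs):
        raise InvalidArgumentError(
            f"rate mismatch: kernel {kernel.fs} Hz vs feature {feature.fs} Hz"
        )
    lagged = _lagged_matrix(feature.values, kernel.lag_samples, sign=+1)
    data = (lagged @ kernel.coefs).T
    return TimeSeriesBlock(data, kernel.fs, kernel.channel_names)


def reconstruct_backward(kernel: TRFKernel, eeg: TimeSeriesBlock) -> FeatureSignal:
    """Backward reconstruction ``xhat(k) = sum_i sum_l h_{l,i} y_i(k+l)``."""
    if kernel.direction != "backward":
        raise InvalidArgumentError("kernel direction must be 'backward'")
    if eeg.n_channels != kernel.n_channels:
        raise InvalidArgumentError(
            f"channel mismatch: kernel {kernel.n_channels} vs EEG {eeg.n_channels}"
        )
    if not np.isclose(kernel.fs, eeg.fs):
        raise InvalidArgumentError("sampling-rate mismatch")
    lags = kernel.lag_samples
    out = np.zeros(eeg.n_samples)
    for i in range(eeg.n_channels):
        lagged = _lagged_matrix(eeg.data[i], lags, sign=-1)
        out += lagged @ kernel.coefs[:, i]
    return FeatureSignal(out, kernel.fs, name="reconstruction")


# ---------------------------------------------------------------------------
# Pearson correlation

def pearson_r(a, b) -> float:
    """Pearson correlation coefficient of two equal-length signals."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise InvalidArgumentError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise InvalidArgumentError("need at least 2 samples")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da * da).sum() * (db * db).sum())
    if denom == 0:
        raise ZeroVarianceError("correlation undefined for constant input")
    return float((da * db).sum() / denom)


# ---------------------------------------------------------------------------
# boosting

@dataclass
class BoostingConfig:
    """Settings for the greedy coordinate boosting estimator.

    ``step_size`` is in units of target SD per input SD.  ``partitions``
    contiguous segments of the training data each serve once as the inner
    validation set; the final kernel averages the per-partition solutions.
    ``patience`` is the number of accepted steps tolerated without a new
    inner-validation optimum before stopping.
    """

    step_size: float = 0.005
    partitions: int = 4
    patience: int = 20
    max_steps: int = 20000
    objective: str = "MAE"
    seed: int = 0

    def __post_init__(self):
        if self.step_size <= 0:
            raise InvalidArgumentError("step_size must be positive")
        if self.partitions < 2:
            raise InvalidArgumentError("need at least 2 inner partitions")
        if self.objective != "MAE":
            raise InvalidArgumentError(f"unsupported objective: {self.objective!r}")


if _HAVE_NUMBA:

    @njit(cache=True)
    def _best_candidate(r, C, step):  # pragma: no cover - compiled
        n, q = C.shape[1], C.shape[0]
        base = 0.0
        for k in range(n):
            base += abs(r[k])
        best_err = base
        best_q = -1
        best_sign = 0.0
        for j in range(q):
            ep = 0.0
            em = 0.0
            row = C[j]
            for k in range(n):
                d = step * row[k]
                rv = r[k]
                ep += abs(rv - d)
                em += abs(rv + d)
            if ep < best_err:
                best_err = ep
                best_q = j
                best_sign = 1.0
            if em < best_err:
                best_err = em
                best_q = j
                best_sign = -1.0
        return best_q, best_sign, best_err, base

else:

    def _best_candidate(r, C, step):
        base = np.abs(r).sum()
        best_err, best_q, best_sign = base, -1, 0.0
        # chunk over candidates to bound memory
        chunk = max(1, int(2e6 // max(r.size, 1)))
        for start in range(0, C.shape[0], chunk):
            block = C[start : start + chunk]
            ep = np.abs(r[None, :] - step * block).sum(axis=1)
            em = np.abs(r[None, :] + step * block).sum(axis=1)
            for j in range(block.shape[0]):
                if ep[j] < best_err:
                    best_err, best_q, best_sign = ep[j], start + j, 1.0
                if em[j] < best_err:
                    best_err, best_q, best_sign = em[j], start + j, -1.0
        return best_q, best_sign, best_err, base


def _boost_one(C_train, C_val, y_train, y_val, step, patience, max_steps):
    """Boost a single output against candidate columns; returns weights.

    ``C_*`` are candidate design matrices of shape ``(Q, N)``.
    """
    q = C_train.shape[0]
    w = np.zeros(q)
    best_w = np.zeros(q)
    r_train = y_train.copy()
    r_val = y_val.copy()
    best_val = np.abs(r_val).mean()
    stall = 0
    for _ in range(max_steps):
        jq, sign, err, base = _best_candidate(r_train, C_train, step)
        if jq < 0 or err >= base - 1e-12:
            break  # no candidate reduces training MAE
        delta = sign * step
        w[jq] += delta
        r_train -= delta * C_train[jq]
        r_val -= delta * C_val[jq]
        val = np.abs(r_val).mean()
        if val < best_val - 1e-12:
            best_val = val
            best_w[:] = w
            stall = 0
        else:
            stall += 1
            if stall > patience:
                break
    return best_w


def _candidate_designs(
    inputs: np.ndarray, lag_samples: np.ndarray, basis: BasisSet, sign: int
) -> np.ndarray:
    """Stack per-input-channel basis-response columns -> (n_in * P, N)."""
    blocks = []
    for i in range(inputs.shape[0]):
        lagged = _lagged_matrix(inputs[i], lag_samples, sign=sign)
        blocks.append(np.ascontiguousarray((lagged @ basis.matrix).T))
    return np.concatenate(blocks, axis=0)


def _partition_slices(n: int, k: int) -> list[slice]:
    edges = np.linspace(0, n, k + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def boosting_fit(
    inputs: TimeSeriesBlock,
    targets: TimeSeriesBlock,
    lag_range: tuple[float, float],
    basis: BasisSet | None = None,
    cfg: BoostingConfig | None = None,
    direction: str = "forward",
) -> TRFKernel:
    """Estimate a TRF by sparse boosting with inner-validation stopping.

    For ``direction='forward'`` every target channel is regressed
    independently onto the (single- or multi-channel) input feature; for
    ``'backward'`` the single target feature is regressed onto all input
    EEG channels jointly (lag sign convention ``k + l``).
    """
    cfg = cfg or BoostingConfig()
    if direction not in ("forward", "backward"):
        raise InvalidArgumentError(f"bad direction: {direction!r}")
    if not np.isclose(inputs.fs, targets.fs):
        raise InvalidArgumentError("inputs and targets must share a sampling rate")
    if inputs.n_samples != targets.n_samples:
        raise InvalidArgumentError("inputs and targets must have equal duration")
    fs = float(inputs.fs)
    lags = make_lag_grid(lag_range, fs)
    if basis is None:
        basis = make_basis(lags.size, fs=fs)
    if basis.n_lags != lags.size:
        raise InvalidArgumentError(
            f"basis has {basis.n_lags} lags but grid has {lags.size}"
        )
    lag_samples = np.round(lags * fs).astype(int)
    sign = +1 if direction == "forward" else -1

    in_sd = inputs.data.std(axis=1)
    degenerate = np.all(in_sd == 0)
    if degenerate:
        warnings.warn("constant input signal; returning zero kernel", stacklevel=2)

    n = inputs.n_samples
    if direction == "backward" and targets.n_channels != 1:
        raise InvalidArgumentError("backward fitting expects a 1-channel target")
    if direction == "forward" and inputs.n_channels != 1:
        raise InvalidArgumentError("forward fitting expects a 1-channel feature")
    n_out = targets.n_channels
    n_in = inputs.n_channels
    P = basis.n_functions

    C = _candidate_designs(inputs.data, lag_samples, basis, sign)
    parts = _partition_slices(n, cfg.partitions)

    coefs = np.zeros((lags.size, n_in if direction == "backward" else n_out))
    weights = np.zeros_like(coefs)
    for out_ch in range(n_out):
        y = targets.data[out_ch]
        y_sd = y.std()
        if y_sd == 0 or degenerate:
            continue
        # step in raw units: step_size is expressed in target SD per input SD
        in_scale = float(np.exp(np.log(in_sd[in_sd > 0]).mean()))
        w_accum = np.zeros(C.shape[0])
        for val_slice in parts:
            mask = np.ones(n, dtype=bool)
            mask[val_slice] = False
            C_train = np.ascontiguousarray(C[:, mask])
            C_val = np.ascontiguousarray(C[:, ~mask])
            step = cfg.step_size * y_sd / in_scale
            w_accum += _boost_one(
                C_train, C_val, y[mask], y[~mask], step, cfg.patience, cfg.max_steps
            )
        w_mean = w_accum / cfg.partitions
        if direction == "backward":
            weights = w_mean.reshape(n_in, P).T
            coefs = basis.matrix @ weights
        else:
            weights[:, out_ch] = w_mean
            coefs[:, out_ch] = basis.matrix @ w_mean

    names = inputs.channel_names if direction == "backward" else targets.channel_names
    return TRFKernel(
        coefs=coefs,
        lags=lags,
        fs=fs,
        direction=direction,
        basis=basis,
        weights=weights,
        channel_names=names,
    )
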