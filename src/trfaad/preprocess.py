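"""Deterministic EEG conditioning chain.

Stages (in the order enforced by :func:`preprocess_chain`): rereferencing,
50-Hz notch, 0.1-40 Hz bandpass, an optional artifact-removal hook, 1-20 Hz
bandpass, resampling to 50 Hz, and per-channel/per-trial normalization.

Bandpass filters are linear-phase FIRs designed with a Hamming window
(``scipy.signal.firwin``) and applied forward and backward in time, so the
net group delay is zero and the effective magnitude response is the squared
single-pass response.  Filter length is derived from the transition
bandwidth, which defaults to ``min(max(0.25 * edge, 2 Hz), edge)`` on each
band edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Optional

import numpy as np
from scipy import signal

from .core import Montage, TimeSeriesBlock
from .errors import FlaggedChannelError, InvalidArgumentError

__all__ = [
    "rereference",
    "fir_bandpass",
    "notch",
    "resample",
    "normalize",
    "PreprocessConfig",
    "preprocess_chain",
]

# Hamming-window FIR length multiplier (attenuation ~53 dB single-pass)
_FIR_LENGTH_FACTOR = 3.3


def rereference(eeg: TimeSeriesBlock, montage: Montage, scheme: str) -> TimeSeriesBlock:
    """Rereference a block in place of its recorded reference.

    ``common_average`` subtracts the instantaneous mean over all channels of
    the block; ``linked_L4R4`` subtracts the mean of channels L4 and R4.
    """
    out = eeg.copy()
    if scheme == "common_average":
        out.data -= out.data.mean(axis=0, keepdims=True)
    elif scheme == "linked_L4R4":
        names = eeg.channel_names or []
        missing = [c for c in ("L4", "R4") if c not in names]
        if missing:
            raise InvalidArgumentError(f"missing reference channels: {missing}")
        ref = out.data[[names.index("L4"), names.index("R4")]].mean(axis=0)
        out.data -= ref[None, :]
    else:
        raise InvalidArgumentError(f"unknown rereference scheme: {scheme!r}")
    return out


def _transition_bandwidth(edge: float, nyq: float, upper: bool) -> float:
    if upper:
        return min(max(0.25 * edge, 2.0), nyq - edge)
    return min(max(0.25 * edge, 2.0), edge)


def design_fir_bandpass(lo: float, hi: float, fs: float) -> np.ndarray:
    """Hamming-window linear-phase FIR bandpass taps (odd length)."""
    nyq = fs / 2.0
    if not (0 <= lo < hi):
        raise InvalidArgumentError(f"need 0 <= lo < hi, got ({lo}, {hi})")
    if hi > nyq:
        raise InvalidArgumentError(f"upper edge {hi} Hz exceeds Nyquist {nyq} Hz")
    trans = min(
        _transition_bandwidth(lo, nyq, upper=False) if lo > 0 else np.inf,
        _transition_bandwidth(hi, nyq, upper=True) if hi < nyq else np.inf,
    )
    if not np.isfinite(trans) or trans <= 0:
        raise InvalidArgumentError("cannot derive a transition bandwidth")
    numtaps = int(round(_FIR_LENGTH_FACTOR / trans * fs))
    numtaps += 1 - numtaps % 2  # force odd (type-I linear phase)
    numtaps = max(numtaps, 3)
    if hi >= nyq:  # pure highpass
        return signal.firwin(numtaps, lo, window="hamming", pass_zero=False, fs=fs)
    if lo <= 0:  # pure lowpass
        return signal.firwin(numtaps, hi, window="hamming", pass_zero=True, fs=fs)
    return signal.firwin(numtaps, [lo, hi], window="hamming", pass_zero=False, fs=fs)


def _zero_phase_apply(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR forward and backward (zero net group delay).

    Implemented as one convolution with the filter's autocorrelation, with
    odd (reflect-and-negate) edge extension like ``filtfilt``.
    """
    h2 = np.convolve(taps, taps[::-1])
    half = (len(h2) - 1) // 2
    n = data.shape[-1]
    pad = min(half, n - 1)
    if pad > 0:
        left = 2 * data[..., :1] - data[..., 1 : pad + 1][..., ::-1]
        right = 2 * data[..., -1:] - data[..., -pad - 1 : -1][..., ::-1]
        ext = np.concatenate([left, data, right], axis=-1)
    else:
        ext = data
    out = signal.fftconvolve(ext, h2[None, :], mode="same", axes=-1)
    return out[..., pad : pad + n] if pad > 0 else out


def fir_bandpass(x: TimeSeriesBlock, lo: float, hi: float) -> TimeSeriesBlock:
    """Zero-phase FIR bandpass between ``lo`` and ``hi`` Hz."""
    taps = design_fir_bandpass(lo, hi, x.fs)
    out = x.copy()
    out.data = _zero_phase_apply(out.data, taps)
    return out


def notch(x: TimeSeriesBlock, f0: float, quality: float = 35.0) -> TimeSeriesBlock:
    """Zero-phase IIR notch at ``f0`` Hz (line-noise removal)."""
    nyq = x.fs / 2.0
    if f0 >= nyq:
        raise InvalidArgumentError(f"notch frequency {f0} Hz >= Nyquist {nyq} Hz")
    if f0 <= 0:
        raise InvalidArgumentError("notch frequency must be positive")
    b, a = signal.iirnotch(f0, quality, fs=x.fs)
    out = x.copy()
    out.data = signal.filtfilt(b, a, out.data, axis=-1)
    return out


def resample(x: TimeSeriesBlock, fs_new: float) -> TimeSeriesBlock:
    """Polyphase anti-aliased resampling (downsampling only by default)."""
    if fs_new <= 0:
        raise InvalidArgumentError("fs_new must be positive")
    if fs_new > x.fs:
        raise InvalidArgumentError(
            f"upsampling {x.fs} -> {fs_new} Hz is outside the configured policy"
        )
    if fs_new == x.fs:
        return x.copy()
    frac = Fraction(fs_new / x.fs).limit_denominator(1000)
    data = signal.resample_poly(x.data, frac.numerator, frac.denominator,
                                axis=-1, padtype="line")
    return TimeSeriesBlock(data, fs_new,
                           list(x.channel_names) if x.channel_names else None)


def normalize(x: TimeSeriesBlock, scope: str = "per_channel_per_trial") -> TimeSeriesBlock:
    """Zero mean, unit SD per channel within the trial."""
    if scope != "per_channel_per_trial":
        raise InvalidArgumentError(f"unknown normalization scope: {scope!r}")
    out = x.copy()
    mean = out.data.mean(axis=-1, keepdims=True)
    sd = out.data.std(axis=-1, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        names = x.channel_names or [str(i) for i in range(x.n_channels)]
        raise FlaggedChannelError([names[i] for i in flat])
    out.data = (out.data - mean) / sd
    return out


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain."""

    notch_hz: float = 50.0
    broadband: tuple[float, float] = (0.1, 40.0)
    narrowband: tuple[float, float] = (1.0, 20.0)
    fs_out: float = 50.0
    scalp_reference: str = "common_average"
    ceegrid_reference: str = "linked_L4R4"
    log: list = field(default_factory=list)


_CHAIN_ORDER = [
    "rereference", "notch", "bandpass_broad", "artifact", "bandpass_narrow",
    "resample", "normalize",
]


def preprocess_chain(
    eeg: TimeSeriesBlock,
    montage: Montage,
    cfg: Optional[PreprocessConfig] = None,
    artifact_stage: Optional[Callable[[TimeSeriesBlock], TimeSeriesBlock]] = None,
) -> TimeSeriesBlock:
    """Run the full conditioning chain on one trial of raw EEG.

    Scalp and cEEGrid groups are rereferenced separately (common average
    vs. linked L4/R4) and processed in parallel with identical filters.
    ``artifact_stage`` is a pluggable slot between the two bandpass stages
    (ICA-style cleanup); it defaults to a no-op.
    """
    cfg = cfg or PreprocessConfig()
    log: list[tuple[str, dict]] = []

    def _record(stage, **params):
        if stage != _CHAIN_ORDER[len(log)]:
            raise AssertionError(
                f"stage {stage!r} out of order; expected {_CHAIN_ORDER[len(log)]!r}"
            )
        log.append((stage, params))

    scalp = eeg.pick(montage.scalp) if montage.scalp else None
    grid = eeg.pick(montage.ceegrid) if montage.ceegrid else None
    parts = []
    if scalp is not None:
        parts.append(rereference(scalp, montage, cfg.scalp_reference))
    if grid is not None:
        parts.append(rereference(grid, montage, cfg.ceegrid_reference))
    x = TimeSeriesBlock(
        np.vstack([p.data for p in parts]),
        eeg.fs,
        [c for p in parts for c in (p.channel_names or [])],
    )
    _record("rereference", scalp=cfg.scalp_reference, ceegrid=cfg.ceegrid_reference)

    x = notch(x, cfg.notch_hz)
    _record("notch", f0=cfg.notch_hz)
    x = fir_bandpass(x, *cfg.broadband)
    _record("bandpass_broad", band=cfg.broadband)
    if artifact_stage is not None:
        x = artifact_stage(x)
    _record("artifact", enabled=artifact_stage is not None)
    x = fir_bandpass(x, *cfg.narrowband)
    _record("bandpass_narrow", band=cfg.narrowband)
    x = resample(x, cfg.fs_out)
    _record("resample", fs=cfg.fs_out)
    try:
        x = normalize(x)
    except FlaggedChannelError:
        raise
    _record("normalize", scope="per_channel_per_trial")

    cfg.log = log
    return x
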