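"""Speech feature extraction: gammatone decomposition, envelope, onsets.

Audio is decomposed by a 128-band gammatone filterbank with ERB-rate band
spacing (Glasberg & Moore), each band realized as a cascade of four complex
one-pole resonators.  Band magnitudes are decimated to 1-ms resolution
(1000 Hz).  Two features are derived: the broadband *acoustic envelope*
(sum of band magnitudes) and *acoustic onsets* (per-band edge detection:
log-compressed magnitude minus a delayed low-passed copy, half-wave
rectified, summed across bands).  Either feature is finalized by
:func:`prepare_feature`: 1-20 Hz zero-phase FIR bandpass, resampling to
50 Hz, and z-scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import FeatureSignal, TimeSeriesBlock
from .errors import InvalidArgumentError
from .preprocess import design_fir_bandpass, _zero_phase_apply

__all__ = [
    "GTRepresentation",
    "erb_bandwidth",
    "erb_space",
    "gammatone_decompose",
    "acoustic_envelope",
    "acoustic_onsets",
    "prepare_feature",
]

GT_FS = 1000.0  # 1-ms resolution of the filterbank representation


@dataclass
class GTRepresentation:
    """Time x band matrix of nonnegative gammatone magnitudes."""

    values: np.ndarray  # (n_times, n_bands)
    band_centers: np.ndarray  # Hz, strictly increasing
    fs: float = GT_FS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("GT values must be 2-D (time x band)")
        if self.values.shape[1] != self.band_centers.size:
            raise InvalidArgumentError("band axis does not match band_centers")
        if np.any(np.diff(self.band_centers) <= 0):
            raise InvalidArgumentError("band centers must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return self.band_centers.size

    @property
    def n_times(self) -> int:
        return self.values.shape[0]


def erb_bandwidth(f: np.ndarray) -> np.ndarray:
    """Equivalent rectangular bandwidth at frequency ``f`` (Glasberg-Moore)."""
    f = np.asarray(f, dtype=float)
    return 24.7 * (4.37 * f / 1000.0 + 1.0)


def _erb_rate(f):
    return 21.4 * np.log10(1.0 + 4.37 * np.asarray(f, dtype=float) / 1000.0)


def _erb_rate_inv(r):
    return (10.0 ** (np.asarray(r, dtype=float) / 21.4) - 1.0) * 1000.0 / 4.37


def erb_space(fmin: float, fmax: float, n: int) -> np.ndarray:
    """``n`` center frequencies equally spaced on the ERB-rate scale."""
    return _erb_rate_inv(np.linspace(_erb_rate(fmin), _erb_rate(fmax), n))


def _gammatone_band(x: np.ndarray, fc: float, fs: float, order: int = 4) -> np.ndarray:
    """Magnitude output of one 4th-order complex gammatone band."""
    bw = 1.019 * erb_bandwidth(fc)
    pole = np.exp(-2.0 * np.pi * bw / fs) * np.exp(2j * np.pi * fc / fs)
    # unit gain at fc for the whole cascade
    z0 = np.exp(2j * np.pi * fc / fs)
    gain = abs(1.0 - pole / z0) ** order
    y = x.astype(complex)
    for _ in range(order):
        y = signal.lfilter([1.0], [1.0, -pole], y)
    return gain * np.abs(y)


def gammatone_decompose(
    audio: TimeSeriesBlock | FeatureSignal,
    n_bands: int = 128,
    fmin: float = 80.0,
    fmax: float = 15000.0,
) -> GTRepresentation:
    """Decompose mono audio into an ERB-spaced gammatone magnitude matrix.

    Multi-channel audio is mixed down by averaging.  If ``fmax`` exceeds the
    Nyquist frequency it is clipped (with a warning).  Output is decimated
    to 1000 Hz.
    """
    if isinstance(audio, FeatureSignal):
        audio = audio.as_block()
    if audio.n_samples == 0:
        raise InvalidArgumentError("empty audio")
    x = audio.data.mean(axis=0)
    fs = audio.fs
    nyq = fs / 2.0
    if fmax > nyq:
        warnings.warn(
            f"fmax {fmax} Hz above Nyquist {nyq} Hz; clipping", stacklevel=2
        )
        fmax = 0.95 * nyq
    if fmin <= 0 or fmin >= fmax:
        raise InvalidArgumentError(f"need 0 < fmin < fmax, got ({fmin}, {fmax})")
    centers = erb_space(fmin, fmax, n_bands)

    frac = Fraction(GT_FS / fs).limit_denominator(10000)
    bands = []
    for fc in centers:
        mag = _gammatone_band(x, fc, fs)
        if fs != GT_FS:
            mag = signal.resample_poly(mag, frac.numerator, frac.denominator,
                                       padtype="line")
        bands.append(np.maximum(mag, 0.0))
    return GTRepresentation(np.column_stack(bands), centers, GT_FS)


def acoustic_envelope(gt: GTRepresentation) -> FeatureSignal:
    """Broadband envelope: sum of absolute GT magnitudes across bands."""
    values = np.abs(gt.values).sum(axis=1)
    return FeatureSignal(values, gt.fs, name="envelope")


def acoustic_onsets(
    gt: GTRepresentation,
    delay: float = 10.0,
    compression: str = "log",
    lowpass_hz: float = 30.0,
    compression_gain: float = 100.0,
) -> FeatureSignal:
    """Acoustic-edge onset feature.

    Per band: compress the magnitude (``log(1 + k x)`` by default), subtract
    a ``delay``-ms-delayed low-passed copy, half-wave rectify; sum across
    bands.  The causal comparison path guarantees the onset response never
    lags behind the underlying edge by more than the delay + filter memory.
    """
    if delay <= 0:
        raise InvalidArgumentError("delay must be positive (ms)")
    if compression == "log":
        z = np.log1p(compression_gain * np.abs(gt.values))
    elif compression == "none":
        z = np.abs(gt.values)
    else:
        raise InvalidArgumentError(f"unknown compression: {compression!r}")
    d = int(round(delay * gt.fs / 1000.0))
    if d < 1:
        raise InvalidArgumentError("delay shorter than one sample")
    delayed = np.zeros_like(z)
    delayed[d:] = z[:-d]
    b, a = signal.butter(2, lowpass_hz, fs=gt.fs)
    smooth = signal.lfilter(b, a, delayed, axis=0)
    edges = np.maximum(z - smooth, 0.0)
    return FeatureSignal(edges.sum(axis=1), gt.fs, name="onset")


def prepare_feature(
    f: FeatureSignal,
    band: tuple[float, float] = (1.0, 20.0),
    fs_out: float = 50.0,
) -> FeatureSignal:
    """Bandpass 1-20 Hz (zero-phase FIR), resample to 50 Hz, z-score."""
    if f.fs < fs_out:
        raise InvalidArgumentError(
            f"input rate {f.fs} Hz below output rate {fs_out} Hz"
        )
    taps = design_fir_bandpass(band[0], band[1], f.fs)
    x = _zero_phase_apply(f.values[None, :], taps)[0]
    if f.fs != fs_out:
        frac = Fraction(fs_out / f.fs).limit_denominator(10000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator, padtype="line")
    sd = x.std()
    if sd == 0:
        raise InvalidArgumentError("feature has zero variance after filtering")
    x = (x - x.mean()) / sd
    return FeatureSignal(x, fs_out, name=f.name, normalized=True)
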