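"""Core data containers shared by every stage of the pipeline.

The whole package passes around a small set of plain dataclasses wrapping
numpy arrays: :class:`TimeSeriesBlock` for multichannel signals,
:class:`FeatureSignal` for single-channel stimulus features,
:class:`TRFKernel` for estimated (or ground-truth) response functions, and
:class:`Trial` / :class:`Session` for the experimental structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "Condition",
    "TimeSeriesBlock",
    "FeatureSignal",
    "Montage",
    "BasisSet",
    "TRFKernel",
    "Trial",
    "Session",
]


class Condition(str, Enum):
    """The three listening conditions."""

    SustAC = "SustAC"
    SwitAC = "SwitAC"
    ConvAC = "ConvAC"

    @classmethod
    def parse(cls, value) -> "Condition":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise InvalidArgumentError(f"unknown condition: {value!r}") from None


@dataclass
class TimeSeriesBlock:
    """Uniformly sampled multichannel signal.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    channel_names
        Optional channel labels, one per row of ``data``.
    """

    data: np.ndarray
    fs: float
    channel_names: Optional[list[str]] = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise InvalidArgumentError(f"fs must be positive, got {self.fs}")
        if self.channel_names is not None:
            self.channel_names = [str(c) for c in self.channel_names]
            if len(self.channel_names) != self.data.shape[0]:
                raise InvalidArgumentError(
                    f"{len(self.channel_names)} channel names for "
                    f"{self.data.shape[0]} channels"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "TimeSeriesBlock":
        return TimeSeriesBlock(
            self.data.copy(),
            self.fs,
            list(self.channel_names) if self.channel_names else None,
        )

    def pick(self, names: Sequence[str]) -> "TimeSeriesBlock":
        """Return a new block restricted to the named channels (in order)."""
        if self.channel_names is None:
            raise InvalidArgumentError("block has no channel names to pick from")
        idx = []
        for name in names:
            try:
                idx.append(self.channel_names.index(name))
            except ValueError:
                raise InvalidArgumentError(f"channel {name!r} not present") from None
        return TimeSeriesBlock(self.data[idx].copy(), self.fs, list(names))


@dataclass
class FeatureSignal:
    """Single-channel stimulus feature (envelope or onsets)."""

    values: np.ndarray
    fs: float
    name: str = "envelope"
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.fs <= 0:
            raise InvalidArgumentError(f"fs must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def as_block(self) -> TimeSeriesBlock:
        return TimeSeriesBlock(self.values[None, :], self.fs, [self.name])

    def copy(self) -> "FeatureSignal":
        return FeatureSignal(self.values.copy(), self.fs, self.name, self.normalized)


# canonical 44-channel scalp layout used by the synthetic montage
SCALP_44 = [
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P7", "P3", "Pz", "P4", "P8", "PO3", "POz", "PO4",
    "O1", "Oz", "O2", "Iz",
]
CEEGRID_20 = [f"L{i}" for i in range(1, 11)] + [f"R{i}" for i in range(1, 11)]


@dataclass
class Montage:
    """Channel labels split into scalp and around-the-ear (cEEGrid) groups."""

    scalp: list[str]
    ceegrid: list[str]

    def __post_init__(self):
        overlap = set(self.scalp) & set(self.ceegrid)
        if overlap:
            raise InvalidArgumentError(f"groups overlap: {sorted(overlap)}")

    @property
    def channels(self) -> list[str]:
        return list(self.scalp) + list(self.ceegrid)

    @property
    def n_channels(self) -> int:
        return len(self.scalp) + len(self.ceegrid)

    def group(self, name: str) -> list[str]:
        if name == "scalp":
            return list(self.scalp)
        if name == "ceegrid":
            return list(self.ceegrid)
        raise InvalidArgumentError(f"unknown montage group: {name!r}")

    @classmethod
    def default(cls, n_scalp: int = 44, n_ceegrid: int = 20) -> "Montage":
        if n_scalp <= len(SCALP_44):
            scalp = SCALP_44[:n_scalp]
        else:
            scalp = SCALP_44 + [f"EEG{i}" for i in range(n_scalp - len(SCALP_44))]
        n_per_ear = (n_ceegrid + 1) // 2
        ceegrid = [f"L{i}" for i in range(1, n_per_ear + 1)]
        ceegrid += [f"R{i}" for i in range(1, n_ceegrid - n_per_ear + 1)]
        return cls(scalp, ceegrid)

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "Montage":
        """Split arbitrary labels: L1-L10 / R1-R10 go to cEEGrid, rest to scalp."""
        ceegrid_names = set(CEEGRID_20)
        ceegrid = [c for c in labels if c in ceegrid_names]
        scalp = [c for c in labels if c not in ceegrid_names]
        return cls(scalp, ceegrid)


@dataclass
class BasisSet:
    """Hamming-window basis parameterizing a TRF over its lag grid.

    ``matrix`` has shape ``(n_lags, n_functions)``; a kernel with basis
    weights ``w`` has coefficients ``matrix @ w``.
    """

    matrix: np.ndarray
    width_ms: float
    spacing_ms: float
    fs: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)

    @property
    def n_lags(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_functions(self) -> int:
        return self.matrix.shape[1]

    def reconstruct(self, weights: np.ndarray) -> np.ndarray:
        """Kernel coefficients from basis weights (lags first axis)."""
        return self.matrix @ weights


@dataclass
class TRFKernel:
    """Temporal response function over a uniform lag grid.

    ``coefs`` has shape ``(n_lags, n_channels)``.  For ``direction ==
    'forward'`` the channel axis indexes predicted EEG channels; for
    ``'backward'`` it indexes the EEG input channels.
    """

    coefs: np.ndarray
    lags: np.ndarray
    fs: float
    direction: str = "forward"
    basis: Optional[BasisSet] = None
    weights: Optional[np.ndarray] = None
    channel_names: Optional[list[str]] = None

    def __post_init__(self):
        self.coefs = np.atleast_2d(np.asarray(self.coefs, dtype=float))
        if self.coefs.ndim == 1:
            self.coefs = self.coefs[:, None]
        self.lags = np.asarray(self.lags, dtype=float).ravel()
        if self.coefs.shape[0] != self.lags.size:
            raise InvalidArgumentError(
                f"coefs first axis ({self.coefs.shape[0]}) must match lag grid "
                f"({self.lags.size})"
            )
        if self.direction not in ("forward", "backward"):
            raise InvalidArgumentError(f"bad direction: {self.direction!r}")
        if self.lags.size > 1:
            steps = np.diff(self.lags)
            if not np.allclose(steps, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
                raise InvalidArgumentError("lag grid must be uniform at 1/fs spacing")

    @property
    def n_lags(self) -> int:
        return self.lags.size

    @property
    def n_channels(self) -> int:
        return self.coefs.shape[1]

    @property
    def lag_samples(self) -> np.ndarray:
        return np.round(self.lags * self.fs).astype(int)

    def channel_average(self) -> np.ndarray:
        return self.coefs.mean(axis=1)

    def copy(self) -> "TRFKernel":
        return replace(
            self,
            coefs=self.coefs.copy(),
            lags=self.lags.copy(),
            weights=None if self.weights is None else self.weights.copy(),
        )


@dataclass
class Trial:
    """One 180-s presentation: condition, stimulus streams, schedule, EEG.

    ``schedule`` is a list of ``(start_s, end_s, stream_id)`` segments that
    tile ``[0, duration]``; the named stream is the attended one during the
    segment.
    """

    condition: Condition
    streams: dict[str, FeatureSignal]
    schedule: list[tuple[float, float, str]]
    eeg: TimeSeriesBlock

    def __post_init__(self):
        self.condition = Condition.parse(self.condition)
        sched = sorted(self.schedule, key=lambda seg: seg[0])
        for (a0, a1, _), (b0, _, _) in zip(sched, sched[1:]):
            if b0 < a1 - 1e-9:
                raise InvalidArgumentError("schedule segments overlap")
        self.schedule = [(float(s), float(e), str(i)) for s, e, i in sched]

    @property
    def duration(self) -> float:
        return self.eeg.duration

    @property
    def switch_times(self) -> list[float]:
        return [seg[0] for seg in self.schedule[1:]]

    def attended_stream_at(self, t: float) -> str:
        for start, end, stream in self.schedule:
            if start - 1e-9 <= t < end + 1e-9:
                return stream
        raise InvalidArgumentError(f"time {t} outside schedule")

    def competing_streams(self) -> list[str]:
        """Stream ids that can carry attention (everything except control)."""
        return [s for s in self.streams if s != "control"]


@dataclass
class Session:
    """Ordered trials for one (synthetic) subject plus the montage."""

    trials: list[Trial]
    montage: Montage
    subject: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def by_condition(self, condition) -> list[int]:
        condition = Condition.parse(condition)
        return [i for i, t in enumerate(self.trials) if t.condition == condition]

    @property
    def conditions(self) -> list[Condition]:
        seen = []
        for t in self.trials:
            if t.condition not in seen:
                seen.append(t.condition)
        return seen
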