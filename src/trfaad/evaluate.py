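"""Attention-tracking evaluation.

Everything here operates on *prepared* sessions (EEG and stimulus features
at the 50-Hz analysis rate, normalized; see ``pipeline.prepare_session``).
Backward models are fitted per leave-one-trial-out fold on the schedule-
stitched attended feature, reconstructions are correlated with the
attended / ignored / control streams over decision windows, and attention
is classified by comparing the two correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Condition, FeatureSignal, Session, TimeSeriesBlock, Trial, TRFKernel
from .errors import InvalidArgumentError
from .trf import (
    BoostingConfig,
    boosting_fit,
    make_basis,
    make_lag_grid,
    pearson_r,
    predict_forward,
    reconstruct_backward,
)

__all__ = [
    "TRFSettings",
    "FoldPlan",
    "SegmentScore",
    "EvalResult",
    "LagScanResult",
    "make_folds",
    "attended_signal",
    "fit_backward",
    "fit_forward",
    "score_reconstruction",
    "classify_attention",
    "decision_window_curve",
    "optimal_lag_scan",
    "cross_condition_eval",
    "DEFAULT_WINDOW_GRID",
]

# geometric doubling from 1.1 s to 35 s plus the full-trial window
DEFAULT_WINDOW_GRID = (1.1, 2.2, 4.4, 8.8, 17.5, 35.0, 178.0)


@dataclass
class TRFSettings:
    """Lag range, basis and boosting settings used for model fitting."""

    lag_range: tuple[float, float] = (-1.0, 1.0)
    basis_width_ms: float = 50.0
    boosting: BoostingConfig = field(default_factory=BoostingConfig)


@dataclass
class FoldPlan:
    """Leave-one-trial-out folds: ``(train_ids, test_id)`` per fold."""

    folds: list[tuple[tuple[int, ...], int]]
    condition: Condition

    def __post_init__(self):
        seen = set()
        for train, test in self.folds:
            if test in train:
                raise InvalidArgumentError("train/test overlap in fold plan")
            if test in seen:
                raise InvalidArgumentError("trial is test in more than one fold")
            seen.add(test)

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


@dataclass
class SegmentScore:
    trial: int
    start: float
    end: float
    rho_att: float
    rho_ign: float
    rho_ctl: float

    @property
    def correct(self) -> bool:
        # exact ties are scored incorrect (conservative)
        return self.rho_att > self.rho_ign


@dataclass
class EvalResult:
    """Per-segment correlations and decisions plus aggregate accuracy."""

    scores: list[SegmentScore]
    condition: Optional[Condition] = None
    window_s: Optional[float] = None
    subject: str = ""

    @property
    def decisions(self) -> np.ndarray:
        return np.array([s.correct for s in self.scores], dtype=bool)

    @property
    def accuracy(self) -> float:
        if not self.scores:
            return float("nan")
        return float(self.decisions.mean())

    @property
    def n_decisions(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": self.subject,
                "condition": getattr(self.condition, "value", self.condition),
                "window_s": self.window_s,
                "trial": s.trial,
                "segment_start_s": s.start,
                "rho_att": s.rho_att,
                "rho_ign": s.rho_ign,
                "rho_ctl": s.rho_ctl,
                "correct": s.correct,
            }
            for s in self.scores
        ]
        return pd.DataFrame(rows)


@dataclass
class LagScanResult:
    """Sliding-lag-window scan output."""

    centers_ms: np.ndarray
    table: pd.DataFrame  # columns: center_ms, direction, montage, role, rho

    def argmax_center(self, direction: str, montage: str, role: str = "attended") -> float:
        sel = self.table[
            (self.table.direction == direction)
            & (self.table.montage == montage)
            & (self.table.role == role)
        ]
        if sel.empty:
            raise InvalidArgumentError("no scan entries for that selection")
        return float(sel.loc[sel.rho.idxmax(), "center_ms"])


# ---------------------------------------------------------------------------
# folds and stitched features

def make_folds(session: Session, condition) -> FoldPlan:
    """Leave-one-trial-out fold plan for one condition."""
    condition = Condition.parse(condition)
    ids = session.by_condition(condition)
    if len(ids) < 2:
        raise InvalidArgumentError(
            f"need >= 2 trials in {condition.value}, got {len(ids)}"
        )
    folds = [(tuple(t for t in ids if t != test), test) for test in ids]
    return FoldPlan(folds, condition)


def _role_stream(trial: Trial, role: str, t: float) -> str:
    att = trial.attended_stream_at(t)
    if role == "attended":
        return att
    if role == "ignored":
        others = [s for s in trial.competing_streams() if s != att]
        if len(others) != 1:
            raise InvalidArgumentError("ambiguous ignored stream")
        return others[0]
    if role == "control":
        return "control"
    raise InvalidArgumentError(f"unknown role: {role!r}")


def attended_signal(trial: Trial, role: str = "attended") -> FeatureSignal:
    """Schedule-stitched feature signal for a stream role.

    For 'attended' the stream named in each schedule segment is used; for
    'ignored' the competing (non-control) stream; 'control' returns the
    control stream unchanged.
    """
    ref = next(iter(trial.streams.values()))
    fs = ref.fs
    n = ref.n_samples
    out = np.empty(n)
    for start, end, _ in trial.schedule:
        a = int(round(start * fs))
        b = min(int(round(end * fs)), n)
        stream = _role_stream(trial, role, (start + end) / 2.0)
        out[a:b] = trial.streams[stream].values[a:b]
    return FeatureSignal(out, fs, name=ref.name, normalized=ref.normalized)


# ---------------------------------------------------------------------------
# fitting

def _concat_training(
    session: Session, trial_ids: Sequence[int], channels: Optional[Sequence[str]]
) -> tuple[TimeSeriesBlock, FeatureSignal, FeatureSignal]:
    eegs, att, ign = [], [], []
    for tid in trial_ids:
        trial = session.trials[tid]
        eeg = trial.eeg if channels is None else trial.eeg.pick(channels)
        eegs.append(eeg.data)
        att.append(attended_signal(trial, "attended").values)
        ign.append(attended_signal(trial, "ignored").values)
    fs = session.trials[trial_ids[0]].eeg.fs
    names = channels if channels is not None else session.trials[trial_ids[0]].eeg.channel_names
    block = TimeSeriesBlock(np.concatenate(eegs, axis=1), fs,
                            list(names) if names else None)
    return (
        block,
        FeatureSignal(np.concatenate(att), fs, name="attended"),
        FeatureSignal(np.concatenate(ign), fs, name="ignored"),
    )


def fit_backward(
    session: Session,
    trial_ids: Sequence[int],
    settings: Optional[TRFSettings] = None,
    channels: Optional[Sequence[str]] = None,
    role: str = "attended",
) -> TRFKernel:
    """Fit a backward (EEG -> feature) model on the given trials."""
    settings = settings or TRFSettings()
    eeg, att, ign = _concat_training(session, trial_ids, channels)
    target = att if role == "attended" else ign
    fs = eeg.fs
    basis = make_basis(
        make_lag_grid(settings.lag_range, fs).size, settings.basis_width_ms, fs=fs
    )
    return boosting_fit(
        eeg, target.as_block(), settings.lag_range, basis, settings.boosting,
        direction="backward",
    )


def fit_forward(
    session: Session,
    trial_ids: Sequence[int],
    settings: Optional[TRFSettings] = None,
    channels: Optional[Sequence[str]] = None,
    role: str = "attended",
) -> TRFKernel:
    """Fit a forward (feature -> EEG) model on the given trials."""
    settings = settings or TRFSettings()
    eeg, att, ign = _concat_training(session, trial_ids, channels)
    feature = att if role == "attended" else ign
    fs = eeg.fs
    basis = make_basis(
        make_lag_grid(settings.lag_range, fs).size, settings.basis_width_ms, fs=fs
    )
    return boosting_fit(
        feature.as_block(), eeg, settings.lag_range, basis, settings.boosting,
        direction="forward",
    )


# ---------------------------------------------------------------------------
# scoring and classification

def _segment_bounds(trial: Trial, window: float) -> list[tuple[float, float]]:
    duration = trial.duration
    if window > duration + 1e-9:
        raise InvalidArgumentError(
            f"window {window} s exceeds trial duration {duration} s"
        )
    n_seg = int(np.floor(duration / window + 1e-9))
    bounds = [(i * window, (i + 1) * window) for i in range(n_seg)]
    switches = trial.switch_times
    if switches:
        bounds = [
            (a, b)
            for a, b in bounds
            if not any(a + 1e-9 < sw < b - 1e-9 for sw in switches)
        ]
    return bounds


def _segment_scores(
    xhat: FeatureSignal, trial: Trial, window: float, trial_id: int = -1
) -> list[SegmentScore]:
    fs = xhat.fs
    scores = []
    for start, end in _segment_bounds(trial, window):
        a, b = int(round(start * fs)), int(round(end * fs))
        seg = xhat.values[a:b]
        rhos = {}
        for role in ("attended", "ignored", "control"):
            ref = attended_signal(trial, role).values[a:b]
            rhos[role] = pearson_r(seg, ref)
        scores.append(
            SegmentScore(trial_id, start, end,
                         rhos["attended"], rhos["ignored"], rhos["control"])
        )
    return scores


def score_reconstruction(
    kernel: TRFKernel,
    trial: Trial,
    window: float,
    channels: Optional[Sequence[str]] = None,
    trial_id: int = -1,
) -> list[SegmentScore]:
    """Per-segment correlations of the reconstruction with each stream.

    The trial is split into consecutive non-overlapping ``window``-second
    segments; SwitAC segments straddling an attention switch are excluded.
    """
    eeg = trial.eeg if channels is None else trial.eeg.pick(channels)
    xhat = reconstruct_backward(kernel, eeg)
    return _segment_scores(xhat, trial, window, trial_id)


def classify_attention(scores: Sequence[SegmentScore], **meta) -> EvalResult:
    """Decision per segment: attended iff rho_att > rho_ign (ties incorrect)."""
    if not scores:
        raise InvalidArgumentError("no segment scores to classify")
    return EvalResult(list(scores), **meta)


def decision_window_curve(
    session: Session,
    condition,
    lengths: Optional[Sequence[float]] = None,
    settings: Optional[TRFSettings] = None,
    channels: Optional[Sequence[str]] = None,
) -> dict[float, EvalResult]:
    """Classification accuracy per decision-window length (one CV pass).

    Kernels are fitted once per leave-one-trial-out fold; each held-out
    trial is reconstructed once and segmented at every requested length.
    The 178-s window is dropped automatically for SwitAC (attention is not
    sustained that long).
    """
    condition = Condition.parse(condition)
    lengths = list(lengths if lengths is not None else DEFAULT_WINDOW_GRID)
    if condition == Condition.SwitAC:
        dropped = [w for w in lengths if w >= 178.0]
        if dropped:
            import logging

            logging.getLogger(__name__).info(
                "dropping %s-s windows for SwitAC (attention not sustained)", dropped
            )
        lengths = [w for w in lengths if w < 178.0]
    folds = make_folds(session, condition)
    settings = settings or TRFSettings()

    per_fold: list[tuple[int, FeatureSignal]] = []
    for train_ids, test_id in folds:
        kernel = fit_backward(session, train_ids, settings, channels)
        trial = session.trials[test_id]
        eeg = trial.eeg if channels is None else trial.eeg.pick(channels)
        per_fold.append((test_id, reconstruct_backward(kernel, eeg)))

    out: dict[float, EvalResult] = {}
    for window in lengths:
        scores: list[SegmentScore] = []
        for test_id, xhat in per_fold:
            trial = session.trials[test_id]
            if window > trial.duration + 1e-9:
                continue
            scores.extend(_segment_scores(xhat, trial, window, test_id))
        if scores:
            out[window] = EvalResult(scores, condition=condition, window_s=window,
                                     subject=session.subject)
    return out


def optimal_lag_scan(
    session: Session,
    condition,
    settings: Optional[TRFSettings] = None,
    directions: Sequence[str] = ("backward", "forward"),
    montages: Sequence[str] = ("scalp", "ceegrid"),
    roles: Sequence[str] = ("attended", "ignored"),
    window_length: float = 0.045,
    step: float = 0.015,
    lag_min: float = -0.600,
    lag_max: float = 0.600,
) -> LagScanResult:
    """Sliding short-lag-window TRF scan (45-ms windows, 15-ms steps).

    For every window a fresh model is fitted per CV fold using only the
    lags inside the window; fold-averaged correlations are recorded per
    direction, montage group and stream role.  Forward correlations are
    additionally averaged across electrodes, giving one estimate per
    window.
    """
    condition = Condition.parse(condition)
    settings = settings or TRFSettings()
    folds = make_folds(session, condition)

    starts = []
    s = lag_min
    while s + window_length <= lag_max + 1e-9:
        starts.append(round(s, 6))
        s += step
    centers = np.array([st + window_length / 2.0 for st in starts]) * 1000.0

    rows = []
    for montage_name in montages:
        channels = session.montage.group(montage_name)
        if not channels:
            continue
        for start in starts:
            lag_range = (start, start + window_length)
            win_settings = TRFSettings(
                lag_range=lag_range,
                basis_width_ms=settings.basis_width_ms,
                boosting=settings.boosting,
            )
            for direction in directions:
                for role in roles:
                    rhos = []
                    for train_ids, test_id in folds:
                        trial = session.trials[test_id]
                        eeg = trial.eeg.pick(channels)
                        ref = attended_signal(trial, role)
                        if direction == "backward":
                            kern = fit_backward(session, train_ids, win_settings,
                                                channels, role=role)
                            xhat = reconstruct_backward(kern, eeg)
                            # an all-zero kernel carries no information
                            rhos.append(
                                0.0 if xhat.values.std() == 0
                                else pearson_r(xhat.values, ref.values)
                            )
                        else:
                            kern = fit_forward(session, train_ids, win_settings,
                                               channels, role=role)
                            pred = predict_forward(kern, ref)
                            ch_rhos = []
                            for i in range(eeg.n_channels):
                                if pred.data[i].std() == 0:
                                    ch_rhos.append(0.0)
                                else:
                                    ch_rhos.append(
                                        pearson_r(pred.data[i], eeg.data[i])
                                    )
                            rhos.append(float(np.mean(ch_rhos)))
                    rows.append(
                        {
                            "center_ms": float(start * 1000.0 + window_length * 500.0),
                            "direction": direction,
                            "montage": montage_name,
                            "role": role,
                            "rho": float(np.mean(rhos)),
                        }
                    )
    return LagScanResult(centers, pd.DataFrame(rows))


def cross_condition_eval(
    sessions: Session | Sequence[Session],
    train_cond,
    test_cond,
    window: float = 35.0,
    settings: Optional[TRFSettings] = None,
    channels: Optional[Sequence[str]] = None,
) -> dict:
    """Accuracy of models trained on one condition and tested on another.

    ``train_cond == test_cond`` falls back to within-condition
    leave-one-trial-out CV.  With several sessions the mean accuracy and
    10th/90th percentiles across subjects are reported.
    """
    train_cond = Condition.parse(train_cond)
    test_cond = Condition.parse(test_cond)
    if isinstance(sessions, Session):
        sessions = [sessions]
    settings = settings or TRFSettings()

    accuracies = []
    for session in sessions:
        if train_cond == test_cond:
            curve = decision_window_curve(
                session, train_cond, [window], settings, channels
            )
            accuracies.append(curve[window].accuracy)
            continue
        train_ids = session.by_condition(train_cond)
        test_ids = session.by_condition(test_cond)
        if not train_ids or not test_ids:
            raise InvalidArgumentError("both conditions must be present")
        kernel = fit_backward(session, train_ids, settings, channels)
        scores: list[SegmentScore] = []
        for tid in test_ids:
            scores.extend(
                score_reconstruction(kernel, session.trials[tid], window,
                                     channels, trial_id=tid)
            )
        accuracies.append(EvalResult(scores).accuracy)

    acc = np.asarray(accuracies, dtype=float)
    return {
        "train": train_cond.value,
        "test": test_cond.value,
        "window_s": window,
        "accuracy": float(acc.mean()),
        "p10": float(np.percentile(acc, 10)),
        "p90": float(np.percentile(acc, 90)),
        "per_subject": acc.tolist(),
    }
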