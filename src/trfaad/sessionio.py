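"""File I/O: HDF5 session containers, EDF EEG, WAV audio, CSV results.

The session container layout::

    /meta            attrs: subject, fs, extra metadata (JSON)
    /montage         attrs: scalp, ceegrid (label lists)
    /trial_000 ...   attrs: condition
        eeg          dataset (n_channels, n_samples), attrs: fs, channels
        streams/<name>   dataset (n_samples,), attrs: fs, name, normalized
        schedule     dataset (n_segments,) compound-ish: starts, ends, ids

EDF support is a minimal pure-Python reader/writer for the classic
16-bit-integer European Data Format, sufficient for round-tripping
multichannel EEG.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .core import Condition, FeatureSignal, Montage, Session, TimeSeriesBlock, Trial
from .errors import FormatError, InvalidArgumentError

__all__ = [
    "save_session",
    "load_session",
    "save_kernel",
    "load_kernel",
    "write_wav",
    "read_wav",
    "write_edf",
    "read_edf",
    "feature_to_csv",
]


# ---------------------------------------------------------------------------
# HDF5 session container

def save_session(session: Session, path) -> None:
    """Write a session to an HDF5 container (lossless round trip)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["subject"] = session.subject
        meta.attrs["extra"] = json.dumps(session.meta, default=float)
        mont = f.create_group("montage")
        mont.attrs["scalp"] = json.dumps(session.montage.scalp)
        mont.attrs["ceegrid"] = json.dumps(session.montage.ceegrid)
        for i, trial in enumerate(session.trials):
            g = f.create_group(f"trial_{i:03d}")
            g.attrs["condition"] = trial.condition.value
            eeg = g.create_dataset("eeg", data=trial.eeg.data)
            eeg.attrs["fs"] = trial.eeg.fs
            eeg.attrs["channels"] = json.dumps(trial.eeg.channel_names or [])
            streams = g.create_group("streams")
            for name, feat in trial.streams.items():
                d = streams.create_dataset(name, data=feat.values)
                d.attrs["fs"] = feat.fs
                d.attrs["name"] = feat.name
                d.attrs["normalized"] = feat.normalized
            sched = g.create_group("schedule")
            sched.create_dataset(
                "starts", data=np.array([s[0] for s in trial.schedule])
            )
            sched.create_dataset("ends", data=np.array([s[1] for s in trial.schedule]))
            sched.attrs["streams"] = json.dumps([s[2] for s in trial.schedule])


def load_session(path) -> Session:
    """Load a session container; raises :class:`FormatError` when malformed."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such container: {path}")
    with h5py.File(path, "r") as f:
        for group in ("meta", "montage"):
            if group not in f:
                raise FormatError(f"missing group /{group}")
        montage = Montage(
            json.loads(f["montage"].attrs["scalp"]),
            json.loads(f["montage"].attrs["ceegrid"]),
        )
        trials = []
        names = sorted(k for k in f.keys() if k.startswith("trial_"))
        for key in names:
            g = f[key]
            for sub in ("eeg", "streams", "schedule"):
                if sub not in g:
                    raise FormatError(f"missing group /{key}/{sub}")
            eeg_ds = g["eeg"]
            eeg = TimeSeriesBlock(
                eeg_ds[()],
                float(eeg_ds.attrs["fs"]),
                json.loads(eeg_ds.attrs["channels"]) or None,
            )
            streams = {}
            for name, ds in g["streams"].items():
                streams[name] = FeatureSignal(
                    ds[()], float(ds.attrs["fs"]), str(ds.attrs["name"]),
                    bool(ds.attrs["normalized"]),
                )
            starts = g["schedule"]["starts"][()]
            ends = g["schedule"]["ends"][()]
            ids = json.loads(g["schedule"].attrs["streams"])
            schedule = list(zip(starts.tolist(), ends.tolist(), ids))
            trials.append(
                Trial(
                    condition=Condition.parse(g.attrs["condition"]),
                    streams=streams,
                    schedule=schedule,
                    eeg=eeg,
                )
            )
        return Session(
            trials=trials,
            montage=montage,
            subject=str(f["meta"].attrs["subject"]),
            meta=json.loads(f["meta"].attrs["extra"]),
        )


# ---------------------------------------------------------------------------
# TRF kernel container

def save_kernel(kernel, path, fit_log: dict | None = None) -> None:
    """Serialize a TRF kernel (coefficients, lag grid, basis meta, fit log)."""
    from .core import TRFKernel  # noqa: F401 - documented return type

    with h5py.File(path, "w") as f:
        f.create_dataset("coefs", data=kernel.coefs)
        f.create_dataset("lags", data=kernel.lags)
        f.attrs["fs"] = kernel.fs
        f.attrs["direction"] = kernel.direction
        f.attrs["channels"] = json.dumps(kernel.channel_names or [])
        f.attrs["fit_log"] = json.dumps(fit_log or {}, default=float)
        if kernel.basis is not None:
            g = f.create_group("basis")
            g.create_dataset("matrix", data=kernel.basis.matrix)
            g.attrs["width_ms"] = kernel.basis.width_ms
            g.attrs["spacing_ms"] = kernel.basis.spacing_ms
            g.attrs["fs"] = kernel.basis.fs
        if kernel.weights is not None:
            f.create_dataset("weights", data=kernel.weights)


def load_kernel(path):
    """Load a kernel written by :func:`save_kernel`."""
    from .core import BasisSet, TRFKernel

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such kernel container: {path}")
    with h5py.File(path, "r") as f:
        for key in ("coefs", "lags"):
            if key not in f:
                raise FormatError(f"missing dataset /{key}")
        basis = None
        if "basis" in f:
            g = f["basis"]
            basis = BasisSet(
                g["matrix"][()], float(g.attrs["width_ms"]),
                float(g.attrs["spacing_ms"]), float(g.attrs["fs"]),
            )
        return TRFKernel(
            coefs=f["coefs"][()],
            lags=f["lags"][()],
            fs=float(f.attrs["fs"]),
            direction=str(f.attrs["direction"]),
            basis=basis,
            weights=f["weights"][()] if "weights" in f else None,
            channel_names=json.loads(f.attrs["channels"]) or None,
        )


# ---------------------------------------------------------------------------
# WAV audio

def write_wav(block: TimeSeriesBlock, path, dtype: str = "float32") -> None:
    """Write audio as WAV (PCM 16-bit or float32)."""
    from scipy.io import wavfile

    data = block.data.T.squeeze()
    if dtype == "float32":
        wavfile.write(path, int(block.fs), data.astype(np.float32))
    elif dtype == "int16":
        peak = np.abs(data).max() or 1.0
        scaled = np.clip(data / peak, -1, 1) * 32767
        wavfile.write(path, int(block.fs), scaled.astype(np.int16))
    else:
        raise InvalidArgumentError(f"unsupported WAV dtype: {dtype!r}")


def read_wav(path, mixdown: bool = True) -> TimeSeriesBlock:
    """Read a WAV file; integer PCM is rescaled to [-1, 1]."""
    from scipy.io import wavfile

    fs, raw = wavfile.read(path)
    data = np.atleast_2d(np.asarray(raw).T.astype(float))
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        info = np.iinfo(np.asarray(raw).dtype)
        data = data / max(abs(info.min), info.max)
    if mixdown and data.shape[0] > 1:
        data = data.mean(axis=0, keepdims=True)
    return TimeSeriesBlock(data, float(fs), None)


# ---------------------------------------------------------------------------
# EDF (classic, 16-bit)

def _pad(text: str, width: int) -> bytes:
    return text.encode("ascii")[:width].ljust(width)


def write_edf(block: TimeSeriesBlock, path, patient: str = "X",
              recording: str = "trfaad") -> None:
    """Write a multichannel block as a classic EDF file.

    One data record per second; physical ranges are set per channel from
    the data, digital range is the full signed 16-bit span.
    """
    fs = block.fs
    if abs(fs - round(fs)) > 1e-9:
        raise InvalidArgumentError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = block.n_channels
    n_records = int(np.ceil(block.n_samples / fs))
    total = n_records * fs
    data = np.zeros((n_ch, total))
    data[:, : block.n_samples] = block.data

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = phys_max - phys_min
    flat = span == 0
    phys_max[flat] += 1.0
    span[flat] = 1.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / span
    digital = np.round((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    labels = block.channel_names or [f"EEG{i}" for i in range(n_ch)]
    header = b""
    header += _pad("0", 8)
    header += _pad(patient, 80)
    header += _pad(recording, 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (1 + n_ch)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)  # record duration (s)
    header += _pad(str(n_ch), 4)
    for lab in labels:
        header += _pad(lab, 16)
    header += b" " * (80 * n_ch)  # transducer
    for _ in range(n_ch):
        header += _pad("uV", 8)
    for v in phys_min:
        header += _pad(f"{v:.6g}"[:8], 8)
    for v in phys_max:
        header += _pad(f"{v:.6g}"[:8], 8)
    for _ in range(n_ch):
        header += _pad(str(dig_min), 8)
    for _ in range(n_ch):
        header += _pad(str(dig_max), 8)
    header += b" " * (80 * n_ch)  # prefiltering
    for _ in range(n_ch):
        header += _pad(str(fs), 8)
    header += b" " * (32 * n_ch)

    with open(path, "wb") as f:
        f.write(header)
        for rec in range(n_records):
            chunk = digital[:, rec * fs : (rec + 1) * fs]
            f.write(chunk.tobytes())


def read_edf(path) -> tuple[TimeSeriesBlock, Montage]:
    """Read a classic EDF file and auto-split the montage.

    Labels matching L1-L10 / R1-R10 are assigned to the cEEGrid group; all
    other channels go to the scalp group.
    """
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise FormatError("truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            rec_dur = float(head[244:252].decode("ascii").strip())
            n_ch = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"bad EDF header fields: {exc}") from exc
        sig = f.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise FormatError("truncated EDF signal headers")

        def field(offset, width):
            base = offset * n_ch
            return [
                sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        labels = field(0, 16)
        # layout: label16 transducer80 unit8 pmin8 pmax8 dmin8 dmax8 filt80 ns8
        off = 16 * n_ch + 80 * n_ch + 8 * n_ch
        pmin = np.array([float(sig[off + i * 8 : off + (i + 1) * 8]) for i in range(n_ch)])
        off += 8 * n_ch
        pmax = np.array([float(sig[off + i * 8 : off + (i + 1) * 8]) for i in range(n_ch)])
        off += 8 * n_ch
        dmin = np.array([float(sig[off + i * 8 : off + (i + 1) * 8]) for i in range(n_ch)])
        off += 8 * n_ch
        dmax = np.array([float(sig[off + i * 8 : off + (i + 1) * 8]) for i in range(n_ch)])
        off += 8 * n_ch + 80 * n_ch
        ns = np.array([int(sig[off + i * 8 : off + (i + 1) * 8]) for i in range(n_ch)])

        if len(set(ns.tolist())) != 1:
            raise FormatError("mixed per-channel rates not supported")
        spr = int(ns[0])
        fs = spr / rec_dur
        raw = np.frombuffer(f.read(n_records * n_ch * spr * 2), dtype="<i2")
        if raw.size != n_records * n_ch * spr:
            raise FormatError("truncated EDF data records")
        raw = raw.reshape(n_records, n_ch, spr)
        data = np.concatenate([raw[r] for r in range(n_records)], axis=1).astype(float)
        gain = (pmax - pmin) / (dmax - dmin)
        data = (data - dmin[:, None]) * gain[:, None] + pmin[:, None]

    block = TimeSeriesBlock(data, fs, labels)
    return block, Montage.from_labels(labels)


# ---------------------------------------------------------------------------
# tabular export

def feature_to_csv(feature: FeatureSignal, path) -> None:
    """Single-channel feature export with (time_s, value) header."""
    import pandas as pd

    pd.DataFrame(
        {"time_s": np.arange(feature.n_samples) / feature.fs, "value": feature.values}
    ).to_csv(path, index=False)
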