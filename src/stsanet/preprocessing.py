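"""Preprocessing of continuous multi-channel EEG into labeled epochs.

The pipeline mirrors the standard motor-imagery decoding front end:
band-pass (or pure low-pass) filtering, causal exponential moving
standardization per channel, and cue-aligned epoch extraction.  The fixed
order is filter -> standardize -> epoch; resampling, when a recording's
rate differs from the target, happens before filtering.

Core functions accept plain NumPy arrays so nothing here requires GDF/EDF
files; thin adapters at the bottom read those containers through MNE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as _sig

logger = logging.getLogger("stsanet")

__all__ = [
    "Recording",
    "Epoch",
    "PreprocessConfig",
    "DataError",
    "InvalidConfigError",
    "bandpass_filter",
    "exponential_moving_standardize",
    "resample",
    "extract_epochs",
    "preprocess_recording",
    "save_epochs",
    "load_epochs",
    "load_raw",
]


class DataError(ValueError):
    """Raised when input data violate a contract (non-finite, empty, ...)."""


class InvalidConfigError(ValueError):
    """Raised for configuration values that cannot be honoured."""


@dataclass
class Recording:
    """Continuous multi-channel signal with event markers.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Raw EEG in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        Unique, ordered electrode names.
    events : sequence of (int, int)
        ``(sample_index, class_label)`` cue markers.
    subject_id : str
    """

    signal: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    events: Sequence[tuple[int, int]]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise DataError("signal must be a channels x samples matrix")
        if not self.fs > 0:
            raise InvalidConfigError("sampling rate must be positive")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidConfigError("channel labels must be unique")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise InvalidConfigError("one label per channel required")
        n = self.signal.shape[1]
        for s, _ in self.events:
            if not (0 <= s < n):
                raise DataError(f"event at sample {s} outside recording of length {n}")


@dataclass
class Epoch:
    """A cue-aligned channels x samples trial with its class label."""

    M: np.ndarray
    label: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] < 2:
            raise DataError("epoch must be a matrix with at least 2 channels")
        if not np.all(np.isfinite(self.M)):
            raise DataError("epoch contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.M.shape[0]

    @property
    def n_samples(self) -> int:
        return self.M.shape[1]


@dataclass
class PreprocessConfig:
    """Single source of truth for the preprocessing stage.

    ``low_cut`` of 0 (or ``None``) means no high-pass is applied, i.e. a
    pure low-pass at ``high_cut``.  ``window`` is in seconds relative to
    the cue; the default (-0.5, 4.0) at 250 Hz yields 1125 samples.
    """

    low_cut: float | None = 0.0
    high_cut: float = 38.0
    decay: float = 0.999
    eps_var: float = 1e-4
    window: tuple[float, float] = (-0.5, 4.0)
    target_fs: float = 250.0

    def __post_init__(self) -> None:
        if not (0 < self.decay < 1):
            raise InvalidConfigError("decay must lie in (0, 1)")
        if not self.eps_var > 0:
            raise InvalidConfigError("eps_var must be positive")
        if self.high_cut >= self.target_fs / 2:
            raise InvalidConfigError("high_cut must be below Nyquist of target_fs")
        if self.window[0] >= self.window[1]:
            raise InvalidConfigError("window start must precede end")


# ---------------------------------------------------------------------------
# filtering / standardization / resampling
# ---------------------------------------------------------------------------

_FILTER_ORDER = 4  # Butterworth, applied forward-backward (zero phase)


def bandpass_filter(
    signal: np.ndarray,
    fs: float,
    low_cut: float | None,
    high_cut: float,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (or low-pass) per channel.

    A ``low_cut`` of 0 or ``None`` selects a pure low-pass at ``high_cut``.
    Filtering is forward-backward (``sosfiltfilt``) so epoch alignment is
    preserved.
    """
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("cannot filter non-finite data")
    nyq = fs / 2.0
    if high_cut >= nyq:
        raise InvalidConfigError(f"high_cut {high_cut} Hz >= Nyquist {nyq} Hz")
    low = 0.0 if low_cut is None else float(low_cut)
    if low < 0 or low >= high_cut:
        raise InvalidConfigError("need 0 <= low_cut < high_cut")
    if low == 0.0:
        sos = _sig.butter(_FILTER_ORDER, high_cut, btype="lowpass", fs=fs, output="sos")
    else:
        sos = _sig.butter(
            _FILTER_ORDER, [low, high_cut], btype="bandpass", fs=fs, output="sos"
        )
    return _sig.sosfiltfilt(sos, x, axis=-1)


def exponential_moving_standardize(
    signal: np.ndarray,
    decay: float = 0.999,
    eps_var: float = 1e-4,
) -> np.ndarray:
    """Causal per-channel standardization by exponential running moments.

    For each channel, sample ``t`` is mapped to
    ``(x_t - m_t) / max(sqrt(v_t), sqrt(eps_var))`` with

        m_t = decay * m_{t-1} + (1 - decay) * x_t,
        v_t = decay * v_{t-1} + (1 - decay) * (x_t - m_t)**2,

    initialized from the first sample (``m_{-1} = x_0``, ``v_{-1} = 0``).
    The recursions are first-order IIR filters and are evaluated with
    ``scipy.signal.lfilter``, which is exactly equivalent to the
    sample-by-sample loop.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if x.size == 0:
        raise DataError("cannot standardize an empty signal")
    if not (0 < decay < 1):
        raise InvalidConfigError("decay must lie in (0, 1)")
    if not eps_var > 0:
        raise InvalidConfigError("eps_var must be positive")

    b, a = [1.0 - decay], [1.0, -decay]
    # zi for y[-1] = x0 is decay * x0 (lfilter state carries a*y contribution)
    zi_m = decay * x[:, :1]
    m, _ = _sig.lfilter(b, a, x, axis=-1, zi=zi_m)
    d2 = (x - m) ** 2
    v, _ = _sig.lfilter(b, a, d2, axis=-1, zi=np.zeros_like(zi_m))
    out = (x - m) / np.maximum(np.sqrt(v), np.sqrt(eps_var))
    return out.reshape(np.shape(signal))


def resample(signal: np.ndarray, fs_from: float, fs_to: float) -> np.ndarray:
    """Band-limited (polyphase) resampling along the time axis.

    Output length is ``round(n_in * fs_to / fs_from)`` exactly; the
    polyphase result is trimmed or edge-padded by at most one sample to
    honour that contract.
    """
    if not (np.isfinite(fs_from) and np.isfinite(fs_to) and fs_from > 0 and fs_to > 0):
        raise InvalidConfigError("sampling rates must be finite and positive")
    x = np.asarray(signal, dtype=float)
    if fs_to == fs_from:
        return x.copy()
    frac = Fraction(fs_to / fs_from).limit_denominator(1000)
    y = _sig.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    n_target = int(round(x.shape[-1] * fs_to / fs_from))
    if y.shape[-1] > n_target:
        y = y[..., :n_target]
    elif y.shape[-1] < n_target:
        pad = n_target - y.shape[-1]
        y = np.concatenate([y, np.repeat(y[..., -1:], pad, axis=-1)], axis=-1)
    return y


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------


def extract_epochs(
    recording: Recording,
    window: tuple[float, float],
) -> list[Epoch]:
    """Cut one epoch per event from a continuous recording.

    The window ``(start_s, end_s)`` is relative to the cue at t = 0; the
    sample interval is half-open, ``[cue + round(start*fs), cue +
    round(start*fs) + W)`` with ``W = round((end - start) * fs)``.  Events
    whose window leaves the recording are skipped with a warning.
    """
    start_s, end_s = window
    if start_s >= end_s:
        raise InvalidConfigError("window start must precede end")
    fs = recording.fs
    W = int(round((end_s - start_s) * fs))
    offset = int(round(start_s * fs))
    n = recording.signal.shape[1]
    epochs: list[Epoch] = []
    for cue, label in recording.events:
        s0 = cue + offset
        s1 = s0 + W
        if s0 < 0 or s1 > n:
            logger.warning(
                "skipping event at sample %d: window [%d, %d) outside recording",
                cue, s0, s1,
            )
            continue
        epochs.append(
            Epoch(recording.signal[:, s0:s1].copy(), int(label), recording.subject_id)
        )
    return epochs


def preprocess_recording(
    recording: Recording, config: PreprocessConfig
) -> list[Epoch]:
    """Full pipeline: (resample) -> filter -> standardize -> epoch."""
    sig = recording.signal
    fs = recording.fs
    events = list(recording.events)
    if fs != config.target_fs:
        ratio = config.target_fs / fs
        sig = resample(sig, fs, config.target_fs)
        events = [(int(round(s * ratio)), lab) for s, lab in events]
        fs = config.target_fs
    sig = bandpass_filter(sig, fs, config.low_cut, config.high_cut)
    sig = exponential_moving_standardize(sig, config.decay, config.eps_var)
    rec = Recording(sig, fs, recording.channel_labels, events, recording.subject_id)
    return extract_epochs(rec, config.window)


def epochs_to_arrays(epochs: Sequence[Epoch]) -> tuple[np.ndarray, np.ndarray]:
    """Stack epochs into ``X (n, H, W) float32`` and ``y (n,) int64``."""
    X = np.stack([e.M for e in epochs]).astype(np.float32)
    y = np.array([e.label for e in epochs], dtype=np.int64)
    return X, y


# ---------------------------------------------------------------------------
# archives and raw-file adapters
# ---------------------------------------------------------------------------


def save_epochs(
    path,
    X: np.ndarray,
    y: np.ndarray,
    fs: float,
    channel_labels: Sequence[str] | None = None,
) -> None:
    """Write an epoch archive: datasets ``X`` (float32) and ``y`` (int)."""
    import h5py

    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 3 or X.shape[0] != y.shape[0]:
        raise DataError("X must be (n_trials, H, W) aligned with y")
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=X)
        f.create_dataset("y", data=y)
        f.attrs["fs"] = float(fs)
        if channel_labels is None:
            channel_labels = [f"ch{i}" for i in range(X.shape[1])]
        f.attrs["channel_labels"] = [str(c) for c in channel_labels]


def load_epochs(path) -> tuple[np.ndarray, np.ndarray, float, list[str]]:
    import h5py

    with h5py.File(path, "r") as f:
        X = f["X"][()].astype(np.float32)
        y = f["y"][()].astype(np.int64)
        fs = float(f.attrs["fs"])
        labels = [str(c) for c in f.attrs["channel_labels"]]
    return X, y, fs, labels


def load_raw(
    path,
    picks: Sequence[str] | None = None,
    drop_eog: bool = True,
) -> Recording:
    """Read a continuous GDF or EDF/EDF+ recording into a :class:`Recording`.

    ``picks`` selects an explicit channel subset by name (e.g. a montage's
    motor-cortex electrodes); otherwise all EEG channels are kept and, with
    ``drop_eog``, EOG channels are removed before modeling.
    """
    import mne

    path = str(path)
    if path.lower().endswith(".gdf"):
        raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if picks is not None:
        raw.pick(list(picks))
    elif drop_eog:
        keep = [
            ch
            for ch, kind in zip(raw.ch_names, raw.get_channel_types())
            if kind != "eog" and "eog" not in ch.lower()
        ]
        raw.pick(keep)
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    ev = [(int(s), int(code)) for s, _, code in events]
    return Recording(
        raw.get_data() * 1e6,  # volts -> microvolts
        float(raw.info["sfreq"]),
        list(raw.ch_names),
        ev,
    )
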