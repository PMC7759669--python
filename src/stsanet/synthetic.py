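"""Synthetic motor-imagery EEG with class-dependent ERD/ERS.

Real MI epochs differ between classes mainly through band-power changes:
imagining a movement suppresses (ERD) or enhances (ERS) the mu (8-12 Hz)
and beta (16-26 Hz) rhythms on task-dependent channel subsets.  The
generator emulates exactly that structure: every channel carries

    1/f background  +  mu oscillation  +  beta oscillation  +  white noise,

where the oscillations are band-pass-filtered white noise (fresh noise per
epoch, so phases and envelopes vary) whose amplitude on a channel is the
base amplitude times the class's ERD/ERS factor (>1 = ERS, <1 = ERD,
1 = no modulation).

The default four-class spec loosely mimics left hand / right hand / feet /
tongue imagery over a 22-channel montage with C3-, Cz- and C4-like channel
groups, with strong, well-separated factors so that desk-scale end-to-end
training is feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _sig

__all__ = [
    "BANDS",
    "RhythmEffect",
    "SyntheticSpec",
    "default_spec",
    "generate_epoch",
    "generate_dataset",
    "band_power_features",
]

BANDS: dict[str, tuple[float, float]] = {"mu": (8.0, 12.0), "beta": (16.0, 26.0)}


@dataclass(frozen=True)
class RhythmEffect:
    """ERD/ERS of one band on one channel subset: amplitude factor."""

    channels: tuple[int, ...]
    band: str
    factor: float

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}; choose from {list(BANDS)}")
        if not self.factor > 0:
            raise ValueError("amplitude factors must be positive")


@dataclass
class SyntheticSpec:
    """Study conditions for the generator.

    ``classes`` maps each class label (list position) to its rhythm
    effects; channels without an effect keep factor 1.  ``osc_amplitude``
    is the baseline RMS of each band oscillation, ``background_scale`` the
    RMS of the 1/f background (exponent ``background_exponent``), and
    ``noise_sd`` the white-noise standard deviation, all in the same
    arbitrary units.
    """

    n_channels: int = 22
    fs: float = 250.0
    epoch_length_s: float = 4.5
    classes: list[list[RhythmEffect]] = field(default_factory=list)
    background_exponent: float = 1.0
    background_scale: float = 1.0
    osc_amplitude: float = 1.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        for effects in self.classes:
            for e in effects:
                if any(c < 0 or c >= self.n_channels for c in e.channels):
                    raise ValueError("effect channels outside the montage")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_length_s))

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def default_spec() -> SyntheticSpec:
    """Well-separated four-class conditions on a 22-channel montage.

    Channel groups play the roles of left motor cortex (around C3),
    midline (around Cz) and right motor cortex (around C4).  Hand imagery
    suppresses mu/beta contralaterally and enhances mu ipsilaterally;
    feet imagery modulates the midline; tongue imagery modulates a
    fronto-parietal set.
    """
    left, mid, right = (7, 8), (9, 10), (11, 12)
    fronto_parietal = (2, 3, 18, 19)
    return SyntheticSpec(
        classes=[
            [  # left hand: contralateral (right) ERD, ipsilateral mu ERS
                RhythmEffect(right, "mu", 0.35),
                RhythmEffect(right, "beta", 0.5),
                RhythmEffect(left, "mu", 1.8),
            ],
            [  # right hand: mirror image
                RhythmEffect(left, "mu", 0.35),
                RhythmEffect(left, "beta", 0.5),
                RhythmEffect(right, "mu", 1.8),
            ],
            [  # feet: midline ERD, flanking beta ERS
                RhythmEffect(mid, "mu", 0.35),
                RhythmEffect(mid, "beta", 0.5),
                RhythmEffect(left + right, "beta", 1.8),
            ],
            [  # tongue: fronto-parietal mu ERS, midline beta ERD
                RhythmEffect(fronto_parietal, "mu", 2.0),
                RhythmEffect(mid, "beta", 0.5),
            ],
        ]
    )


def _class_factors(spec: SyntheticSpec, label: int) -> dict[str, np.ndarray]:
    factors = {b: np.ones(spec.n_channels) for b in BANDS}
    for e in spec.classes[label]:
        for c in e.channels:
            factors[e.band][c] = e.factor
    return factors


def _band_noise(rng, n_channels, n, fs, band) -> np.ndarray:
    """Unit-RMS band-limited noise per channel (random phase and envelope)."""
    lo, hi = BANDS[band]
    sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfiltfilt(sos, rng.standard_normal((n_channels, n + 200)))[:, 100:-100]
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / np.maximum(rms, 1e-12)


def _pink_background(rng, n_channels, n, fs, exponent, scale) -> np.ndarray:
    """Spectrally shaped Gaussian noise with a 1/f^exponent power spectrum."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return scale * x / np.maximum(rms, 1e-12)


def generate_epoch(
    spec: SyntheticSpec, class_label: int, rng: np.random.Generator
) -> np.ndarray:
    """One (n_channels, n_samples) epoch of the given class."""
    if not (0 <= class_label < spec.n_classes):
        raise ValueError(f"unknown class {class_label}; spec has {spec.n_classes}")
    n = spec.n_samples
    factors = _class_factors(spec, class_label)
    x = _pink_background(
        rng, spec.n_channels, n, spec.fs, spec.background_exponent,
        spec.background_scale,
    )
    for band in BANDS:
        osc = _band_noise(rng, spec.n_channels, n, spec.fs, band)
        x += spec.osc_amplitude * factors[band][:, None] * osc
    x += spec.noise_sd * rng.standard_normal((spec.n_channels, n))
    return x


def generate_dataset(
    spec: SyntheticSpec, n_per_class: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced, seeded and shuffled dataset: X (n, H, W) float32, y (n,)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    X, y = [], []
    for label in range(spec.n_classes):
        for _ in range(n_per_class):
            X.append(generate_epoch(spec, label, rng))
            y.append(label)
    X = np.stack(X).astype(np.float32)
    y = np.asarray(y, dtype=np.int64)
    order = rng.permutation(len(y))
    return X[order], y[order]


def band_power_features(X: np.ndarray, fs: float) -> np.ndarray:
    """Welch band power in mu and beta per channel: (n, 2 * n_channels).

    A convenient linear-classifier feature set; also the oracle used to
    check that the generator's class structure is present in band power.
    """
    X = np.asarray(X)
    f, psd = _sig.welch(X, fs=fs, nperseg=min(256, X.shape[-1]), axis=-1)
    feats = []
    for lo, hi in BANDS.values():
        sel = (f >= lo) & (f <= hi)
        feats.append(np.trapezoid(psd[..., sel], f[sel], axis=-1))
    return np.concatenate(feats, axis=-1).reshape(X.shape[0], -1)
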