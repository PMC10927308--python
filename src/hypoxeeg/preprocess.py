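"""Deterministic EEG signal conditioning.

Implements the automated preprocessing chain used for sensor-space
resting-state analysis: zero-phase band-pass filtering (broadband FIR or
per-band 3rd-order Bessel), anti-aliased downsampling, common average
reference, and segmentation into fixed-length epochs.

All operations are pure functions of their inputs.  Filters are applied
forward-backward (zero phase): downstream phase-based connectivity (wPLI)
must not see filter-induced phase distortion, at the cost of doubling the
effective filter order.

Artifact rejection (ICA, visual inspection) is intentionally not part of
this chain — it is a manual step on real recordings; ``Recording`` objects
from pre-cleaned data can enter the pipeline directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .channels import default_region_map

#: Canonical EEG band edges in Hz, half-open [low, high).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Broadband normalization range for relative power, Hz.
BROADBAND: tuple[float, float] = (0.5, 30.0)

CONDITIONS = ("sea", "altitude")


@dataclass
class Recording:
    """One subject-condition multichannel time series.

    ``data`` is channels x samples (µV for real data, arbitrary units for
    synthetic signals).  ``region_map`` assigns every analyzed channel to
    one of the five scalp regions.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    region_map: dict[str, str] = field(default_factory=default_region_map)
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("Recording contains non-finite samples")
        missing = [c for c in self.channel_labels if c not in self.region_map]
        if missing:
            raise ValueError(f"region_map does not cover channels: {missing}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Non-overlapping fixed-length segments of a recording.

    ``epochs`` is epochs x channels x samples.
    """

    epochs: np.ndarray
    fs: float
    epoch_length: float
    band: str = "broadband"

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def _fir_filtfilt(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Two zero-phase passes of a symmetric FIR via FFT convolution.

    Equivalent to filtfilt for a linear-phase kernel (squared magnitude
    response, zero phase) but O(n log n); edges are reflect-padded by the
    kernel length.
    """
    pad = len(taps)
    xp = np.concatenate(
        [x[..., 1 : pad + 1][..., ::-1], x, x[..., -pad - 1 : -1][..., ::-1]],
        axis=-1,
    )
    for _ in range(2):
        xp = signal.fftconvolve(xp, taps[None, :], mode="same", axes=-1)
    return xp[..., pad:-pad]


def bandpass(
    recording: Recording,
    low: float,
    high: float,
    design: str = "bessel3_band",
) -> Recording:
    """Zero-phase band-pass filter.

    ``design='fir_broadband'`` uses a linear-phase FIR (Hamming window,
    filtfilt) for the wide conditioning band; ``design='bessel3_band'``
    uses a 3rd-order Bessel IIR (sosfiltfilt) for the narrow EEG bands.
    """
    fs = recording.fs
    nyq = fs / 2.0
    if not (0 <= low < high):
        raise ValueError(f"need 0 <= low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz >= Nyquist {nyq} Hz")

    x = recording.data
    if design == "fir_broadband":
        # Transition width tied to the low edge so very low cutoffs resolve.
        width = max(min(low, 0.5), 0.1) if low > 0 else 1.0
        numtaps = int(6.6 * fs / width) // 2 * 2 + 1  # odd, Hamming rule
        numtaps = min(numtaps, 2 * (x.shape[1] // 3) - 3)
        if low > 0:
            taps = signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs)
        else:
            taps = signal.firwin(numtaps, high, pass_zero=True, fs=fs)
        filtered = _fir_filtfilt(taps, x)
    elif design == "bessel3_band":
        sos = signal.bessel(3, [low, high], btype="bandpass", fs=fs, output="sos")
        filtered = signal.sosfiltfilt(sos, x, axis=-1)
    else:
        raise ValueError(f"unknown filter design {design!r}")
    return replace(recording, data=filtered)


def resample(recording: Recording, target_fs: float) -> Recording:
    """Downsample with polyphase anti-alias filtering; upsampling is refused."""
    if target_fs > recording.fs:
        raise ValueError(
            f"upsampling not supported ({recording.fs} -> {target_fs} Hz)"
        )
    if target_fs == recording.fs:
        return recording
    ratio = Fraction(target_fs / recording.fs).limit_denominator(1000)
    data = signal.resample_poly(recording.data, ratio.numerator, ratio.denominator, axis=-1)
    return replace(recording, data=data, fs=target_fs)


def average_reference(recording: Recording) -> Recording:
    """Re-reference to the instantaneous mean across channels."""
    if recording.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return replace(recording, data=data)


def epoch(recording: Recording, epoch_length: float, band: str = "broadband") -> EpochSet:
    """Cut into floor(duration / epoch_length) consecutive epochs.

    The trailing partial segment is discarded.
    """
    n_per = int(round(epoch_length * recording.fs))
    n_epochs = recording.n_samples // n_per
    if n_epochs == 0:
        raise ValueError(
            f"recording of {recording.duration:.1f} s shorter than one "
            f"{epoch_length} s epoch"
        )
    x = recording.data[:, : n_epochs * n_per]
    epochs = x.reshape(recording.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochSet(epochs=epochs, fs=recording.fs, epoch_length=epoch_length, band=band)
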