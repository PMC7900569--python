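"""Sensor-space preprocessing: epoching, artifact rejection, and filtering.

Continuous multi-channel recordings (units fT) are split into fixed-length
non-overlapping epochs, epochs containing any sample whose absolute value
exceeds an amplitude threshold are discarded, the site's utility (power-line)
frequency is removed with a zero-phase band-stop filter, and band-limited
signals are obtained with zero-phase Butterworth bandpasses.

All filters are order-4 Butterworth applied forward-backward (``sosfiltfilt``),
so they are zero-phase and the effective attenuation is doubled relative to a
single pass. The notch is 2 Hz wide, centered on the utility frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .bands import UTILITY_FREQUENCIES, BandDefinition

__all__ = [
    "Recording",
    "EpochSet",
    "segment_epochs",
    "reject_epochs",
    "notch_filter",
    "bandpass",
]


@dataclass
class Recording:
    """A continuous multi-channel sensor recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Sensor time series in fT.
    sampling_rate : float
        Sampling rate in Hz. Must exceed twice the highest band edge in use.
    utility_hz : int
        Site power-line frequency, 50 or 60 Hz.
    """

    data: np.ndarray
    sampling_rate: float
    utility_hz: int = 60

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a (n_channels, n_samples) array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.utility_hz not in UTILITY_FREQUENCIES:
            raise ValueError(f"utility_hz must be one of {UTILITY_FREQUENCIES}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.sampling_rate


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one recording.

    ``epochs`` has shape (n_epochs, n_channels, n_samples_per_epoch);
    ``kept_indices`` maps each epoch back to its position in the original
    segmentation (strictly increasing).
    """

    epochs: np.ndarray
    epoch_length_s: float
    sampling_rate: float
    utility_hz: int
    kept_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if not self.kept_indices:
            self.kept_indices = list(range(self.epochs.shape[0]))
        if list(self.kept_indices) != sorted(set(self.kept_indices)):
            raise ValueError("kept_indices must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def segment_epochs(rec: Recording, epoch_length_s: float = 10.0) -> EpochSet:
    """Cut a recording into non-overlapping epochs of ``epoch_length_s`` seconds.

    The number of epochs is floor(duration / epoch_length); any trailing
    remainder shorter than one epoch is dropped. A recording shorter than one
    epoch is an error.
    """
    n_per = int(round(epoch_length_s * rec.sampling_rate))
    if n_per <= 0:
        raise ValueError("epoch_length_s must be positive")
    n_epochs = rec.data.shape[1] // n_per
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s is shorter than one "
            f"{epoch_length_s} s epoch"
        )
    trimmed = rec.data[:, : n_epochs * n_per]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochSet(
        epochs=epochs.copy(),
        epoch_length_s=epoch_length_s,
        sampling_rate=rec.sampling_rate,
        utility_hz=rec.utility_hz,
    )


def reject_epochs(epochs: EpochSet, threshold_ft: float = 6000.0) -> EpochSet:
    """Discard epochs whose signal exceeds ``threshold_ft`` (fT) in magnitude.

    An epoch is dropped iff any channel's absolute value exceeds the threshold
    at any sample. Raises if every epoch is rejected, since downstream power
    estimates would be undefined.
    """
    if threshold_ft <= 0:
        raise ValueError("threshold_ft must be positive")
    peak = np.max(np.abs(epochs.epochs), axis=(1, 2))
    keep = peak <= threshold_ft
    if not keep.any():
        raise ValueError("all epochs rejected by the amplitude criterion")
    kept_indices = [idx for idx, k in zip(epochs.kept_indices, keep) if k]
    return replace(epochs, epochs=epochs.epochs[keep], kept_indices=kept_indices)


def _apply_sos(epochs: EpochSet, sos: np.ndarray) -> EpochSet:
    filtered = signal.sosfiltfilt(sos, epochs.epochs, axis=-1)
    return replace(epochs, epochs=np.ascontiguousarray(filtered))


def notch_filter(epochs: EpochSet, utility_hz: int | None = None) -> EpochSet:
    """Remove the utility frequency with a zero-phase 2-Hz-wide band-stop.

    ``utility_hz`` defaults to the value recorded with the epochs (60 Hz for
    the patient site, 50 Hz for the control site).
    """
    f0 = epochs.utility_hz if utility_hz is None else utility_hz
    if f0 not in UTILITY_FREQUENCIES:
        raise ValueError(f"utility_hz must be one of {UTILITY_FREQUENCIES}")
    nyq = epochs.sampling_rate / 2.0
    if f0 >= nyq:
        raise ValueError("utility frequency must be below Nyquist")
    sos = signal.butter(
        4, [f0 - 1.0, f0 + 1.0], btype="bandstop", fs=epochs.sampling_rate, output="sos"
    )
    return _apply_sos(epochs, sos)


def bandpass(epochs: EpochSet, band: BandDefinition) -> EpochSet:
    """Zero-phase Butterworth bandpass restricted to ``band``.

    Raises if the band's upper edge is at or above Nyquist.
    """
    nyq = epochs.sampling_rate / 2.0
    if band.hi >= nyq:
        raise ValueError(
            f"band {band.name!r} upper edge {band.hi} Hz is not below Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(
        4, [band.lo, band.hi], btype="bandpass", fs=epochs.sampling_rate, output="sos"
    )
    return _apply_sos(epochs, sos)
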