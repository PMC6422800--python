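"""Filtering, epoch segmentation, amplitude-based artifact rejection, and
band-power covariates.

Processing order follows the usual resting-state pipeline: the continuous
recording is filtered first (broadband 0.5-50 Hz, then per-band zero-phase
bandpass), and only then segmented into fixed-length epochs — filtering the
continuous signal keeps per-epoch edge transients out of the phase
estimates.  Epochs in which any channel exceeds an absolute amplitude
threshold (default +/-150 microvolts) are rejected automatically; a subject
retaining fewer than ``min_epochs`` epochs (default 80) is flagged for the
QC report rather than dropped, so that small synthetic runs still complete.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
from scipy.integrate import trapezoid
from scipy.signal import butter, sosfiltfilt, welch

from .bands import BandDefinition, get_band
from .recording import EpochedRecording, MultichannelRecording

__all__ = ["bandpass", "segment", "reject_epochs", "band_power",
           "rereference", "LowEpochCountWarning", "FILTER_ORDER"]

#: Butterworth order per pass (applied forward and backward).
FILTER_ORDER = 4


class LowEpochCountWarning(UserWarning):
    """Raised (as a warning, never an error) when a recording retains fewer
    kept epochs than the configured minimum."""


@lru_cache(maxsize=64)
def _design_sos(order: int, low: float, high: float, fs: float):
    # identical designs recur for every subject of a cohort; cache them
    return butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(recording: MultichannelRecording,
             band: "BandDefinition | str | tuple[float, float]",
             order: int = FILTER_ORDER) -> MultichannelRecording:
    """Zero-phase Butterworth bandpass of a continuous recording.

    Forward-backward filtering (``sosfiltfilt``) gives unit passband gain,
    zero group delay, and doubles the effective order.

    Raises
    ------
    ValueError
        If the band's upper edge reaches the Nyquist frequency.
    """
    band = get_band(band)
    nyq = recording.fs / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band {band.name} upper edge {band.high} Hz >= Nyquist {nyq} Hz")
    sos = _design_sos(order, band.low, band.high, recording.fs)
    out = recording.copy_with(sosfiltfilt(sos, recording.data, axis=-1))
    out.meta["band"] = band.name
    return out


def rereference(recording: MultichannelRecording,
                reference_channels: list[str]) -> MultichannelRecording:
    """Subtract the mean of named reference channels from every channel
    (e.g. linked-mastoid re-referencing).  Optional; off by default in the
    synthetic pipeline."""
    idx = [recording.channel_labels.index(ch) for ch in reference_channels]
    ref = recording.data[idx].mean(axis=0, keepdims=True)
    return recording.copy_with(recording.data - ref)


def segment(recording: MultichannelRecording,
            epoch_len_s: float = 2.0) -> EpochedRecording:
    """Cut a continuous recording into consecutive non-overlapping epochs.

    A trailing partial epoch is discarded.  360 s of signal at any sampling
    rate yields 180 epochs of 2 s.

    Raises
    ------
    ValueError
        If the recording is shorter than one epoch.
    """
    if epoch_len_s <= 0:
        raise ValueError("epoch_len_s must be positive")
    samples_per_epoch = round(epoch_len_s * recording.fs)
    n_epochs = recording.n_samples // samples_per_epoch
    if n_epochs < 1:
        raise ValueError(
            f"recording of {recording.duration_s:.3f} s shorter than one "
            f"{epoch_len_s} s epoch")
    used = recording.data[:, :n_epochs * samples_per_epoch]
    data = used.reshape(recording.n_channels, n_epochs, samples_per_epoch)
    return EpochedRecording(
        data=np.ascontiguousarray(data.transpose(1, 0, 2)),
        channel_labels=list(recording.channel_labels),
        fs=recording.fs,
        epoch_len_s=epoch_len_s,
    )


def reject_epochs(epoched: EpochedRecording,
                  amp_threshold_uv: float = 150.0,
                  min_epochs: int = 80,
                  subject_id: str = "") -> EpochedRecording:
    """Reject epochs whose absolute amplitude exceeds a threshold anywhere.

    An epoch is rejected when |x| > amp_threshold_uv at any channel and any
    sample.  If fewer than ``min_epochs`` epochs survive, a
    :class:`LowEpochCountWarning` is emitted (analysis proceeds).  The
    operation is idempotent: already-rejected epochs stay rejected.
    """
    if amp_threshold_uv <= 0:
        raise ValueError("amplitude threshold must be positive")
    exceeds = np.abs(epoched.data).max(axis=(1, 2)) > amp_threshold_uv
    kept = epoched.kept_mask & ~exceeds
    if kept.sum() < min_epochs:
        who = f" for subject {subject_id}" if subject_id else ""
        warnings.warn(
            f"only {int(kept.sum())} epochs kept{who} "
            f"(< minimum {min_epochs})", LowEpochCountWarning, stacklevel=2)
    return EpochedRecording(epoched.data, list(epoched.channel_labels),
                            epoched.fs, epoched.epoch_len_s, kept)


def band_power(epoched: EpochedRecording,
               band: "BandDefinition | str | tuple[float, float]") -> float:
    """Mean band-limited power over kept epochs and channels.

    Welch PSD per epoch and channel (Hann window spanning the whole epoch)
    integrated over [low, high]; for a unit-amplitude sinusoid inside the
    band this is its mean square, 0.5.

    Raises
    ------
    ValueError
        If no epochs are kept.
    """
    band = get_band(band)
    data = epoched.kept_data()
    if data.shape[0] == 0:
        raise ValueError("no kept epochs")
    nperseg = data.shape[-1]
    freqs, psd = welch(data, fs=epoched.fs, nperseg=nperseg, axis=-1)
    in_band = (freqs >= band.low) & (freqs <= band.high)
    if in_band.sum() < 2:
        raise ValueError(f"band {band.name} unresolved at "
                         f"df={freqs[1] - freqs[0]:.3f} Hz")
    power = trapezoid(psd[..., in_band], freqs[in_band], axis=-1)
    return float(power.mean())
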