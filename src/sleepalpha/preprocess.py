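"""Conditioning of raw recordings: bandpass filter, epoching, artifact rejection.

The filter mirrors the acquisition device's 0.5–30 Hz analog passband but
is applied zero-phase (forward-backward 4th-order Butterworth) so band
powers are not distorted by group delay. Artifact handling is a
deterministic epoch-rejection rule: an epoch is dropped if any sample
exceeds an absolute amplitude threshold or if its peak-to-peak range is
an outlier (z-score across epochs) — a transparent stand-in for
blink/EMG cleaning that two frontal channels cannot support with
component decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .types import Recording


@dataclass
class EpochSet:
    """Uniform non-overlapping epochs of one recording with a kept mask.

    epochs has shape (n_epochs, n_channels, n_samples); µV.
    """

    source: tuple[str, int, str]
    fs: float
    length_s: float
    epochs: np.ndarray
    kept: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.kept = np.asarray(self.kept, dtype=bool)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if self.kept.shape != (self.epochs.shape[0],):
            raise ValueError("kept mask length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def kept_epochs(self, channel: int) -> np.ndarray:
        """(n_kept, n_samples) array for one channel."""
        if self.n_kept == 0:
            raise ValueError("no kept epochs")
        return self.epochs[self.kept, channel, :]


def bandpass(
    recording: Recording, f_lo: float = 0.5, f_hi: float = 30.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth bandpass of all channels."""
    nyq = recording.fs / 2.0
    if not 0 < f_lo < f_hi < nyq:
        raise ValueError(
            f"need 0 < f_lo < f_hi < Nyquist ({nyq:g} Hz); got [{f_lo}, {f_hi}]"
        )
    sos = butter(order, [f_lo, f_hi], btype="bandpass", fs=recording.fs, output="sos")
    filtered = sosfiltfilt(sos, recording.samples, axis=1)
    return replace(recording, samples=filtered)


def epoch(recording: Recording, length_s: float = 4.0, overlap: float = 0.0) -> EpochSet:
    """Cut the recording into non-overlapping fixed-length epochs.

    The trailing remainder shorter than one epoch is discarded. Overlap
    other than 0 is not supported (the multitaper averaging downstream
    assumes independent epochs).
    """
    if overlap != 0.0:
        raise NotImplementedError("overlapping epochs are not supported")
    n_per = int(round(length_s * recording.fs))
    n_ep = recording.n_samples // n_per
    if n_ep < 1:
        raise ValueError(
            f"recording of {recording.duration:g} s shorter than one "
            f"{length_s:g} s epoch"
        )
    used = recording.samples[:, : n_ep * n_per]
    eps = used.reshape(recording.samples.shape[0], n_ep, n_per).transpose(1, 0, 2)
    return EpochSet(
        source=recording.key,
        fs=recording.fs,
        length_s=length_s,
        epochs=eps,
        kept=np.ones(n_ep, dtype=bool),
    )


def reject_artifacts(
    epochs: EpochSet,
    amp_threshold_uv: float = 150.0,
    z_threshold: float = 5.0,
) -> EpochSet:
    """Flag artifact epochs by absolute amplitude and peak-to-peak outlier z-score.

    The z-score is computed per channel across the currently kept epochs;
    the rule is idempotent because rejected epochs are excluded from the
    reference statistics of a second pass only if they were outliers on
    the first. A run that rejects every epoch raises instead of silently
    producing an empty average.
    """
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    kept = epochs.kept.copy()
    absmax = np.abs(epochs.epochs).max(axis=2)  # (n_epochs, n_channels)
    amp_bad = (absmax > amp_threshold_uv).any(axis=1)
    ptp = epochs.epochs.max(axis=2) - epochs.epochs.min(axis=2)
    ref = kept & ~amp_bad
    z_bad = np.zeros(epochs.n_epochs, dtype=bool)
    if ref.sum() >= 3 and np.isfinite(z_threshold):
        mu = ptp[ref].mean(axis=0)
        sd = ptp[ref].std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (ptp - mu) / np.where(sd > 0, sd, np.inf)
        z_bad = (z > z_threshold).any(axis=1)
    new_kept = kept & ~amp_bad & ~z_bad
    if not new_kept.any():
        raise ValueError(
            "all epochs rejected; review amp_threshold_uv/z_threshold "
            "against the recording's amplitude scale"
        )
    return replace(epochs, kept=new_kept, epochs=epochs.epochs.copy())


def butter_response_db(
    f: float, f_lo: float = 0.5, f_hi: float = 30.0, fs: float = 512.0, order: int = 4
) -> float:
    """Magnitude response (dB) of the zero-phase bandpass at frequency f.

    Forward-backward filtering squares the magnitude response, hence the
    factor 2 on the single-pass response.
    """
    from scipy.signal import sosfreqz

    sos = butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    _, h = sosfreqz(sos, worN=[f * 2 * np.pi / fs])
    return float(2 * 20 * np.log10(np.abs(h[0]) + 1e-300))
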