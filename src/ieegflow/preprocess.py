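"""Preprocessing: cohort inclusion rules, filtering, resampling,
z-scoring, and epoch segmentation.

The protocol is the standard one for MVAR-based directed connectivity on
iEEG: band-pass 3-45 Hz with a 60 Hz notch, downsample to 500 Hz, z-score
each channel, then cut the 28-s preictal (ending at onset) and ictal
(starting at onset) epochs into seven non-overlapping 4-s segments so each
window is approximately stationary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import Recording, SegmentSet, ValidationError


@dataclass(frozen=True)
class ValidationOutcome:
    accepted: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.accepted


def validate_recording(rec: Recording, min_fs: float = 500.0,
                       min_preictal_s: float = 30.0) -> ValidationOutcome:
    """Apply the cohort inclusion rules to one recording.

    A recording is rejected when its original sampling rate is below
    ``min_fs`` or when less than ``min_preictal_s`` seconds of signal
    precede seizure onset.  Total function: never raises.
    """
    if rec.fs < min_fs:
        return ValidationOutcome(False, f"sampling rate below {min_fs:g} Hz")
    if rec.preictal_seconds < min_preictal_s:
        return ValidationOutcome(
            False, f"<{min_preictal_s:g} s of preictal activity")
    return ValidationOutcome(True, "")


def bandpass_notch(rec: Recording, low: float = 3.0, high: float = 45.0,
                   notch: float = 60.0, order: int = 4,
                   notch_q: float = 30.0) -> Recording:
    """Zero-phase Butterworth band-pass followed by an IIR notch.

    Both filters are applied forward-backward (``filtfilt``) so no phase lag
    is introduced that could bias directed-connectivity estimates.
    """
    nyq = rec.fs / 2.0
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs,
                        output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    if notch is not None and notch < nyq:
        b, a = signal.iirnotch(notch, notch_q, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=1)
    return rec.with_data(out)


def resample_to(rec: Recording, target_fs: float = 500.0) -> Recording:
    """Polyphase anti-aliased resampling down to ``target_fs``.

    Upsampling is refused: the inclusion rules already guarantee at least
    500 Hz, and interpolation would fabricate bandwidth.  The onset index is
    mapped by rounding ``onset * target_fs / fs``.
    """
    if target_fs > rec.fs:
        raise ValueError(
            f"cannot upsample from {rec.fs:g} to {target_fs:g} Hz")
    if target_fs == rec.fs:
        return rec
    from fractions import Fraction
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                               axis=1)
    onset = int(round(rec.onset_sample * target_fs / rec.fs))
    return rec.with_data(out, fs=target_fs, onset_sample=min(onset, out.shape[1]))


def zscore_channels(rec: Recording) -> Recording:
    """Standardize each channel to zero mean and unit standard deviation."""
    mean = rec.data.mean(axis=1, keepdims=True)
    sd = rec.data.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd[:, 0] == 0)
    if flat.size:
        labels = [rec.channel_labels[i] for i in flat]
        raise ValidationError(f"constant (zero-variance) channels: {labels}")
    return rec.with_data((rec.data - mean) / sd)


def segment_epoch(rec: Recording, period: str, epoch_s: float = 28.0,
                  window_s: float = 4.0) -> SegmentSet:
    """Cut the requested epoch into non-overlapping ``window_s`` segments.

    The preictal epoch is the ``epoch_s`` window ending exactly at onset;
    the ictal epoch starts exactly at onset.  ``epoch_s`` must be an exact
    multiple of ``window_s`` (the protocol only ever uses 28/4); partial
    windows are refused rather than truncated.
    """
    if period not in ("preictal", "ictal"):
        raise ValidationError(f"unknown period {period!r}")
    n_win = int(round(window_s * rec.fs))
    n_epoch = int(round(epoch_s * rec.fs))
    k, rem = divmod(n_epoch, n_win)
    if rem or k < 1:
        raise ValidationError(
            f"epoch_s={epoch_s} is not a multiple of window_s={window_s}")
    if period == "preictal":
        if rec.onset_sample < n_epoch:
            raise ValidationError(
                f"only {rec.preictal_seconds:.1f} s preictal signal, "
                f"{epoch_s:g} s requested")
        start = rec.onset_sample - n_epoch
    else:
        if rec.n_samples - rec.onset_sample < n_epoch:
            raise ValidationError(
                f"only {(rec.n_samples - rec.onset_sample) / rec.fs:.1f} s "
                f"ictal signal, {epoch_s:g} s requested")
        start = rec.onset_sample
    epoch = rec.data[:, start:start + n_epoch]
    segments = [epoch[:, i * n_win:(i + 1) * n_win].copy() for i in range(k)]
    origin = str(rec.meta.get("seizure_id", rec.meta.get("patient_id", "")))
    return SegmentSet(segments=segments, fs=rec.fs, period=period,
                      window_s=window_s, origin=origin)


def preprocess(rec: Recording, low: float = 3.0, high: float = 45.0,
               notch: float = 60.0, target_fs: float = 500.0,
               bad_channels: tuple[str, ...] = ()) -> Recording:
    """Full preprocessing chain: drop bad channels, filter, resample, z-score."""
    rec = rec.drop_channels(bad_channels)
    rec = bandpass_notch(rec, low=low, high=high, notch=notch)
    rec = resample_to(rec, target_fs=target_fs)
    return zscore_channels(rec)
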