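"""Container types and I/O for multichannel intracranial EEG recordings.

A :class:`Recording` holds one seizure's worth of iEEG: a channel-by-sample
matrix, its sampling rate, the sample index of electrical seizure onset, and
a boolean mask marking the clinician-annotated seizure-onset-zone (SOZ)
channels.  Recordings can be loaded from EDF files, from BIDS-iEEG-style
directories, or from a compact ``.npz`` fixture format used for tests and
synthetic cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violates a structural invariant (named in the message)."""


@dataclass
class Recording:
    """One multichannel iEEG recording around a single seizure.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolt-like arbitrary units.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names, one per row of ``data``.
    onset_sample : int
        Index of electrical seizure onset within ``data``.
    soz_mask : ndarray of bool, shape (n_channels,)
        True for channels annotated as seizure onset zone.
    meta : dict
        Free-form metadata (dataset id, patient id, seizure id,
        implant type, lesional flag, ...).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    onset_sample: int
    soz_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (n_channels, n_samples)")
        n_channels, n_samples = self.data.shape
        if n_channels < 2:
            raise ValidationError("a recording needs at least 2 channels")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != n_channels:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {n_channels} channels"
            )
        if len(set(self.channel_labels)) != n_channels:
            raise ValidationError("channel_labels must be unique")
        if not 0 <= int(self.onset_sample) <= n_samples:
            raise ValidationError(
                f"onset_sample {self.onset_sample} outside [0, {n_samples}]"
            )
        self.onset_sample = int(self.onset_sample)
        self.soz_mask = np.asarray(self.soz_mask, dtype=bool)
        if self.soz_mask.shape != (n_channels,):
            raise ValidationError("soz_mask length must equal n_channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def preictal_seconds(self) -> float:
        """Length of signal available before seizure onset, in seconds."""
        return self.onset_sample / self.fs

    def with_data(self, data: np.ndarray, fs: float | None = None,
                  onset_sample: int | None = None) -> "Recording":
        """Copy of this recording with replaced signal (labels/mask kept)."""
        return replace(
            self,
            data=data,
            fs=self.fs if fs is None else fs,
            onset_sample=self.onset_sample if onset_sample is None
            else onset_sample,
        )

    def drop_channels(self, labels: Sequence[str]) -> "Recording":
        """Return a copy without the named channels (e.g. artifactual ones)."""
        drop = set(labels)
        keep = [i for i, c in enumerate(self.channel_labels) if c not in drop]
        if len(keep) == self.n_channels:
            return self
        return Recording(
            data=self.data[keep],
            fs=self.fs,
            channel_labels=[self.channel_labels[i] for i in keep],
            onset_sample=self.onset_sample,
            soz_mask=self.soz_mask[keep],
            meta=dict(self.meta),
        )


@dataclass
class SegmentSet:
    """Non-overlapping, contiguous fixed-length windows cut from one epoch.

    Under the default protocol a 28-s epoch yields seven 4-s segments.
    """

    segments: list[np.ndarray]
    fs: float
    period: str  # "preictal" or "ictal"
    window_s: float
    origin: str = ""

    def __post_init__(self) -> None:
        if self.period not in ("preictal", "ictal"):
            raise ValidationError(f"unknown period {self.period!r}")
        shapes = {s.shape for s in self.segments}
        if len(shapes) > 1:
            raise ValidationError(f"segments differ in shape: {shapes}")

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def save_fixture(path: str | Path, rec: Recording) -> Path:
    """Write a recording to the internal compressed-array fixture format."""
    path = Path(path)
    np.savez_compressed(
        path,
        data=rec.data,
        fs=rec.fs,
        channel_labels=np.array(rec.channel_labels),
        onset_sample=rec.onset_sample,
        soz_mask=rec.soz_mask,
        meta=json.dumps(rec.meta),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def _load_npz(path: Path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        return Recording(
            data=z["data"],
            fs=float(z["fs"]),
            channel_labels=[str(c) for c in z["channel_labels"]],
            onset_sample=int(z["onset_sample"]),
            soz_mask=z["soz_mask"],
            meta=json.loads(str(z["meta"])) if "meta" in z else {},
        )


def _load_edf(path: Path, onset_s: float | None, soz_channels: Sequence[str],
              bad_channels: Sequence[str]) -> Recording:
    import mne  # deferred: only needed for EDF input

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rec = Recording(
        data=raw.get_data() * 1e6,  # MNE loads volts; keep µV-scale units
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        onset_sample=0,
        soz_mask=np.zeros(len(raw.ch_names), dtype=bool),
        meta={"source": str(path)},
    )
    rec = rec.drop_channels(bad_channels)
    if onset_s is None:
        raise ValidationError("EDF input requires an onset annotation "
                              "(missing field: onset)")
    rec.onset_sample = int(round(onset_s * rec.fs))
    rec.soz_mask = np.array([c in set(soz_channels) for c in rec.channel_labels])
    return rec


def _load_bids_ieeg(path: Path) -> Recording:
    """Read a minimal BIDS-iEEG layout: one directory holding the data file
    plus ``*_channels.tsv`` (with a ``status`` column used to drop bad
    channels) and ``*_events.tsv`` (with an ``onset`` column in seconds,
    first row of ``trial_type`` containing 'onset' or first row overall)."""
    channels_tsv = sorted(path.glob("*_channels.tsv"))
    events_tsv = sorted(path.glob("*_events.tsv"))
    if not channels_tsv or not events_tsv:
        raise ValidationError(f"BIDS directory {path} lacks channels/events TSV")
    channels = pd.read_csv(channels_tsv[0], sep="\t")
    events = pd.read_csv(events_tsv[0], sep="\t")

    onset_rows = events
    if "trial_type" in events.columns:
        hits = events[events["trial_type"].astype(str).str.contains(
            "onset", case=False, na=False)]
        if len(hits):
            onset_rows = hits
    if "onset" not in onset_rows.columns or not len(onset_rows):
        raise ValidationError("missing onset annotation in events TSV "
                              "(missing field: onset)")
    onset_s = float(onset_rows["onset"].iloc[0])

    bad = []
    if "status" in channels.columns:
        bad = channels.loc[
            channels["status"].astype(str).str.lower() != "good", "name"
        ].astype(str).tolist()
    soz = []
    if "soz" in channels.columns:
        soz = channels.loc[channels["soz"].astype(bool), "name"].astype(str).tolist()

    data_files = sorted(path.glob("*_ieeg.edf")) + sorted(path.glob("*_ieeg.npz"))
    if not data_files:
        raise ValidationError(f"no *_ieeg.edf or *_ieeg.npz data file in {path}")
    data_file = data_files[0]
    if data_file.suffix == ".npz":
        rec = _load_npz(data_file)
        rec = rec.drop_channels(bad)
        rec.onset_sample = int(round(onset_s * rec.fs))
        if soz:
            rec.soz_mask = np.array([c in set(soz) for c in rec.channel_labels])
        return rec
    return _load_edf(data_file, onset_s, soz, bad)


def load_recording(path: str | Path, format: str | None = None, *,
                   onset_s: float | None = None,
                   soz_channels: Sequence[str] = (),
                   bad_channels: Sequence[str] = ()) -> Recording:
    """Load a recording from disk.

    Parameters
    ----------
    path : path
        File (``.edf``/``.npz``) or BIDS-iEEG-style directory.
    format : {"edf", "bids_ieeg", "npz_fixture"}, optional
        Inferred from the path when omitted.
    onset_s, soz_channels, bad_channels
        Sidecar annotations for bare EDF files, which carry none themselves.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if format is None:
        if path.is_dir():
            format = "bids_ieeg"
        elif path.suffix == ".edf":
            format = "edf"
        elif path.suffix == ".npz":
            format = "npz_fixture"
        else:
            raise ValidationError(f"cannot infer format of {path}")
    if format == "npz_fixture":
        rec = _load_npz(path)
        return rec.drop_channels(bad_channels)
    if format == "edf":
        return _load_edf(path, onset_s, soz_channels, bad_channels)
    if format == "bids_ieeg":
        return _load_bids_ieeg(path)
    raise ValidationError(f"unknown format {format!r}")
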