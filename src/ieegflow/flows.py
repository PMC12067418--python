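"""Per-channel inflow/outflow (weighted in-/out-strength) and their
dynamics across the seven analysis segments.

With the convention weights(i, j) = flow j -> i, a channel's inflow is its
row sum and its outflow its column sum, self-connections excluded.  Scores
are min-max normalized within each segment across channels so the 0-1 ROC
threshold sweep is well defined segment by segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .recording import ValidationError


@dataclass
class FlowSeries:
    """Normalized per-channel flow scores across segments.

    ``values[s, c]`` is channel c's normalized score in segment s; every row
    spans [0, 1] unless that segment's raw scores were constant (then 0).
    """

    method: str
    measure: str  # "inflow" or "outflow"
    period: str  # "preictal" or "ictal"
    values: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    soz_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be (n_segments, n_channels)")
        if self.soz_mask is not None:
            self.soz_mask = np.asarray(self.soz_mask, dtype=bool)
            if self.soz_mask.size != self.values.shape[1]:
                raise ValidationError("soz_mask length mismatch")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def soz_values(self) -> np.ndarray:
        """All SOZ-channel scores pooled across segments (flattened)."""
        return self.values[:, self.soz_mask].ravel()

    def non_soz_values(self) -> np.ndarray:
        return self.values[:, ~self.soz_mask].ravel()

    def channel_scores(self, pooling: str = "median") -> np.ndarray:
        """One score per channel, pooled over segments (default: median)."""
        if pooling == "median":
            return np.median(self.values, axis=0)
        if pooling == "mean":
            return self.values.mean(axis=0)
        raise ValueError(f"unknown pooling {pooling!r}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (segment, channel)."""
        n_seg, n_ch = self.values.shape
        labels = self.channel_labels or [str(i) for i in range(n_ch)]
        soz = self.soz_mask if self.soz_mask is not None \
            else np.zeros(n_ch, bool)
        rows = []
        for s in range(n_seg):
            for c in range(n_ch):
                rows.append((s, labels[c], self.method, self.measure,
                             self.period, self.values[s, c], bool(soz[c])))
        return pd.DataFrame(rows, columns=[
            "segment", "channel", "method", "measure", "period",
            "normalized_value", "is_soz"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def inflow(conn: ConnectivityMatrix) -> np.ndarray:
    """Weighted in-strength: inflow(i) = sum_{j != i} weights(i, j)."""
    w = conn.weights.copy()
    np.fill_diagonal(w, 0.0)
    return w.sum(axis=1)


def outflow(conn: ConnectivityMatrix) -> np.ndarray:
    """Weighted out-strength: outflow(j) = sum_{i != j} weights(i, j)."""
    w = conn.weights.copy()
    np.fill_diagonal(w, 0.0)
    return w.sum(axis=0)


def normalize_scores(values: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant vector maps to all zeros."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def assemble_flow_series(conns: list[ConnectivityMatrix], measure: str,
                         soz_mask: np.ndarray | None = None,
                         channel_labels: list[str] | None = None) -> FlowSeries:
    """Stack per-segment normalized flow scores into one FlowSeries."""
    if not conns:
        raise ValidationError("no connectivity matrices supplied")
    reducer = {"inflow": inflow, "outflow": outflow}.get(measure)
    if reducer is None:
        raise ValueError(f"unknown measure {measure!r}")
    n = conns[0].n_channels
    labels = channel_labels or conns[0].channel_labels
    for c in conns:
        if c.n_channels != n or (c.channel_labels and labels
                                 and c.channel_labels != labels):
            raise ValidationError("segments disagree on channel set")
    values = np.stack([normalize_scores(reducer(c)) for c in conns])
    return FlowSeries(method=conns[0].method, measure=measure,
                      period=conns[0].period, values=values,
                      channel_labels=list(labels) if labels else [],
                      soz_mask=soz_mask)
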