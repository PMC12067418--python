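"""Frequency-domain directed connectivity from a fitted MVAR model.

Partial directed coherence (PDC) is the column-normalized magnitude of the
Fourier-transformed coefficient matrix

    Abar(f) = I - sum_k A_k exp(-i 2 pi f k / fs),
    PDC_{ij}(f) = |Abar_{ij}(f)| / sqrt(sum_m |Abar_{mj}(f)|^2),

and the directed transfer function (DTF) is the row-normalized magnitude of
the transfer matrix H(f) = Abar(f)^{-1}:

    DTF_{ij}(f) = |H_{ij}(f)| / sqrt(sum_m |H_{im}(f)|^2).

Both use the orientation convention that entry (i, j) measures the influence
of source channel j on target channel i, so inflow is a row sum and outflow
a column sum of any derived matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .mvar import MVARModel

DEFAULT_BAND = (3.0, 45.0)


def default_freq_grid(low: float = 3.0, high: float = 45.0,
                      step: float = 0.5) -> np.ndarray:
    """Inclusive frequency grid over the analysis band (85 bins at defaults)."""
    n = int(round((high - low) / step))
    return low + step * np.arange(n + 1)


@dataclass
class SpectralConnectivity:
    """Directed connectivity magnitudes on a frequency grid.

    ``values[f, i, j]`` is the influence of channel j on channel i at
    ``freqs[f]``; all entries lie in [0, 1].
    """

    method: str
    freqs: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.method not in ("pdc", "dtf"):
            raise ValueError(f"unknown method {self.method!r}")
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.freqs.size:
            raise ValueError("values first axis must match freqs")


@dataclass
class ConnectivityMatrix:
    """Band-aggregated directed weights; entry (i, j) is flow j -> i."""

    method: str
    band: tuple[float, float]
    weights: np.ndarray
    thresholded: bool = False
    segment_index: int = -1
    period: str = ""
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    def to_csv(self, path: str | Path) -> None:
        """Square CSV with channel labels plus a JSON metadata sidecar."""
        path = Path(path)
        labels = self.channel_labels or [str(i) for i in range(self.n_channels)]
        pd.DataFrame(self.weights, index=labels, columns=labels).to_csv(path)
        sidecar = {
            "method": self.method,
            "band": list(self.band),
            "segment_index": self.segment_index,
            "period": self.period,
            "thresholded": self.thresholded,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def fourier_coefficient_matrix(model: MVARModel,
                               freqs: np.ndarray) -> np.ndarray:
    """Abar(f) = I - sum_k A_k exp(-i 2 pi f k / fs), shape (F, n, n)."""
    freqs = np.asarray(freqs, dtype=float)
    p, n = model.order, model.n_channels
    lags = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / model.fs)  # (F, p)
    abar = np.eye(n)[None] - np.einsum("fk,kij->fij", phase, model.coeffs)
    return abar


def transfer_function(model: MVARModel, freqs: np.ndarray) -> np.ndarray:
    """H(f) = Abar(f)^{-1}, shape (F, n, n)."""
    abar = fourier_coefficient_matrix(model, freqs)
    with np.errstate(all="ignore"):
        try:
            H = np.linalg.inv(abar)
        except np.linalg.LinAlgError:
            H = None
    if H is None or not np.all(np.isfinite(H)):
        for k, f in enumerate(np.asarray(freqs, float)):
            if abs(np.linalg.det(abar[k])) < 1e-300:
                raise np.linalg.LinAlgError(
                    f"Abar(f) singular at f={f:g} Hz")
        raise np.linalg.LinAlgError("Abar(f) numerically singular")
    return H


def pdc(model: MVARModel, freqs: np.ndarray | None = None) -> SpectralConnectivity:
    """Partial directed coherence: column-normalized |Abar(f)|."""
    if freqs is None:
        freqs = default_freq_grid()
    abar = np.abs(fourier_coefficient_matrix(model, freqs))
    col_norm = np.sqrt((abar ** 2).sum(axis=1, keepdims=True))  # over targets i
    if np.any(col_norm == 0):
        raise FloatingPointError("zero column norm in PDC normalization")
    return SpectralConnectivity("pdc", freqs, abar / col_norm)


def dtf(model: MVARModel, freqs: np.ndarray | None = None) -> SpectralConnectivity:
    """Directed transfer function: row-normalized |H(f)|."""
    if freqs is None:
        freqs = default_freq_grid()
    H = np.abs(transfer_function(model, freqs))
    row_norm = np.sqrt((H ** 2).sum(axis=2, keepdims=True))  # over sources j
    if np.any(row_norm == 0):
        raise FloatingPointError("zero row norm in DTF normalization")
    return SpectralConnectivity("dtf", freqs, H / row_norm)


def band_aggregate(spec: SpectralConnectivity,
                   band: tuple[float, float] = DEFAULT_BAND,
                   **matrix_kwargs) -> ConnectivityMatrix:
    """Mean connectivity magnitude over grid frequencies inside ``band``.

    The diagonal (self-prediction) is zeroed; downstream strength metrics
    never consume it.
    """
    low, high = band
    mask = (spec.freqs >= low) & (spec.freqs <= high)
    if not mask.any():
        raise ValueError(f"no grid frequencies inside band {band}")
    weights = spec.values[mask].mean(axis=0)
    np.fill_diagonal(weights, 0.0)
    return ConnectivityMatrix(method=spec.method, band=(low, high),
                              weights=weights, **matrix_kwargs)
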