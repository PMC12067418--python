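"""Phase-randomization surrogate testing for directed edges.

Each surrogate keeps every channel's amplitude spectrum but replaces the
phases of its positive-frequency Fourier coefficients with independent
uniform draws (independently per channel), destroying temporal and
cross-channel correlation while preserving the spectral content.  Fitting
the same-order MVAR and connectivity estimator to many surrogates yields an
empirical null distribution per directed edge; an edge survives only if its
observed weight strictly exceeds the null's (1 - alpha) quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import (ConnectivityMatrix, band_aggregate, dtf, pdc,
                           default_freq_grid)
from .mvar import fit_mvar
from .recording import ValidationError

DEFAULT_N_SURROGATES = 100
DEFAULT_ALPHA = 0.05


@dataclass
class SurrogateNull:
    """Null distribution of band-aggregated connectivity for one segment."""

    method: str
    null_weights: np.ndarray  # (n_surrogates, n, n)
    alpha: float = DEFAULT_ALPHA

    @property
    def n_surrogates(self) -> int:
        return self.null_weights.shape[0]

    def quantile(self) -> np.ndarray:
        """Per-edge empirical (1 - alpha) quantile, taken as the order
        statistic at ceil((1 - alpha) * n_surrogates)."""
        k = int(np.ceil((1.0 - self.alpha) * self.n_surrogates))
        k = min(max(k, 1), self.n_surrogates)
        ordered = np.sort(self.null_weights, axis=0)
        return ordered[k - 1]


def phase_randomize(segment: np.ndarray,
                    seed: int | np.random.Generator) -> np.ndarray:
    """Return a phase-randomized surrogate with identical per-channel
    amplitude spectra.  DC and (for even length) Nyquist bins stay real."""
    segment = np.asarray(segment, dtype=float)
    n, T = segment.shape
    if T < 4:
        raise ValueError("segment too short to phase-randomize")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    spec = np.fft.rfft(segment, axis=1)
    n_bins = spec.shape[1]
    # interior bins get fresh phases; bin 0 (DC) and, for even T, the last
    # (Nyquist) bin must stay real for the inverse transform to be real
    hi = n_bins - 1 if T % 2 == 0 else n_bins
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n, hi - 1))
    spec[:, 1:hi] = np.abs(spec[:, 1:hi]) * np.exp(1j * phases)
    return np.fft.irfft(spec, n=T, axis=1)


def _surrogate_weights(segment: np.ndarray, model_order: int, methods,
                       band, freqs, fs: float, n_surrogates: int,
                       seed: int) -> dict[str, np.ndarray]:
    """Stack of null band-aggregated weights per method, sharing one MVAR
    fit per surrogate across methods."""
    n = segment.shape[0]
    out = {m: np.empty((n_surrogates, n, n)) for m in methods}
    streams = np.random.SeedSequence(seed).spawn(n_surrogates)
    for s, stream in enumerate(streams):
        surr = phase_randomize(segment, np.random.default_rng(stream))
        try:
            model = fit_mvar(surr, model_order, fs=fs)
            for m in methods:
                spec = pdc(model, freqs) if m == "pdc" else dtf(model, freqs)
                out[m][s] = band_aggregate(spec, band).weights
        except Exception as err:  # propagate with provenance
            raise RuntimeError(f"surrogate {s} failed: {err}") from err
    return out


def build_null(segment: np.ndarray, model_order: int, method: str = "pdc",
               band: tuple[float, float] = (3.0, 45.0),
               n_surrogates: int = DEFAULT_N_SURROGATES,
               seed: int = 0, fs: float = 500.0,
               freqs: np.ndarray | None = None,
               alpha: float = DEFAULT_ALPHA) -> SurrogateNull:
    """Null distribution for one segment and one estimator.

    The surrogate MVAR order is pinned to the original segment's selected
    order so model complexity is held constant under the null.
    """
    nulls = build_nulls(segment, model_order, (method,), band=band,
                        n_surrogates=n_surrogates, seed=seed, fs=fs,
                        freqs=freqs, alpha=alpha)
    return nulls[method]


def build_nulls(segment: np.ndarray, model_order: int,
                methods=("pdc", "dtf"),
                band: tuple[float, float] = (3.0, 45.0),
                n_surrogates: int = DEFAULT_N_SURROGATES,
                seed: int = 0, fs: float = 500.0,
                freqs: np.ndarray | None = None,
                alpha: float = DEFAULT_ALPHA) -> dict[str, SurrogateNull]:
    """Like :func:`build_null` but computes several estimators per surrogate
    realization, reusing each surrogate's MVAR fit."""
    if freqs is None:
        freqs = default_freq_grid(band[0], band[1])
    weights = _surrogate_weights(np.asarray(segment, float), model_order,
                                 tuple(methods), band, freqs, fs,
                                 int(n_surrogates), int(seed))
    return {m: SurrogateNull(method=m, null_weights=w, alpha=alpha)
            for m, w in weights.items()}


def threshold_connectivity(conn: ConnectivityMatrix, null: SurrogateNull,
                           alpha: float | None = None) -> ConnectivityMatrix:
    """Zero every edge not strictly above its null (1 - alpha) quantile."""
    if conn.method != null.method:
        raise ValidationError(
            f"method mismatch: {conn.method} vs {null.method}")
    if conn.weights.shape != null.null_weights.shape[1:]:
        raise ValidationError("connectivity / null shape mismatch")
    if alpha is not None and alpha != null.alpha:
        null = SurrogateNull(null.method, null.null_weights, alpha=alpha)
    q = null.quantile()
    kept = np.where(conn.weights > q, conn.weights, 0.0)
    np.fill_diagonal(kept, 0.0)
    return ConnectivityMatrix(
        method=conn.method, band=conn.band, weights=kept, thresholded=True,
        segment_index=conn.segment_index, period=conn.period,
        channel_labels=list(conn.channel_labels))
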