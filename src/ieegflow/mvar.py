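"""Multivariate autoregressive (MVAR) model fitting, order selection,
stability checking, and simulation.

The model is x_t = sum_{k=1..p} A_k x_{t-k} + e_t with Gaussian innovations
e_t ~ N(0, Sigma).  Coefficients are estimated by ordinary least squares on
the lagged design matrix; order selection minimizes Schwarz's Bayesian
criterion (SBC, default) or the Akaike information criterion (AIC) over the
same data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


class EstimationError(RuntimeError):
    pass


@dataclass
class MVARModel:
    """Fitted (or constructed) MVAR model for one quasi-stationary segment.

    ``coeffs`` has shape (p, n, n) with ``coeffs[k-1][i][j]`` the effect of
    channel j at lag k on channel i.  ``noise_cov`` is the innovation
    covariance Sigma.
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    fs: float = 1.0
    n_samples_fit: int = 0

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_3d(np.asarray(self.coeffs, dtype=float))
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError("coeffs must have shape (p, n, n)")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coeffs must be finite")
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        n = self.coeffs.shape[1]
        if self.noise_cov.shape != (n, n):
            raise ValueError("noise_cov shape must match coeffs")
        asym = np.abs(self.noise_cov - self.noise_cov.T).max()
        if asym > 1e-9 * max(1.0, np.abs(self.noise_cov).max()):
            raise ValueError(f"noise_cov not symmetric (max asym {asym:g})")
        self.noise_cov = 0.5 * (self.noise_cov + self.noise_cov.T)

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        """The (n p) x (n p) companion matrix of the lag polynomial."""
        p, n = self.order, self.n_channels
        top = self.coeffs.transpose(1, 0, 2).reshape(n, n * p)
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = top
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return comp


def _lagged_design(segment: np.ndarray, p: int,
                   offset: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Return (Y, Z): targets (n, T-offset) and stacked lags (n*p, T-offset).

    ``offset`` defaults to ``p``; a larger offset lets several orders be
    compared on an identical sample.
    """
    n, T = segment.shape
    off = p if offset is None else offset
    Y = segment[:, off:]
    Z = np.concatenate([segment[:, off - k:T - k] for k in range(1, p + 1)],
                       axis=0)
    return Y, Z


def _solve_ls(Z: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Solve Y = B Z in the least-squares sense via the normal equations
    (fast path); falls back to SVD least squares when the Gram matrix is
    not numerically positive definite."""
    from scipy import linalg as sla

    G = Z @ Z.T
    C = Y @ Z.T
    try:
        cho = sla.cho_factor(G, lower=True, check_finite=False)
        return sla.cho_solve(cho, C.T, check_finite=False).T
    except sla.LinAlgError:
        B, _, rank, sv = np.linalg.lstsq(Z.T, Y.T, rcond=None)
        if rank < Z.shape[0]:
            cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
            raise EstimationError(
                f"singular regressor matrix (rank {rank}/{Z.shape[0]}, "
                f"condition estimate {cond:.3g})")
        return B.T


def fit_mvar(segment: np.ndarray, order: int, fs: float = 1.0) -> MVARModel:
    """Least-squares fit of an order-``order`` MVAR to one segment.

    The residual covariance uses the unbiased denominator
    ``T_eff - n*order`` where ``T_eff = T - order`` is the number of
    regression rows.
    """
    segment = np.asarray(segment, dtype=float)
    n, T = segment.shape
    p = int(order)
    if p < 1:
        raise ValueError("order must be >= 1")
    if T <= n * p + p:
        raise ValueError(
            f"segment too short (T={T}) for n={n}, p={p} least squares")
    Y, Z = _lagged_design(segment, p)
    B = _solve_ls(Z, Y)
    resid = Y - B @ Z
    dof = Y.shape[1] - n * p
    sigma = (resid @ resid.T) / dof
    coeffs = np.stack([B[:, k * n:(k + 1) * n] for k in range(p)])
    return MVARModel(coeffs=coeffs, noise_cov=sigma, fs=fs,
                     n_samples_fit=T)


def _criterion_values(segment: np.ndarray, p_min: int, p_max: int,
                      criterion: str) -> np.ndarray:
    """Information-criterion value for each order, all fitted on the sample
    starting at ``p_max`` so the criteria are comparable across orders."""
    segment = np.asarray(segment, dtype=float)
    n, T = segment.shape
    t_eff = T - p_max
    if t_eff <= n * p_max:
        raise ValueError(
            f"segment too short (T={T}) for order scan up to p={p_max}")
    from scipy import linalg as sla

    _, Z_full = _lagged_design(segment, p_max, offset=p_max)
    Y = segment[:, p_max:]
    # one Gram computation serves every candidate order (leading blocks)
    G_full = Z_full @ Z_full.T
    C_full = Y @ Z_full.T
    YY = Y @ Y.T
    values = np.full(p_max - p_min + 1, np.nan)
    for idx, p in enumerate(range(p_min, p_max + 1)):
        d = n * p
        try:
            cho = sla.cho_factor(G_full[:d, :d], lower=True,
                                 check_finite=False)
            B = sla.cho_solve(cho, C_full[:, :d].T, check_finite=False).T
        except sla.LinAlgError:
            continue
        sigma_ml = (YY - B @ C_full[:, :d].T) / t_eff
        sign, logdet = np.linalg.slogdet(sigma_ml)
        if sign <= 0:
            continue
        k_params = p * n * n
        if criterion == "sbc":
            values[idx] = logdet + k_params * np.log(t_eff) / t_eff
        elif criterion == "aic":
            values[idx] = logdet + 2.0 * k_params / t_eff
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
    return values


def select_order(segment: np.ndarray, p_min: int = 1, p_max: int = 20,
                 criterion: str = "sbc") -> int:
    """Pick the MVAR order minimizing SBC or AIC; ties go to the smaller p."""
    if p_min > p_max:
        raise ValueError("p_min must be <= p_max")
    if p_min == p_max:
        return p_min
    values = _criterion_values(segment, p_min, p_max, criterion)
    if np.all(np.isnan(values)):
        raise EstimationError("criterion non-finite at every candidate order")
    return p_min + int(np.nanargmin(values))


def is_stable(model: MVARModel, radius: float = 1.0) -> bool:
    """True iff the companion-matrix spectral radius is below ``radius``."""
    eigs = np.linalg.eigvals(model.companion())
    return bool(np.max(np.abs(eigs)) < radius)


def spectral_radius(model: MVARModel) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(model.companion()))))


def simulate_mvar(model: MVARModel, n_samples: int, seed: int | np.random.Generator,
                  burn_in: int = 1000,
                  initial: np.ndarray | None = None) -> np.ndarray:
    """Simulate ``n_samples`` observations from a stable MVAR model.

    Gaussian innovations with covariance ``noise_cov`` are drawn from a
    generator seeded by ``seed``; the first ``burn_in`` samples are
    discarded (skipped when ``initial`` supplies a warm state of shape
    (n, order)).
    """
    if not is_stable(model):
        raise ValueError("refusing to simulate an unstable MVAR model")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    p, n = model.order, model.n_channels
    # PSD-safe innovation factor (noise_cov may be singular).
    w, V = np.linalg.eigh(model.noise_cov)
    factor = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    if initial is not None:
        warm = np.asarray(initial, dtype=float)
        if warm.shape != (n, p):
            raise ValueError(f"initial state must have shape ({n}, {p})")
        burn_in = 0
    else:
        warm = np.zeros((n, p))
    total = burn_in + n_samples
    innov = factor @ rng.standard_normal((n, total))
    x = np.empty((n, p + total))
    x[:, :p] = warm
    A = model.coeffs
    for t in range(total):
        acc = innov[:, t].copy()
        for k in range(p):
            acc += A[k] @ x[:, p + t - 1 - k]
        x[:, p + t] = acc
    return x[:, p + burn_in:]
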