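"""Ground-truth-labelled synthetic iEEG cohorts.

Recordings are simulated from order-2 MVAR networks in which a designated
SOZ channel subset acts as a net sink (inflow-dominant regime), a net
source (outflow-dominant regime), or is exchangeable with the rest of the
network (null regime).  Directed coupling may ramp up linearly across the
seven preictal segments, emulating flow that rises as seizure onset
approaches; the ictal block reuses the final preictal network with doubled
coupling.  Every generated model is checked for stability, and all
randomness is reproducible from a single seed.

These are statistical surrogates for iEEG, not biophysical seizure models:
they match the stationarity, spectral-band and directed-coupling structure
the analysis assumes, but contain no spikes, DC shifts or high-frequency
oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mvar import MVARModel, simulate_mvar, spectral_radius
from .recording import Recording

REGIMES = ("inflow_dominant", "outflow_dominant", "null")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic seizure recording.

    ``coupling`` is the off-diagonal MVAR coefficient magnitude of the
    planted directed edges; ``n_links`` edges are planted per SOZ channel.
    With ``ramp`` the coupling scales linearly from half strength in the
    first preictal segment to full strength at onset.  ``bg_edges``
    stationary degree-balanced background edges (stacked derangements, not
    ramped) can be added underneath the regime structure so SOZ channels
    stand out only relative to ambient connectivity, as in real networks.
    """

    n_channels: int
    n_soz: int
    regime: str
    coupling: float = 0.4
    ramp: bool = True
    n_links: int = 3
    bg_edges: int = 0
    fs: float = 500.0
    preictal_s: float = 28.0
    ictal_s: float = 28.0
    pad_s: float = 4.0
    window_s: float = 4.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0 < self.n_soz < self.n_channels:
            raise ValueError("need 0 < n_soz < n_channels")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")

    @property
    def n_segments(self) -> int:
        return int(round(self.preictal_s / self.window_s))


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream scoring."""

    soz_mask: np.ndarray
    regime: str
    expected_measure: str | None  # dominant measure, None for the null regime
    models: list[MVARModel] = field(default_factory=list)
    ictal_model: MVARModel | None = None


def _planted_edges(spec: SyntheticSpec) -> list[tuple[int, int]]:
    """Directed (target, source) pairs, drawn reproducibly from the spec seed
    so every segment of a recording shares one network structure."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    soz = np.arange(spec.n_soz)
    non = np.arange(spec.n_soz, spec.n_channels)
    edges: list[tuple[int, int]] = []
    if spec.regime == "inflow_dominant":
        for i in soz:
            sources = rng.choice(non, size=min(spec.n_links, non.size),
                                 replace=False)
            edges += [(int(i), int(j)) for j in sources]
    elif spec.regime == "outflow_dominant":
        for j in soz:
            targets = rng.choice(non, size=min(spec.n_links, non.size),
                                 replace=False)
            edges += [(int(i), int(j)) for i in targets]
    else:
        # null: a random derangement, so every channel has in-degree =
        # out-degree = 1 and no channel-level flow asymmetry exists even
        # per realization, only estimation noise
        n = spec.n_channels
        perm = _random_derangement(rng, n)
        edges = [(int(i), int(perm[i])) for i in range(n)]
    return edges


def _random_derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    perm = rng.permutation(n)
    while np.any(perm == np.arange(n)):
        perm = rng.permutation(n)
    return perm


def _background_edges(spec: SyntheticSpec) -> list[tuple[int, int]]:
    """Stationary degree-balanced background edges.

    Stacked random derangements give every channel identical background
    in- and out-degree, so ambient connectivity raises the flow floor
    without injecting channel-level degree noise that would swamp the
    planted SOZ asymmetry.
    """
    if spec.bg_edges <= 0:
        return []
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 105]))
    n = spec.n_channels
    edges: list[tuple[int, int]] = []
    rounds = int(np.ceil(spec.bg_edges / n))
    for _ in range(rounds):
        perm = _random_derangement(rng, n)
        edges += [(int(i), int(perm[i])) for i in range(n)]
    return edges[:spec.bg_edges]


def _ramp_factor(spec: SyntheticSpec, segment_index: int) -> float:
    if not spec.ramp or spec.n_segments == 1:
        return 1.0
    return 0.5 + 0.5 * segment_index / (spec.n_segments - 1)


def make_network(spec: SyntheticSpec, segment_index: int,
                 coupling_scale: float = 1.0) -> MVARModel:
    """Order-2 MVAR network for one segment of a synthetic recording.

    Each channel carries stable oscillatory AR(2) self-dynamics: a complex
    pole pair of modulus 0.85 at a channel-specific frequency drawn from
    6-20 Hz, inside the 3-45 Hz analysis band so band-pass filtering
    leaves the dynamics (and hence the directed structure) intact.
    Planted directed edges enter at lag 1 with magnitude
    ``coupling * ramp * coupling_scale``; innovations are unit-variance
    white noise.  Off-diagonal mass is rescaled (at most 20 times) until
    the companion spectral radius is at most 0.95.
    """
    n = spec.n_channels
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 104]))
    A = np.zeros((2, n, n))
    rho = 0.85
    f0 = rng.uniform(6.0, 20.0, size=n)
    A[0][np.diag_indices(n)] = 2 * rho * np.cos(2 * np.pi * f0 / spec.fs)
    A[1][np.diag_indices(n)] = -rho ** 2
    strength = spec.coupling * _ramp_factor(spec, segment_index) * coupling_scale
    off = np.zeros((n, n))
    for (i, j) in _background_edges(spec):
        # ambient network: constant across segments, well below the
        # planted strength so the regime structure stands out but rides on
        # nonzero ambient flow
        off[i, j] = 0.3 * spec.coupling
    for (i, j) in _planted_edges(spec):
        off[i, j] = strength
    for _ in range(20):
        model = MVARModel(coeffs=A + np.array([off, np.zeros_like(off)]),
                          noise_cov=np.eye(n), fs=spec.fs)
        if spectral_radius(model) <= 0.95:
            return model
        off *= 0.8
    raise RuntimeError("could not stabilize synthetic network in 20 rescalings")


def generate_recording(spec: SyntheticSpec) -> tuple[Recording, GroundTruth]:
    """Simulate one seizure recording with known ground truth.

    Each preictal 4-s segment is driven by its own (ramped) network; the
    recursion state carries over between segments so the signal is
    continuous.  The ictal block reuses the final preictal network with
    doubled coupling.  White observation noise of sd ``noise_sd`` is added
    on top of the MVAR process.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    n_win = int(round(spec.window_s * spec.fs))
    models = [make_network(spec, s) for s in range(spec.n_segments)]
    ictal_model = make_network(spec, spec.n_segments - 1, coupling_scale=2.0)

    blocks = []
    state = None
    # lead-in pad (first-segment dynamics) so the recording clears the
    # >=30 s preictal inclusion rule while the analysed epoch stays 28 s
    n_pad = int(round(spec.pad_s * spec.fs))
    if n_pad > 0:
        x = simulate_mvar(models[0], n_pad, rng, burn_in=1000)
        blocks.append(x)
        state = x[:, -models[0].order:]
    for s, model in enumerate(models):
        x = simulate_mvar(model, n_win, rng,
                          burn_in=1000 if state is None else 0,
                          initial=state)
        blocks.append(x)
        state = x[:, -model.order:]
    n_ictal = int(round(spec.ictal_s * spec.fs))
    if n_ictal > 0:
        blocks.append(simulate_mvar(ictal_model, n_ictal, rng, burn_in=0,
                                    initial=state))
    data = np.concatenate(blocks, axis=1)
    # normalize delivered per-channel gain: a linear rescale that preserves
    # the zero/nonzero coupling structure exactly while keeping strongly
    # driven channels on the same amplitude scale as the rest (so the
    # pipeline's z-score cannot reweight the network), then add sensor noise
    data /= data.std(axis=1, keepdims=True)
    data += spec.noise_sd * rng.standard_normal(data.shape)

    soz_mask = np.zeros(spec.n_channels, dtype=bool)
    soz_mask[:spec.n_soz] = True
    expected = {"inflow_dominant": "inflow",
                "outflow_dominant": "outflow",
                "null": None}[spec.regime]
    rec = Recording(
        data=data, fs=spec.fs,
        channel_labels=[f"ch{c:02d}" for c in range(spec.n_channels)],
        onset_sample=n_pad + spec.n_segments * n_win,
        soz_mask=soz_mask,
        meta={"dataset": "synthetic", "regime": spec.regime,
              "seed": spec.seed},
    )
    truth = GroundTruth(soz_mask=soz_mask, regime=spec.regime,
                        expected_measure=expected, models=models,
                        ictal_model=ictal_model)
    return rec, truth


def _regime_counts(n_patients: int, regime_mix: dict[str, float]) -> list[str]:
    total = sum(regime_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"regime proportions sum to {total:g}, expected 1")
    regimes = sorted(regime_mix)
    raw = {r: regime_mix[r] * n_patients for r in regimes}
    counts = {r: int(np.floor(raw[r])) for r in regimes}
    # largest-remainder rounding keeps the requested mix as close as possible
    leftover = n_patients - sum(counts.values())
    for r in sorted(regimes, key=lambda r: raw[r] - counts[r], reverse=True):
        if leftover <= 0:
            break
        counts[r] += 1
        leftover -= 1
    out: list[str] = []
    for r in regimes:
        out += [r] * counts[r]
    return out


def generate_cohort(n_patients: int, regime_mix: dict[str, float],
                    base_seed: int = 0,
                    channels_range: tuple[int, int] = (10, 16),
                    seizures_range: tuple[int, int] = (2, 3),
                    coupling: float | tuple[float, float] = (0.2, 0.45),
                    noise_sd: float = 0.5,
                    ramp: bool = True,
                    preictal_s: float = 28.0, ictal_s: float = 28.0,
                    ) -> list[tuple[Recording, GroundTruth]]:
    """Generate a reproducible multi-patient cohort.

    Channel counts are drawn uniformly over ``channels_range`` and each
    patient contributes ``seizures_range`` seizures; roughly 20% of
    channels (at least 2) form the SOZ.  ``coupling`` may be a scalar or a
    (low, high) range sampled per patient: clinical cohorts show wide
    effect-size heterogeneity (weakly coupled patients hover near chance
    and stay unclassified), and the default range reproduces that spread.
    The desk-scale default of 10-16 channels keeps MVAR fits
    well-conditioned on 4-s windows; pass ``channels_range=(45, 176)`` to
    emulate clinical implant sizes.  Patients also receive effect-free
    ``implant`` and ``lesional`` metadata for stratified-comparison
    exercises.
    """
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 303]))
    regimes = _regime_counts(n_patients, regime_mix)
    rng.shuffle(regimes)
    cohort: list[tuple[Recording, GroundTruth]] = []
    implants = ("ecog", "seeg", "grid_strip_depth")
    for pat, regime in enumerate(regimes):
        n_ch = int(rng.integers(channels_range[0], channels_range[1] + 1))
        n_soz = max(3, int(round(0.2 * n_ch)))
        n_seiz = int(rng.integers(seizures_range[0], seizures_range[1] + 1))
        implant = implants[int(rng.integers(len(implants)))]
        lesional = bool(rng.integers(2))
        if np.ndim(coupling) == 0:
            pat_coupling = float(coupling)
        else:
            pat_coupling = float(rng.uniform(coupling[0], coupling[1]))
        # heterogeneous SOZ prominence: a patient either expresses the
        # regime (planted SOZ links) or shows no detectable asymmetry at
        # all, as most clinical patients do
        pat_links = int(rng.choice([0, 3], p=[0.5, 0.5]))
        pat_bg = int(round(0.75 * n_ch))
        for seiz in range(n_seiz):
            spec = SyntheticSpec(
                n_channels=n_ch, n_soz=n_soz, regime=regime,
                coupling=pat_coupling, noise_sd=noise_sd, ramp=ramp,
                n_links=pat_links, bg_edges=pat_bg,
                preictal_s=preictal_s, ictal_s=ictal_s,
                seed=int(rng.integers(2 ** 31)))
            rec, truth = generate_recording(spec)
            rec.meta.update({"patient_id": f"synpt{pat:03d}",
                             "seizure_id": f"synpt{pat:03d}_sz{seiz}",
                             "implant": implant, "lesional": lesional})
            cohort.append((rec, truth))
    return cohort
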