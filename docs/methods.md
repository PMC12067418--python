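# Methods

`ieegflow` implements a preictal directed-connectivity analysis of
intracranial EEG: multivariate autoregressive (MVAR) modelling of short
quasi-stationary windows, partial directed coherence (PDC) and the directed
transfer function (DTF) as spectral estimators of directed influence,
phase-randomization surrogate pruning of spurious edges, per-channel
inflow/outflow dynamics, ROC/AUC discrimination of seizure-onset-zone (SOZ)
channels, and classification of recordings into inflow-dominant versus
outflow-dominant preictal regimes.

## Model and protocol

Each 4-s window of the preprocessed recording is modelled as an order-p MVAR
process

    x_t = sum_{k=1..p} A_k x_{t-k} + e_t,    e_t ~ N(0, Sigma),

with `A_k[i][j]` the lag-k effect of channel j on channel i. Coefficients
are estimated by ordinary least squares on the lagged design (solved through
the normal equations with a Cholesky factorization; an SVD least-squares
fallback handles ill-conditioned designs). The innovation covariance uses
the unbiased denominator `T_eff − n·p` with `T_eff = T − p` regression rows.

The model order minimizes Schwarz's Bayesian criterion by default
(`ln det Σ̂_p + p n² ln(T_eff)/T_eff`); AIC is available. All candidate
orders are fitted on the common sample starting at `p_max` so the criteria
are comparable; ties break toward the smaller order. Unstable fitted models
(companion spectral radius ≥ 1) are flagged with a warning but retained —
connectivity remains computable and discarding windows would bias the
dynamics.

From the Fourier-transformed coefficient matrix
`Ā(f) = I − Σ_k A_k exp(−i2πfk/fs)` and the transfer matrix `H(f) = Ā(f)⁻¹`:

    PDC_{ij}(f) = |Ā_{ij}(f)| / sqrt(Σ_m |Ā_{mj}(f)|²)   (column-normalized)
    DTF_{ij}(f) = |H_{ij}(f)| / sqrt(Σ_m |H_{im}(f)|²)   (row-normalized)

Entry (i, j) always means influence of source j on target i, so inflow is a
row sum and outflow a column sum of any derived matrix. Magnitudes are
averaged over an inclusive 3–45 Hz grid at 0.5 Hz steps (85 bins,
resolution matched to the 4-s window); averaging magnitudes rather than
squared magnitudes keeps weights in [0, 1] and is configurable.

### Protocol constants (defaults)

| parameter | default | note |
|---|---|---|
| band | 3–45 Hz | zero-phase 4th-order Butterworth band-pass |
| notch | 60 Hz | zero-phase IIR notch, Q = 30 |
| target rate | 500 Hz | polyphase anti-aliased resampling, no upsampling |
| epoch / window | 28 s / 4 s | preictal ends at onset; ictal starts at onset |
| order scan | p ∈ [1, 20] | SBC default; 20 lags = 40 ms memory at 500 Hz |
| surrogates | 100 per segment | phase randomization, per-edge empirical null |
| alpha | 0.05 | strict ">" against the ceil((1−α)·N) order statistic |
| inclusion | fs ≥ 500 Hz, ≥ 30 s preictal | recordings failing either are rejected |

Channels are z-scored over the full retained recording (not per segment)
after filtering and resampling; bad channels from sidecar annotations are
dropped first.

## Surrogate testing

Each surrogate keeps every channel's amplitude spectrum and replaces the
phases of the positive-frequency Fourier coefficients with independent
uniform draws, independently per channel (Theiler-style), destroying
cross-channel dependence. Per segment, 100 surrogates are refitted at the
segment's selected order and pushed through the same PDC/DTF band
aggregation; an edge survives only if its observed weight strictly exceeds
the null's empirical 95th percentile (order statistic at
`ceil((1−alpha)·N)`, conservative on ties). Both estimators share each
surrogate's MVAR fit. Thresholding acts on the band-aggregated weight — the
quantity used downstream — not per frequency bin. One master seed spawns
per-surrogate streams, so runs are exactly reproducible.

## Flows, AUC, and regime classification

Inflow/outflow are weighted node strengths of the (optionally thresholded)
directed matrix, diagonal excluded, min-max normalized across channels
within each segment (a constant vector maps to zeros). A channel's score
for ROC analysis is the median of its seven per-segment values; the AUC
against the clinician SOZ mask equals the tie-corrected Mann-Whitney
statistic.

A recording is *inflow-dominant* when SOZ channels' pooled per-segment
inflow is significantly higher than non-SOZ inflow (two-sided Wilcoxon
rank-sum, p < 0.05) for **both** PDC and DTF while outflow shows no such
pattern; *outflow-dominant* symmetrically; anything else *unclassified*.
The per-test level matches the protocol's stated p < 0.05; Bonferroni-
adjusted p values over the recording's four tests are reported alongside.
Demanding agreement of both estimators plus exclusivity keeps the rule
conservative: on exchangeable null networks the dominant-label rate stays
well below 2·alpha (observed ~5%). The rank-sum test enumerates all group
assignments exactly when the pooled sample is ≤ 12; otherwise it uses the
tie-corrected normal approximation.

Cohort summaries report median and IQR of AUC per (method, measure, period,
group) cell, optionally stratified by a metadata key, with pairwise
rank-sum tests between strata Bonferroni-corrected within the stratified
family.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
seizure biophysics. Each channel has oscillatory AR(2) self-dynamics — a
complex pole pair of modulus 0.85 at a channel-specific frequency drawn
from 6–20 Hz — so nearly all signal power lies inside the 3–45 Hz analysis
band. This matters: with broadband dynamics the zero-phase band-pass does
heavy work and its non-causal smearing can invert the apparent direction of
coupling, a known failure mode of Granger-type estimators on filtered data.

Regimes plant lag-1 directed edges of magnitude `coupling` (default 0.4):
into each SOZ channel from random non-SOZ sources (inflow-dominant regime),
from each SOZ channel to random non-SOZ targets (outflow-dominant), or
uniformly over ordered pairs with no SOZ asymmetry (null). With `ramp` the
planted coupling rises linearly from half to full strength across the seven
preictal segments, emulating flow that builds toward onset. Optional
stationary background edges (`bg_edges`) put the regime structure on top of
ambient connectivity. The ictal block reuses the final preictal network
with doubled coupling, giving the preictal-vs-ictal comparison something to
run on. Every network is rescaled (at most 20 times) until the companion
spectral radius is ≤ 0.95, and the recursion state carries across segment
boundaries so the signal is continuous.

Two generator choices exist purely to keep the measurement chain honest:

- **Per-channel gain normalization.** Channels driven by strong incoming
  coupling are resonantly amplified; left alone their variance can dwarf
  the rest, and the pipeline's global z-score would then rescale the
  effective coupling matrix by the sd ratios — shrinking true incoming
  edges and amplifying spurious outgoing ones quadratically, enough to flip
  the estimated direction. The generator therefore delivers every channel
  at unit sd (a linear per-channel gain, structure-preserving), before
  adding white sensor noise of sd `noise_sd` (default 0.5, in-band SNR ≫ 1
  after filtering).
- **A 4-s lead-in pad** before the 28-s preictal block, so synthetic
  recordings satisfy the ≥30 s preictal inclusion rule while the analysed
  epoch stays 28 s.

`generate_cohort` additionally draws per-patient heterogeneity: coupling
uniform over (0.2, 0.45); an ambient network of ~0.75 degree-balanced
background edges per channel (stacked derangements at 0.3× the planted
strength, so background adds flow without channel-level degree noise);
and, per patient, either an expressed regime (3 planted links per SOZ
channel) or no SOZ asymmetry at all, with equal probability. Clinical
cohorts show exactly this dichotomy (most patients unclassifiable, wide
AUC IQRs); homogeneous saturated cohorts would make the pooled-vs-grouped
contrast degenerate, because a 50/50 mixture of AUCs at ~0.2 and ~1.0 has
its median at the gap midpoint rather than near chance. Note that when
background mass is added, the stability rescaling caps the total
off-diagonal strength, so delivered coefficients are smaller than the
nominal coupling while the planted-to-background ratio is preserved.
Default desk-scale cohorts use 10–16 channels (with ~20% SOZ, at least 3)
and 2–3 seizures per patient: MVAR fits of ~100 channels on 2000-sample
windows would be rank-deficient, so the 45–176 channel range of clinical
implants is available but not the default.

**What passing tests do and do not show.** Synthetic recovery demonstrates
that the estimators, the surrogate null, the flow metrics and the decision
rule are implemented correctly and jointly identify planted directed
structure through the full preprocessing chain. It does not show that real
preictal iEEG contains such structure at such strength — on clinical data
the same pipeline yields AUCs only modestly above chance — nor does the
generator model spikes, DC shifts, high-frequency oscillations, volume
conduction, or common reference artifacts.

## Numerical choices

- Zero-phase (forward-backward) filtering avoids phase lag in directed
  estimates; the generator's in-band dynamics avoid its direction-reversal
  artifact (see above).
- Resampling maps the onset index by `round(onset · target_fs / fs)`.
- Epochs that are not an exact multiple of the window are rejected, not
  truncated.
- `Ā(f)` inversion failures report the offending frequency; zero PDC
  columns / DTF rows (impossible for fitted models) raise rather than
  return NaN.
- Min-max normalization maps constant score vectors to all zeros.
- Exact rank-sum enumeration uses midranks, so ties are handled; the
  threshold for the exact branch is a combined sample of 12 (≤ 924
  assignments).
- Seeds: every stochastic stage takes a seed or spawns children from a
  master seed via `numpy.random.SeedSequence`; identical seeds give
  bit-identical outputs.

## Known limitations

- Linear Granger-family estimators only; nonlinear or cross-frequency
  coupling is invisible.
- Stationarity is handled solely by 4-s windowing; no time-varying MVAR.
- The surrogate null destroys *all* cross-channel dependence, so the test
  is an omnibus test of dependence, not of directionality per se.
- Observation noise makes the true process ARMA; the AR approximation
  needs, and SBC selects, generous orders (often 10–20 after filtering).
- Patient-level grouping follows per-recording labels; the operational
  rule for grouping patients from multiple discordant seizures is a
  documented reconstruction (majority of classified seizures would be the
  natural extension).
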