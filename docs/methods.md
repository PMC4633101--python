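# Methods

This note records the models, conventions and numerical choices behind
`armdyn`, and what the synthetic validation does and does not establish.

## Data model and preprocessing

A recording is a (5 markers × 3 components × N samples) array at a fixed
sampling rate (default 100 Hz, N = 2000, i.e. 20 s). Marker order is rod
end, finger, wrist, elbow, shoulder (distal → proximal); components are X
(lateral), Y (toward the target), Z (vertical). Units are arbitrary lengths
(mm assumed); every measure used is unit-free or unit-covariant after
filtering, so no unit metadata is carried.

All nonlinear measures operate on 0.5 Hz high-pass filtered series; spectra
are computed on raw series. The filter is a 4th-order Butterworth applied
forward–backward (`sosfiltfilt`, even-reflection padding), chosen zero-phase
so that Hilbert phases downstream are not distorted by filter lag. Filtering
twice changes broadband RMS by < 5%, so accidental double filtering is
benign.

The *isolated series* of joint i is Δs^i = s^{i−1} − s^i: the motion joint i
contributes beyond what it inherits from its proximal neighbour. The rod has
no more-distal neighbour; Δr is defined as the bare rod series (the target
is static, and any offset is removed by the high-pass). This convention is a
genuine design choice — nothing in the chain defines Δ for the end marker —
and is flagged here because it affects the network analysis, whose four
channels are Δr, Δf, Δw, Δe.

## Spectra

Per-subject spectra are single full-length FFTs without windowing or segment
averaging (a Welch option exists behind a flag for noise-floor checks). The
one-sided power is normalised so its sum equals the variance of the
mean-removed series (checked to 1e-6 relative for every input). Group
averages are linear, bin-wise; log-domain averaging was considered and
rejected as it biases peak heights down. The log–log slope fit uses least
squares over 0.5–10 Hz by default; integrated white noise gives −2, and the
band avoids both the DC bin and the noise floor.

## Dimensional complexity

Delay embedding follows x(t) = (s(t−(m−1)τ), …, s(t)) with τ = 5 samples and
m = 10, 12, …, 26 for the kinematic defaults. The correlation sum uses
maximum-norm distances, a Theiler window W = 5 (pairs closer than 6 samples
in time are excluded to suppress autocorrelation bias), and normalisation
2/((N−W)(N−1−W)) so C saturates at exactly 1. Pair counting is exact (sorted
distances + binary search), and is verified against an O(N²) brute-force
enumeration.

Numerical choices, where the method itself is silent:

- ε grid: 100 log-spaced thresholds spanning [1e-3, 1] × the attractor's
  max-norm diameter. For delay embeddings of a scalar series the Chebyshev
  diameter equals the range of the series, so one grid serves every m.
- Local slopes: sliding 5-point least squares on (ln ε, ln C).
- Plateau extraction: among contiguous slope windows with unevenness
  (max−min)/max ≤ 0.4, the longest wins, ties toward smaller ε; D₂ is the
  window's mean slope. Minimum window: 3 slope points (the unevenness of a
  shorter window is vacuous). Surrogate mode additionally demands the window
  cover ≥ 10% of the grid.
- The search is restricted to slope points whose central C lies in
  [1e-4, 0.5]. The lower bound removes the statistically starved head; the
  upper bound removes the saturation shoulder where slopes trivially
  collapse toward zero as C → 1 and would otherwise win as a fake plateau
  for stochastic series.
- Cross-m stability: if the plateau's ln ε midpoint drifts across the m
  sweep by more than half the mean plateau width, the result is flagged
  `unstable_across_m` — a plateau that moves with m is not a dimension.
- d_max = 2 log N / log(1/ρ) (base-invariant) with ρ = 0.1; estimates above
  it are flagged, not discarded: they remain usable as practical indices of
  the series, just not as dimensions.

Validation: the Hénon map's D₂ from the full automatic pipeline at N = 2000
lands in [1.0, 1.4] and within 0.2 of a direct Grassberger–Procaccia fit on
a 20,000-point series; 5000 points uniform on a line/plane recover
dimensions 1/2 within 0.1/0.2.

## Surrogate testing

IAAFT surrogates alternate spectrum adjustment (impose the original Fourier
magnitudes) with rank ordering (impose the original value multiset),
stopping when the rank permutation is fixed or after 200 iterations. The
amplitude distribution is preserved exactly (asserted on every run), the
power spectrum to < 1% RMS in practice. The test is one-sided — determinism
can only lower D₂ relative to linear-stochastic surrogates — and rejects
when the bare D₂ lies below all valid surrogate D₂ values: with 100
surrogates the attained p is 1/101 < 0.01. The verdict is withheld when
fewer than 90% of surrogates yield a plateau under the relaxed criteria.
Measured behaviour: rejection on Hénon data, retention on Gaussian AR(2) in
every seeded run of the suite.

## Entropies

SampEn(m, r): B counts pairs of length-m templates within Chebyshev distance
r among the first N−m templates, A the corresponding count at length m+1;
S_E = −ln(A/B), self-matches excluded, NaN (flagged) when either count is
zero. Defaults m = 2, r = 0.15 × population SD of the scale-1 filtered
series, held fixed across scales — the standard multiscale convention; since
the source analysis does not state its (m, r), comparisons of multiscale
curves are qualitative (orderings), never numeric. Coarse-graining is
non-overlapping block means, length ⌊N/τ⌋, scales 1–20.

K₂ = (1/τ) ln[C_m(ε)/C_{m+1}(ε)] is provided as a diagnostic (zero for
periodic signals, divergent as ε → 0 for noise); it takes no part in group
comparisons.

## Synchrony and causality

Phases come from the discrete analytic signal (`scipy.signal.hilbert`) of
the mean-removed series; 5% of samples at each end are trimmed before
averaging, since the transform's edge artifacts would otherwise bias the
order parameters. Ψ₁ and Ψ₂ are the circular resultant lengths of Δφ and
2Δφ; phases are compared wrapped (means on the unit circle). Ψ₂(a, −b) =
Ψ₂(a, b) exactly, which is why Ψ₂ detects out-of-phase (sign-flipped)
locking — relevant because the vertical component responds to gravity with
inverted sign.

Granger causality: series are standardised to zero mean, unit variance
(affects magnitudes, not orderings); the full model regresses u(t) on lags
1..q of u and of the candidate driver v (the conditional variant keeps a
third channel's lags in both models); the reduced model drops v. One q per
directed pair, selected by AIC on the full model over 1..20 with all
candidate orders scored on a common sample, then reused for the reduced
model — required for G = ln(Σ_ξ/Σ_η) ≥ 0. Negative values within numerical
noise are clipped to zero with a warning; rank-deficient designs (identical
or constant series) are flagged degenerate. The pairwise statistic matches
an independent normal-equation implementation to 1e-8 relative.

## Network entropy

Per component and coarse-graining scale, the four isolated series are
summarised as a weighted 4-node graph with edge weights |Pearson r|. Node
clustering coefficients use the geometric-mean triangle convention (weights
rescaled by the maximum), making E_c invariant under uniform weight
rescaling; the coefficients are normalised to a probability distribution and
E_c is its Shannon entropy, bounded by ln 4 ≈ 1.386. An all-zero coefficient
vector (empty graph) is reported as ln 4 with a degenerate flag. Scales
whose coarse-grained length falls below 30 samples are truncated. The
original network construction this stands in for is not fully specified in
the source analysis; this reconstruction satisfies its operational contract
— stronger inter-channel coupling raises E_c at every scale — so E_c
comparisons are orderings only, never against printed values (none exist).

## Group statistics

Printed group rows are mean ± population SD (divisor n): recomputing the
published per-subject dimension table's group rows from its per-subject
values reproduces the printed numbers only under this convention (to one
unit in the last printed digit; one printed SD is a truncation). Group
differences use the conventional two-sample equal-variance Student t-test,
two-sided, α = 0.05, no multiple-testing correction — one asterisk per cell.

## Synthetic generator

The generator reproduces statistical signatures, not biomechanics (no
torques, muscles, or joint limits). Channels are built proximal → distal:
s^i = s^{i+1} + c^i, so the isolated differences recover the injected
per-joint contributions by construction.

Normal subjects: each joint's contribution is a superposition of 30
randomly phased oscillators spanning 1–15 Hz with 1/f amplitudes, mixed with
a chain-shared bank at weight joint_coupling (default 0.15) scaled per joint
by (0.4, 1.6, 0.7, 1.3, 1.0) — joints are not uniformly stiff, which gives
the heterogeneous correlation network a normal subject should have. The
shoulder Y carries two independent integrated-white-noise (Brownian) terms
plus a deterministic shrink drift of −30 length units over the record (the
arm creeps toward the body under fatigue); this yields the 1/f² Y spectrum
(fitted slope −2 ± 0.5 across seeds over 0.5–10 Hz). The rod X and Z receive
lagged linear responses (lags 3 and 6 samples, gain 1.6) to the *two
distinct* white drives of Y — distinct, so that X and Z stay mutually
decoupled while both are caused by Y, and conditioning on X cannot explain
away the Y→Z drive. Measurement noise is white, SD 0.3 × noise_sd on every
channel. noise_sd (default 1) is the master amplitude of every stochastic
term, so noise_sd = 0 degenerates to pure drift.

Patients: a single Rössler oscillator (a = b = 0.2, c = 5.7), x variable,
integrated at fine step and time-rescaled so its dominant frequency lands at
a per-subject value drawn uniformly inside the central part of the tremor
band (default [2, 3] Hz; natural dominant frequency 0.1704 cycles per time
unit, measured once from the attractor's spectrum). Every channel is a
near-affine copy: gain × [jc·(±source) + (1−jc)·bank] + (1−lock)·bank', with
the Z sign flipped, jc = joint_coupling (default 0.85) controlling how much
of the source adjacent joints share and lock = locking_strength (default
0.8) controlling component-level independence. At lock = 1, noise_sd = 0 the
rod channels are exactly proportional and Ψ₁ = 1. Defaults make the
synthetic patients more strongly locked (Ψ₁ ≈ 0.99) than real patients
(≈ 0.6); the pipeline's group contrasts are orderings, so this
conservatively wide separation is acceptable for validation but not for
calibrating absolute synchrony values.

Per-subject variability: each subject jitters its nominal parameters with
seeded multiplicative log-normal factors (σ = 0.1) — applied as exponents
for the [0, 1]-bounded coupling/locking parameters so the endpoints 0 and 1
are preserved exactly. The jitter lives inside the single-subject
simulators, keyed to the subject's own seed, so a group of one is bit-
identical to the corresponding single-subject call.

What passing the synthetic experiments shows: the estimators detect the
structures they target (Brownian slopes, tremor peaks, low-dimensional
chaos, causal directions, locking) at the study's sample sizes. What it does
not show: performance under real measurement artifacts (marker dropout,
nonstationary drift beyond the modelled shrink, broadband patient noise),
nor absolute agreement of D₂/Ψ/G magnitudes with human data — those depend
on unpublished details (ε grids, SampEn radii) and on physiology the
generator does not model.

## Problem sizes and runtime

Cohort runs (tests, drivers, reproduction script) use the reduced embedding
sweep m = (10, 18, 26) with the reporting dimension m = 26 unchanged;
cross-m stability is checked across those three dimensions. Surrogate
validation uses m = 5, τ = 1 on reference systems (N = 1000–2000), where the
test's size and power are unambiguous. The full m = 10…26 sweep is the
library default for single-subject analysis.

## Known limitations

- Plateau extraction reconstructs an automatic procedure whose reference
  implementation details (grid, window) are unpublished; absolute D₂ values
  on real data carry a tolerance of order ±15%.
- The AIC order search caps at q = 20 (200 ms of history at 100 Hz).
- E_c discriminates groups clearly but compresses into a narrow band under
  the ln 4 ceiling; its absolute scale is convention-dependent.
- The generator's patient locking is stronger than clinically typical (see
  above).
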