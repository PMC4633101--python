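# armdyn — nonlinear analysis of goal-directed arm-posture dynamics

`armdyn` analyses multivariate kinematic recordings of a goal-directed
arm-posture task (holding a rod pointed at a target) and quantifies what
separates healthy motor control from stroke-affected control with
pathological tremor: the healthy arm fluctuates aperiodically in a
high-dimensional way, while the tremor-affected arm collapses onto a
low-dimensional oscillation near 2–3 Hz with joints and coordinate
components locked together. It is aimed at movement scientists and
physicists working on nonlinear physiological time series.

A recording is five markers (rod end *r*, finger *f*, wrist *w*, elbow *e*,
shoulder *s*) × three components (X toward the side, Y toward the target,
Z vertical), 2000 samples at 100 Hz, stored as a 15-column CSV. All
nonlinear measures are computed on 0.5 Hz high-pass filtered series; spectra
on the raw series.

## Measures

- **Spectra** — one-sided FFT power/phase spectra, group averages, log–log
  slope (the healthy Y component shows the 1/f² signature of integrated
  white noise), and tremor-band peak detection.
- **Dimensional complexity D₂** — Takens delay embedding
  (m = 10, 12, …, 26, τ = 5), the revised correlation sum
  C(ε) = 2/((N−W)(N−1−W)) Σ_{t₂>t₁+W} Θ(ε − ‖x(t₁) − x(t₂)‖∞)
  with Theiler window W = 5, local slopes ∂lnC/∂lnε, and automatic plateau
  extraction (longest window with unevenness < 0.4); the finite-sample bound
  d_max = 2 log N / log(1/ρ) flags estimates that cannot be trusted as
  dimensions (6.60 for N = 2000, ρ = 0.1).
- **IAAFT surrogate test** — 100 iterative amplitude-adjusted Fourier
  transform surrogates per series; the linear-stochastic null is rejected at
  the 99% level when the bare D₂ falls below every valid surrogate D₂
  (one-sided rank test, p = 1/101).
- **Multiscale sample entropy** — SampEn(m = 2, r = 0.15 SD) of
  coarse-grained series at scales τ = 1…20.
- **Phase synchrony** — Hilbert phases of the isolated joint series
  Δs^i = s^{i−1} − s^i and order parameters
  Ψ₁ = |⟨e^{iΔφ}⟩|, Ψ₂ = |⟨e^{2iΔφ}⟩| (Ψ₂ is blind to sign flips, catching
  out-of-phase locking).
- **Granger causality** — G_{v→u} = ln(Σ_ξ/Σ_η) from lagged OLS regressions
  with AIC-selected order, pairwise and conditioned on a third channel.
- **Multiscale network entropy** — correlation-weighted 4-node networks over
  the isolated series (Δr, Δf, Δw, Δe) per component and scale, summarised
  by the Shannon entropy E_c of the normalised clustering coefficients.

A seeded synthetic generator produces recordings with the statistical
structure of both groups (Brownian-Y normal subjects with a Y→X/Y→Z causal
chain; Rössler-driven 2–3 Hz tremor patients with locked components), so the
entire pipeline runs and is tested without human data.

## Worked example

```python
from armdyn import SimulationParams, simulate_patient_subject, filter_recording
from armdyn import dimensional_complexity, power_phase_spectrum, band_peak

rec = filter_recording(simulate_patient_subject(SimulationParams.patient(seed=7)))
spectrum = power_phase_spectrum(rec.channel("rod", "X"))
print(band_peak(spectrum, (2.0, 3.0)))
res = dimensional_complexity(rec.channel("rod", "X"), m_list=(10, 18, 26))
print(res.plateau.D2, res.plateau.valid, res.limit.d_max)
```

prints

```
(2.35, 687.2668871357814)
2.397156780523091 True 6.6020599913279625
```

— the tremor peak sits at 2.35 Hz with ~690× the median band power, and the
plateau pipeline finds a valid low-dimensional D₂ ≈ 2.40, well under the
d_max = 6.60 bound. The same call on a normal simulation returns D₂ ≈ 13
flagged as exceeding d_max — a number to be read as a practical index, not a
dimension, exactly the caveat that applies to high-dimensional real subjects.

The numbered drivers under `analysis/` run the complete study on a synthetic
6+6 cohort (`01_simulate_cohorts.py` … `07_group_report.py`), writing tables
to `results/`. The `armdyn` CLI exposes the same steps
(`armdyn simulate|spectrum|complexity|mse|coupling|netentropy|analyze`).

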