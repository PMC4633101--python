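"""Synthetic kinematic recordings with normal-subject and tremor-patient structure.

The generator does not model limb biomechanics; it reproduces the statistical
signatures the analysis pipeline probes, so every stage of the pipeline can be
exercised and validated without human recordings.

Normal subjects
    Aperiodic, high-dimensional fluctuation: each joint in the chain
    shoulder -> elbow -> wrist -> finger -> rod adds its own superposition of
    30 randomly phased oscillators spanning 1-15 Hz (1/f amplitude envelope),
    weakly mixed with a bank shared along the chain (weight = joint_coupling).
    The Y components ride on integrated white noise (Brownian motion, giving
    the 1/f^2 spectrum) plus a slow shrink drift -- the arm creeps toward the
    body under fatigue.  The X and Z rod components each contain a lagged
    linear response to a distinct white component of the Y drive (different
    lags), encoding the causal structure Y -> X and Y -> Z with X and Z
    mutually decoupled.

Patients
    A single low-dimensional chaotic source -- the x variable of a Roessler
    oscillator, time-rescaled so its dominant spectral peak falls inside the
    tremor band (2-3 Hz by default) -- drives every channel.  Components of a
    marker are near-affine copies of the source (Z sign-flipped), blurred by
    independent noise of weight (1 - locking_strength); adjacent joints share
    the source with weight joint_coupling.

Per-subject variability: each simulated subject perturbs its nominal
parameters with seeded multiplicative jitter (exponent jitter for parameters
confined to [0, 1], so the endpoints 0 and 1 are preserved exactly), giving
the nonzero between-subject variance that group statistics need.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .io_preprocess import KinematicRecording, write_config, write_recording

# Dominant cycle frequency of the Roessler x variable (a=b=0.2, c=5.7) in
# cycles per natural time unit; used to rescale time so the spectral peak
# lands at the requested tremor frequency.
ROSSLER_BASE_FREQ = 0.1704

_JITTER_SIGMA = 0.1


@dataclass(frozen=True)
class SimulationParams:
    group_label: str
    n_samples: int = 2000
    sampling_rate: float = 100.0
    tremor_freq_band: tuple[float, float] = (2.0, 3.0)
    locking_strength: float = 0.0
    joint_coupling: float = 0.15
    noise_sd: float = 1.0
    seed: int = 0
    jitter_sigma: float = _JITTER_SIGMA

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for name in ("locking_strength", "joint_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def normal(cls, seed: int = 0, **kw) -> "SimulationParams":
        kw.setdefault("locking_strength", 0.0)
        kw.setdefault("joint_coupling", 0.15)
        return cls(group_label="normal", seed=seed, **kw)

    @classmethod
    def patient(cls, seed: int = 0, **kw) -> "SimulationParams":
        kw.setdefault("locking_strength", 0.8)
        kw.setdefault("joint_coupling", 0.85)
        return cls(group_label="patient", seed=seed, **kw)


def _oscillator_bank(
    rng: np.random.Generator,
    n: int,
    fs: float,
    sd: float,
    n_osc: int = 30,
    f_lo: float = 1.0,
    f_hi: float = 15.0,
) -> np.ndarray:
    """Sum of randomly phased sinusoids with a 1/f amplitude envelope.

    A deterministic but effectively high-dimensional broadband fluctuation;
    scaled to the requested standard deviation (zero if sd == 0).
    """
    if sd == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    freqs = rng.uniform(f_lo, f_hi, n_osc)
    phases = rng.uniform(0, 2 * np.pi, n_osc)
    amps = 1.0 / freqs
    x = (amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])).sum(0)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _jitter(params: SimulationParams, rng: np.random.Generator) -> SimulationParams:
    """Seeded per-subject parameter perturbation (see module docstring)."""
    if params.jitter_sigma == 0:
        return params
    g = np.exp(params.jitter_sigma * rng.standard_normal(3))
    return replace(
        params,
        joint_coupling=float(params.joint_coupling ** g[0]),
        locking_strength=float(params.locking_strength ** g[1]),
        noise_sd=float(params.noise_sd * g[2]),
    )


def simulate_normal_subject(
    params: SimulationParams, return_internals: bool = False
) -> KinematicRecording:
    """Normal-subject recording: high-dimensional fluctuation, Brownian Y,
    lagged Y -> X and Y -> Z responses with decoupled X and Z."""
    if params.group_label != "normal":
        raise ValueError("params.group_label must be 'normal'")
    rng = np.random.default_rng(params.seed)
    p = _jitter(params, rng)
    n, fs = p.n_samples, p.sampling_rate
    jc, amp = p.joint_coupling, p.noise_sd
    t = np.arange(n) / fs

    # Two independent white drives; their integrals form the Brownian Y term.
    w1 = rng.standard_normal(n) * 0.5 * amp
    w2 = rng.standard_normal(n) * 0.5 * amp
    brown = np.cumsum(w1) + np.cumsum(w2)
    drift = -30.0 * t / t[-1] if n > 1 else np.zeros(n)  # shrink toward the body

    # Shared bank along the chain (one per component) for weak joint coupling.
    shared = {c: _oscillator_bank(rng, n, fs, amp) for c in range(3)}

    # Per-joint contributions c^j (chain index j = 0 rod ... 4 shoulder).
    # Joints couple to the shared bank with different strengths (joints are
    # not uniformly stiff), which makes the inter-channel correlation
    # network of a normal subject heterogeneous.
    contrib = np.zeros((5, 3, n))
    y_scale = 0.5  # Y keeps its Brownian character: weak oscillator content
    jc_joint = jc * np.array([0.4, 1.6, 0.7, 1.3, 1.0])
    for j in range(5):
        w = min(jc_joint[j], 1.0)
        for c, scale in enumerate((1.0, y_scale, 1.0)):
            own = _oscillator_bank(rng, n, fs, scale * amp)
            contrib[j, c] = (1.0 - w) * own + w * scale * shared[c]
    contrib[4, 1] += brown + drift  # shoulder Y carries the common Y drive

    # Lagged linear responses of the rod's X and Z to the Y increments.
    lag_x, lag_z, gain = 3, 6, 1.6
    resp_x = np.zeros(n)
    resp_x[lag_x:] = gain * w1[:-lag_x]
    resp_z = np.zeros(n)
    resp_z[lag_z:] = gain * w2[:-lag_z]
    contrib[0, 0] += resp_x
    contrib[0, 2] += resp_z

    series = np.zeros((5, 3, n))
    series[4] = contrib[4]
    for i in (3, 2, 1, 0):  # elbow, wrist, finger, rod
        series[i] = series[i + 1] + contrib[i]
    series += rng.standard_normal(series.shape) * 0.3 * amp  # measurement noise

    rec = KinematicRecording(
        series,
        sampling_rate=fs,
        subject_id=f"normal-{params.seed}",
        group_label="normal",
        meta={"params": params, "realized": p},
    )
    if return_internals:
        return rec, {"contrib": contrib, "w1": w1, "w2": w2, "brown": brown}
    return rec


def roessler_source(
    n: int,
    fs: float,
    peak_freq: float,
    rng: np.random.Generator,
    a: float = 0.2,
    b: float = 0.2,
    c: float = 5.7,
    transient: float = 100.0,
) -> np.ndarray:
    """Unit-variance x series of a time-rescaled Roessler oscillator.

    The natural dominant frequency is rescaled to ``peak_freq`` Hz at sampling
    rate ``fs``; initial conditions are drawn near the attractor so different
    seeds give different chaotic realisations of the same dynamics.
    """

    def rhs(_t, s):
        x, y, z = s
        return (-y - z, x + a * y, b + z * (x - c))

    dt = peak_freq / (ROSSLER_BASE_FREQ * fs)  # natural time units per sample
    t_end = transient + n * dt
    t_eval = transient + dt * np.arange(n)
    s0 = np.array([1.0, 1.0, 0.0]) + 0.5 * rng.standard_normal(3)
    sol = solve_ivp(
        rhs, (0.0, t_end), s0, t_eval=t_eval, rtol=1e-9, atol=1e-9, method="RK45",
        max_step=0.5,
    )
    x = sol.y[0]
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_patient_subject(
    params: SimulationParams, return_internals: bool = False
) -> KinematicRecording:
    """Patient recording: one chaotic tremor source locks components and joints."""
    if params.group_label != "patient":
        raise ValueError("params.group_label must be 'patient'")
    rng = np.random.default_rng(params.seed)
    p = _jitter(params, rng)
    n, fs = p.n_samples, p.sampling_rate
    jc, lock, amp = p.joint_coupling, p.locking_strength, p.noise_sd
    lo, hi = p.tremor_freq_band
    pad = min(0.2, 0.25 * (hi - lo))
    peak = rng.uniform(lo + pad, hi - pad)
    src = roessler_source(n, fs, peak, rng)
    sign = np.array([1.0, 1.0, -1.0])  # Z responds with flipped sign

    # Joint-contribution gains: distinct per marker/component so the chain
    # differences retain a source term.
    gains = np.array(
        [
            [1.2, 1.0, 1.1],   # rod
            [0.9, 0.8, 1.0],   # finger
            [0.8, 0.7, 0.9],   # wrist
            [0.6, 0.6, 0.7],   # elbow
            [0.5, 0.5, 0.6],   # shoulder
        ]
    )
    contrib = np.zeros((5, 3, n))
    for j in range(5):
        for c in range(3):
            bank1 = _oscillator_bank(rng, n, fs, 0.3 * amp)
            bank2 = _oscillator_bank(rng, n, fs, 0.3 * amp)
            contrib[j, c] = gains[j, c] * (
                jc * sign[c] * src + (1.0 - jc) * bank1
            ) + (1.0 - lock) * bank2

    series = np.zeros((5, 3, n))
    series[4] = contrib[4]
    for i in (3, 2, 1, 0):
        series[i] = series[i + 1] + contrib[i]
    series += rng.standard_normal(series.shape) * 0.05 * amp * (1.0 - lock)

    rec = KinematicRecording(
        series,
        sampling_rate=fs,
        subject_id=f"patient-{params.seed}",
        group_label="patient",
        meta={"params": params, "realized": p, "tremor_peak_hz": peak},
    )
    if return_internals:
        return rec, {"contrib": contrib, "source": src, "peak_freq": peak}
    return rec


def simulate_subject(params: SimulationParams) -> KinematicRecording:
    if params.group_label == "normal":
        return simulate_normal_subject(params)
    if params.group_label == "patient":
        return simulate_patient_subject(params)
    raise ValueError(f"unknown group_label {params.group_label!r}")


def simulate_group(
    n_subjects: int, params: SimulationParams, base_seed: int | None = None
) -> list[KinematicRecording]:
    """Cohort of seeded recordings: seeds base_seed, base_seed+1, ...

    Each subject's parameters receive their own seeded jitter (inside the
    single-subject simulators), so group variance is nonzero by default.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if base_seed is None:
        base_seed = params.seed
    return [
        simulate_subject(replace(params, seed=base_seed + k)) for k in range(n_subjects)
    ]


def save_group(recordings: list[KinematicRecording], out_dir: str | Path) -> list[Path]:
    """Write each recording as S1-layout CSV plus a key=value sidecar config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        stem = rec.subject_id or "recording"
        csv_path = out_dir / f"{stem}.csv"
        write_recording(rec, csv_path)
        params = rec.meta.get("params")
        cfg = {
            "subject_id": rec.subject_id,
            "group_label": rec.group_label,
            "sampling_rate": rec.sampling_rate,
            "n_samples": rec.n_samples,
        }
        if params is not None:
            cfg.update(
                seed=params.seed,
                locking_strength=params.locking_strength,
                joint_coupling=params.joint_coupling,
                noise_sd=params.noise_sd,
            )
        write_config(cfg, out_dir / f"{stem}.cfg")
        paths.append(csv_path)
    return paths
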