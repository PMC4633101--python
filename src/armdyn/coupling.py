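"""Hilbert phases, synchrony order parameters and Granger causality.

Phase locking between two channels is measured by the circular order
parameters

    Psi_1 e^{i Phi_1} = <e^{ i (phi_a - phi_b)}>,
    Psi_2 e^{i Phi_2} = <e^{2i (phi_a - phi_b)}>,

with phi the instantaneous Hilbert phase.  Psi_1 detects in-phase locking;
Psi_2 doubles the phase difference so an overall sign flip (phase shift of
pi) is invisible, making it sensitive to out-of-phase locking.

Granger causality G_{v->u} = ln(Sigma_xi / Sigma_eta) compares residual
variances of an autoregression of u with and without lagged terms of v; the
lag order q is chosen by AIC on the full model.  The conditional variant
keeps a third channel's lags in both models, removing indirect paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .io_preprocess import (
    COMPONENTS,
    ComponentSeries,
    IsolatedSeries,
    KinematicRecording,
    isolated_series,
)

EDGE_TRIM_FRACTION = 0.05  # Hilbert transform edge artifacts: trim 5% per end


@dataclass(frozen=True)
class PhaseSeries:
    phases: np.ndarray     # wrapped, radians
    amplitude: np.ndarray  # envelope, >= 0
    source_label: str = ""


@dataclass(frozen=True)
class SynchronyResult:
    psi1: float
    psi2: float
    phi1: float
    phi2: float
    pair_label: str = ""
    degenerate: bool = False


@dataclass(frozen=True)
class GrangerResult:
    G: float
    order_q: int
    residual_var_full: float
    residual_var_reduced: float
    direction_label: str = ""
    conditional_on: str | None = None
    degenerate: bool = False


def _values(series) -> np.ndarray:
    if isinstance(series, (ComponentSeries, IsolatedSeries)):
        return np.asarray(series.values, float)
    return np.asarray(series, float)


def analytic_phase(series, label: str = "") -> PhaseSeries:
    """Instantaneous phase and envelope from the discrete analytic signal."""
    x = _values(series)
    x = x - x.mean()
    if np.ptp(x) == 0:
        raise ValueError("constant series has no defined phase")
    z = hilbert(x)
    return PhaseSeries(np.angle(z), np.abs(z), label)


def phase_synchrony(a: PhaseSeries, b: PhaseSeries, trim: float = EDGE_TRIM_FRACTION,
                    pair_label: str = "") -> SynchronyResult:
    """Order parameters Psi_1, Psi_2 of the wrapped phase difference.

    The first and last ``trim`` fraction of samples are discarded before
    averaging to avoid Hilbert-transform edge artifacts.
    """
    if a.phases.size != b.phases.size:
        raise ValueError("phase series lengths differ")
    n = a.phases.size
    k = int(np.floor(trim * n))
    sl = slice(k, n - k if k else n)
    dphi = a.phases[sl] - b.phases[sl]
    z1 = np.mean(np.exp(1j * dphi))
    z2 = np.mean(np.exp(2j * dphi))
    return SynchronyResult(
        psi1=float(np.abs(z1)),
        psi2=float(np.abs(z2)),
        phi1=float(np.angle(z1)),
        phi2=float(np.angle(z2)),
        pair_label=pair_label,
    )


def _lag_matrix(columns: list[np.ndarray], q: int, n: int, start: int) -> np.ndarray:
    """Design matrix of lags 1..q for each column series, rows start..n-1."""
    rows = n - start
    X = np.empty((rows, q * len(columns)))
    for c, x in enumerate(columns):
        for k in range(1, q + 1):
            X[:, c * q + k - 1] = x[start - k : n - k]
    return X


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("constant series cannot enter a Granger regression")
    return x / sd


def _aic_order(u: np.ndarray, predictors: list[np.ndarray], max_order: int) -> int:
    """AIC-minimising lag order for the full regression of u on all predictors.

    All candidate orders are scored on the common sample t = max_order..N-1 so
    the information criteria are comparable.
    """
    n = u.size
    start = max_order
    y = u[start:]
    n_eff = y.size
    best_q, best_aic = 1, np.inf
    for q in range(1, max_order + 1):
        X = _lag_matrix(predictors, q, n, start)
        rss, _ = _ols_rss(X, y)
        sigma2 = max(rss / n_eff, 1e-300)
        aic = n_eff * np.log(sigma2) + 2.0 * X.shape[1]
        if aic < best_aic - 1e-12:
            best_aic, best_q = aic, q
    return best_q


def _granger(
    u: np.ndarray,
    full_predictors: list[np.ndarray],
    reduced_predictors: list[np.ndarray],
    max_order: int,
    direction_label: str,
    conditional_on: str | None,
) -> GrangerResult:
    n = u.size
    if n < 10 * max_order:
        raise ValueError("series too short for the requested maximum lag order")
    q = _aic_order(u, full_predictors, max_order)
    start = q
    y = u[start:]
    n_eff = y.size
    X_full = _lag_matrix(full_predictors, q, n, start)
    X_red = _lag_matrix(reduced_predictors, q, n, start)
    rss_full, rank_full = _ols_rss(X_full, y)
    rss_red, _ = _ols_rss(X_red, y)
    var_full = rss_full / n_eff
    var_red = rss_red / n_eff
    degenerate = rank_full < X_full.shape[1] or var_full < 1e-10
    if degenerate:
        warnings.warn(f"degenerate Granger regression for {direction_label}")
        g = 0.0
    else:
        g = float(np.log(var_red / var_full))
        if g < 0:
            warnings.warn(f"negative Granger value {g:.2e} clipped to 0 ({direction_label})")
            g = 0.0
    return GrangerResult(
        G=g,
        order_q=q,
        residual_var_full=var_full,
        residual_var_reduced=var_red,
        direction_label=direction_label,
        conditional_on=conditional_on,
        degenerate=degenerate,
    )


def granger_pairwise(u, v, max_order: int = 20, label: str = "v->u") -> GrangerResult:
    """G_{v->u}: does v's past improve the autoregressive prediction of u?

    Both series are standardised to zero mean and unit variance; the same
    AIC-selected order q is used for the full and the reduced model so the
    statistic is non-negative by construction.
    """
    uu = _standardize(_values(u))
    vv = _standardize(_values(v))
    return _granger(uu, [uu, vv], [uu], max_order, label, None)


def granger_conditional(u, v, z, max_order: int = 20, label: str = "v->u|z") -> GrangerResult:
    """G_{v->u|z}: causality from v to u with z's lags present in both models."""
    uu = _standardize(_values(u))
    vv = _standardize(_values(v))
    zraw = _values(z)
    if np.ptp(zraw) == 0:
        warnings.warn("conditioning series constant; falling back to pairwise causality")
        return _granger(uu, [uu, vv], [uu], max_order, label, None)
    zz = _standardize(zraw)
    return _granger(uu, [uu, vv, zz], [uu, zz], max_order, label, "z")


# ---------------------------------------------------------------------------
# Recording-level tables


@dataclass
class CouplingRow:
    label: str
    synchrony: SynchronyResult | None
    granger: GrangerResult | None
    failed: bool = False


def joint_coupling_table(recording: KinematicRecording, max_order: int = 20) -> list[CouplingRow]:
    """Per-joint synchrony and isolated causality rows (finger, wrist, elbow).

    For joint i and component alpha: Psi_1/Psi_2 between the isolated series
    Δs^i and Δs^{i+1}, and the proximal-to-distal causality G_{Δs^{i+1}->Δs^i}.
    The recording must already be high-pass filtered.
    """
    rows: list[CouplingRow] = []
    names = {2: "Δf", 3: "Δw", 4: "Δe"}
    for i in (2, 3, 4):
        for alpha in COMPONENTS:
            label = f"{names[i]}_{alpha}"
            a = isolated_series(recording, i, alpha)
            b = isolated_series(recording, i + 1, alpha)
            try:
                sync = phase_synchrony(
                    analytic_phase(a), analytic_phase(b), pair_label=label
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    # proximal joint drives the distal one: G_{Δs^{i+1} -> Δs^i}
                    gr = granger_pairwise(
                        a, b, max_order=max_order, label=f"G_Δs{i+1}→Δs{i}_{alpha}"
                    )
                rows.append(CouplingRow(label, sync, gr))
            except ValueError:
                rows.append(CouplingRow(label, None, None, failed=True))
    return rows


def component_coupling_table(recording: KinematicRecording, max_order: int = 20) -> dict:
    """Rod-component synchrony (3 pairs) and causality (6 ordered + 2 conditional).

    Uses the bare rod series (not the isolated one), high-pass filtered.
    """
    rod = {alpha: recording.channel("rod", alpha) for alpha in COMPONENTS}
    phases = {}
    for alpha, ch in rod.items():
        try:
            phases[alpha] = analytic_phase(ch, f"r_{alpha}")
        except ValueError:
            phases[alpha] = None
    sync: dict[str, SynchronyResult | None] = {}
    for a, b in (("X", "Y"), ("Y", "Z"), ("Z", "X")):
        key = f"({a},{b})"
        if phases[a] is None or phases[b] is None:
            sync[key] = None
        else:
            sync[key] = phase_synchrony(phases[a], phases[b], pair_label=key)
    caus: dict[str, GrangerResult | None] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a in COMPONENTS:
            for b in COMPONENTS:
                if a == b:
                    continue
                key = f"{a}->{b}"
                try:
                    caus[key] = granger_pairwise(rod[b], rod[a], max_order, f"G_r{a}->r{b}")
                except ValueError:
                    caus[key] = None
        for src, dst in (("Y", "Z"), ("Z", "Y")):
            key = f"{src}->{dst}|X"
            try:
                caus[key] = granger_conditional(
                    rod[dst], rod[src], rod["X"], max_order, f"G_r{src}->r{dst}|r_X"
                )
            except ValueError:
                caus[key] = None
    return {"synchrony": sync, "causality": caus}
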