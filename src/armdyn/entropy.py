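"""Sample entropy, multiscale (coarse-grained) entropy and the K2 entropy.

Sample entropy SampEn(m, r) is -ln(A/B), where B counts template pairs of
length m whose Chebyshev distance stays within r and A the same count at
length m+1; self-matches are excluded.  The multiscale curve applies SampEn
to non-overlapping block averages of the series at scale factors tau = 1..20;
coarse-graining suppresses uncorrelated noise, so genuinely structured series
keep their entropy at large tau while white noise loses it.

K2, the correlation entropy, is a lower bound of the Kolmogorov-Sinai entropy
obtained from the ratio of correlation sums at consecutive embedding
dimensions; it is kept as a diagnostic rather than a headline measure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .complexity import CorrelationCurve
from .io_preprocess import ComponentSeries, LengthError


@dataclass(frozen=True)
class MSECurve:
    scales: np.ndarray          # 1..tau_max
    S_E: np.ndarray             # nats; NaN where undefined
    defined: np.ndarray         # bool mask
    m_pattern: int
    r: float


@dataclass(frozen=True)
class K2Estimate:
    value: float                # nats per second
    m: int
    epsilon: float


def coarse_grain(series: ComponentSeries, scale: int) -> ComponentSeries:
    """Non-overlapping block means of length ``scale``; trailing samples drop."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    x = series.values
    n_blocks = x.size // scale
    if n_blocks < 2:
        raise ValueError(f"scale {scale} leaves fewer than 2 samples")
    y = x[: n_blocks * scale].reshape(n_blocks, scale).mean(axis=1)
    return replace(series, values=y, sampling_rate=series.sampling_rate / scale)


def _template_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """(A, B): matching template pairs at lengths m+1 and m (self-pairs excluded)."""
    n_t = x.size - m  # number of templates used at both lengths
    if n_t < 2:
        raise LengthError("series too short for the template length")
    idx = np.arange(n_t)[:, None] + np.arange(m + 1)[None, :]
    templates = x[idx]
    d_m = cdist(templates[:, :m], templates[:, :m], "chebyshev")
    d_m1 = np.maximum(d_m, np.abs(templates[:, -1:] - templates[:, -1:].T))
    iu = np.triu_indices(n_t, k=1)
    b = int(np.count_nonzero(d_m[iu] <= r))
    a = int(np.count_nonzero(d_m1[iu] <= r))
    return a, b


def sample_entropy(series: ComponentSeries, m_pattern: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) in nats; NaN when no template pair matches (undefined).

    ``r`` defaults to 0.15 x the population SD of the series.
    """
    x = series.values
    if r is None:
        r = 0.15 * float(np.std(x))
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    if x.size < m_pattern + 2:
        raise LengthError("need at least m_pattern + 2 samples")
    a, b = _template_counts(x, m_pattern, r)
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def multiscale_entropy(
    series: ComponentSeries,
    m_pattern: int = 2,
    r_factor: float = 0.15,
    tau_max: int = 20,
) -> MSECurve:
    """Sample entropy of the coarse-grained series at scales 1..tau_max.

    The tolerance r is fixed from the scale-1 series (r_factor x its SD) and
    held constant across scales, the standard multiscale-entropy convention,
    so the curve reflects structure and not a shrinking yardstick.
    """
    r = r_factor * float(np.std(series.values))
    if r <= 0:
        raise ValueError("series is constant up to machine precision" if r == 0 else "bad r")
    scales = np.arange(1, tau_max + 1)
    values = np.full(scales.size, np.nan)
    defined = np.zeros(scales.size, dtype=bool)
    for k, tau in enumerate(scales):
        try:
            cg = coarse_grain(series, int(tau))
            se = sample_entropy(cg, m_pattern, r)
        except (ValueError, LengthError):
            continue
        values[k] = se
        defined[k] = np.isfinite(se)
    return MSECurve(scales, values, defined, m_pattern, r)


def k2_entropy(
    curve_m: CorrelationCurve,
    curve_m1: CorrelationCurve,
    epsilon: float,
    tau_seconds: float,
) -> K2Estimate:
    """Correlation entropy K2 = (1/tau) ln[C_m(eps) / C_{m+1}(eps)] in nats/s.

    Correlation sums are interpolated log-log onto the requested threshold.
    """
    if curve_m1.m != curve_m.m + 1:
        raise ValueError("curves must be at consecutive embedding dimensions")
    if tau_seconds <= 0:
        raise ValueError("tau_seconds must be positive")

    def _interp(curve: CorrelationCurve) -> float:
        pos = curve.C > 0
        if pos.sum() < 2:
            raise ValueError("correlation sum vanishes; K2 undefined")
        ln_c = np.interp(np.log(epsilon), np.log(curve.epsilons[pos]), np.log(curve.C[pos]))
        return float(np.exp(ln_c))

    cm, cm1 = _interp(curve_m), _interp(curve_m1)
    if cm1 <= 0:
        raise ValueError("correlation sum vanishes at m+1; K2 undefined")
    return K2Estimate(float(np.log(cm / cm1) / tau_seconds), curve_m.m, float(epsilon))
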