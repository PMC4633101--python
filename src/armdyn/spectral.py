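"""Power and phase spectra, log-log slope fits and tremor-band peak detection.

Per-subject spectra are single full-length FFTs (no windowing or segment
averaging), mirroring how raw kinematic spectra are usually inspected; a
Welch estimate is available behind a flag for noise-floor checks.  The
one-sided power is normalised so that its sum equals the variance of the
mean-removed series (a discrete Parseval identity), which keeps slopes and
band powers comparable across series lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io_preprocess import ComponentSeries, LengthError


@dataclass(frozen=True)
class Spectrum:
    frequencies: np.ndarray  # Hz, strictly increasing, excludes DC
    power: np.ndarray        # one-sided; sums to time-domain variance
    phase: np.ndarray | None  # radians in (-pi, pi]; None for averaged spectra
    n_samples: int
    sampling_rate: float


def power_phase_spectrum(series: ComponentSeries, welch: bool = False) -> Spectrum:
    """One-sided power and phase spectrum of a single channel via the FFT."""
    x = series.values
    n = x.size
    if n < 4:
        raise LengthError("need at least 4 samples for a spectrum")
    x = x - x.mean()
    if welch:
        freqs, pxx = sps.welch(x, fs=series.sampling_rate, nperseg=min(n, 256))
        keep = freqs > 0
        scale = pxx[keep].sum()
        power = pxx[keep] * (x.var() / scale if scale > 0 else 1.0)
        return Spectrum(freqs[keep], power, None, n, series.sampling_rate)
    coef = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / series.sampling_rate)
    # one-sided power; double interior bins so the sum equals the variance
    power = np.abs(coef) ** 2 / n**2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    phase = np.angle(coef)
    return Spectrum(freqs[1:], power[1:], phase[1:], n, series.sampling_rate)


def group_average_spectrum(spectra: list[Spectrum]) -> Spectrum:
    """Bin-wise linear average of power; phase is dropped (undefined)."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    ref = spectra[0]
    for sp in spectra[1:]:
        if sp.frequencies.shape != ref.frequencies.shape or not np.allclose(
            sp.frequencies, ref.frequencies
        ):
            raise ValueError("spectra do not share a common frequency grid")
    power = np.mean([sp.power for sp in spectra], axis=0)
    return Spectrum(ref.frequencies.copy(), power, None, ref.n_samples, ref.sampling_rate)


def loglog_slope(spectrum: Spectrum, band: tuple[float, float] = (0.5, 10.0)) -> float:
    """Least-squares slope of log10 power vs log10 frequency over ``band``.

    Brownian (integrated white) noise gives a slope near -2; white noise
    gives a slope near 0.  Zero-power bins are excluded with a warning.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must be a nonempty (low, high) interval")
    mask = (spectrum.frequencies >= lo) & (spectrum.frequencies <= hi)
    if mask.sum() < 5:
        raise ValueError("need at least 5 frequency bins inside the band")
    f = spectrum.frequencies[mask]
    p = spectrum.power[mask]
    pos = p > 0
    if not pos.all():
        warnings.warn("excluding zero-power bins from log-log slope fit")
        f, p = f[pos], p[pos]
        if f.size < 2:
            raise ValueError("not enough positive-power bins in band")
    slope, _ = np.polyfit(np.log10(f), np.log10(p), 1)
    return float(slope)


def band_peak(
    spectrum: Spectrum, band: tuple[float, float] = (2.0, 3.0)
) -> tuple[float, float]:
    """Frequency of maximum power in ``band`` and its prominence.

    Prominence is peak power over the median power in the band; a flat
    spectrum yields a prominence near 1, a tremor line a large one.
    """
    lo, hi = band
    mask = (spectrum.frequencies >= lo) & (spectrum.frequencies <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    f = spectrum.frequencies[mask]
    p = spectrum.power[mask]
    k = int(np.argmax(p))
    med = float(np.median(p))
    prominence = float(p[k] / med) if med > 0 else np.inf
    return float(f[k]), prominence
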