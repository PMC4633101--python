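"""Dimensional complexity: delay embedding, correlation sums, plateau D2,
the finite-length dimension bound, and IAAFT surrogate hypothesis testing.

The correlation dimension D2 is read off the scaling region of the revised
correlation sum

    C(eps) = 2 / ((N-W)(N-1-W)) * sum_{t2 > t1+W} Theta(eps - ||x(t1)-x(t2)||)

computed with the maximum-norm distance on Takens delay vectors and a Theiler
window W that excludes temporally adjacent pairs.  D2 is the slope of
ln C vs ln eps on a plateau of the local-slope curve; the plateau is found
automatically by an unevenness criterion so no by-eye judgement enters.

Because only N points are available, estimated dimensions cannot exceed
d_max = 2 log N / log(1/rho) (rho = eps/diameter); estimates above this bound
are flagged as unreliable rather than rejected.

The surrogate test compares the bare D2 against D2 values from iterative
amplitude-adjusted Fourier-transform (IAAFT) surrogates, which preserve the
amplitude distribution exactly and the power spectrum almost exactly and so
realise the null of a monotonically transformed linear stochastic process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .io_preprocess import ComponentSeries, LengthError

DEFAULT_M_LIST = tuple(range(10, 28, 2))  # 10, 12, ..., 26
DEFAULT_TAU = 5
DEFAULT_THEILER = 5


@dataclass(frozen=True)
class DelayEmbedding:
    """Delay vectors x(t) = (s(t-(m-1)τ), ..., s(t))."""

    vectors: np.ndarray  # (n_vectors, m)
    m: int
    tau: int

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class CorrelationCurve:
    epsilons: np.ndarray
    C: np.ndarray
    W: int
    m: int
    tau: int


@dataclass(frozen=True)
class SlopeCurve:
    """Local slopes d ln C / d ln eps, with the center C value of each window."""

    ln_eps: np.ndarray
    slope: np.ndarray
    center_C: np.ndarray


@dataclass
class PlateauResult:
    start_index: int = -1
    end_index: int = -1
    length: int = 0
    unevenness: float = np.nan
    D2: float = np.nan
    valid: bool = False
    failure_reason: str = "none"  # none | no_plateau | unstable_across_m
    ln_eps_mid: float = np.nan
    ln_eps_width: float = np.nan


@dataclass(frozen=True)
class LimitCheck:
    N: int
    rho: float
    d_max: float
    exceeded: bool | None = None


@dataclass
class SurrogateTestResult:
    bare_statistic: float
    surrogate_statistics: np.ndarray
    n_requested: int
    n_valid: int
    level: float
    rejected: bool
    evaluable: bool


def embed(series: ComponentSeries | np.ndarray, m: int, tau: int) -> DelayEmbedding:
    """Takens delay embedding with dimension ``m`` and delay ``tau`` samples."""
    x = series.values if isinstance(series, ComponentSeries) else np.asarray(series, float)
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be >= 1")
    n = x.size - (m - 1) * tau
    if n < 1:
        raise LengthError(
            f"series of length {x.size} too short for m={m}, tau={tau}"
        )
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return DelayEmbedding(x[idx], m, tau)


def _pair_distances(vectors: np.ndarray, W: int) -> np.ndarray:
    """Max-norm distances of all vector pairs separated by more than W samples."""
    n = vectors.shape[0]
    D = cdist(vectors, vectors, "chebyshev")
    iu = np.triu_indices(n, k=W + 1)
    return D[iu]


def correlation_sum(
    embedding: DelayEmbedding, epsilons: np.ndarray, W: int = DEFAULT_THEILER
) -> CorrelationCurve:
    """Revised correlation sum on a grid of thresholds (exact pair counting).

    Pairs with temporal separation <= W are excluded (Theiler correction) and
    the count is normalised by (N-W)(N-1-W)/2, the number of admissible pairs,
    so that C -> 1 once eps exceeds the attractor diameter.
    """
    eps = np.asarray(epsilons, dtype=float)
    if eps.ndim != 1 or eps.size < 1 or np.any(eps <= 0) or np.any(np.diff(eps) <= 0):
        raise ValueError("epsilons must be a strictly increasing positive grid")
    if W < 0:
        raise ValueError("Theiler window W must be >= 0")
    n = embedding.n_vectors
    if n - 1 - W < 1:
        raise LengthError("embedding too short for this Theiler window")
    d = np.sort(_pair_distances(embedding.vectors, W))
    counts = np.searchsorted(d, eps, side="right")  # Theta(eps - d) with Theta(0)=1
    norm = 0.5 * (n - W) * (n - 1 - W)
    return CorrelationCurve(eps, counts / norm, W, embedding.m, embedding.tau)


def slope_curve(curve: CorrelationCurve, window: int = 5) -> SlopeCurve:
    """Sliding least-squares slope of ln C vs ln eps over ``window`` grid points."""
    if window < 2:
        raise ValueError("window must be >= 2")
    pos = curve.C > 0
    if pos.sum() < window:
        raise LengthError("fewer positive correlation-sum points than the window")
    ln_e = np.log(curve.epsilons[pos])
    ln_c = np.log(curve.C[pos])
    c_pos = curve.C[pos]
    n = ln_e.size - window + 1
    mids = np.empty(n)
    slopes = np.empty(n)
    centers = np.empty(n)
    half = window // 2
    for i in range(n):
        xe = ln_e[i : i + window]
        ye = ln_c[i : i + window]
        slopes[i] = np.polyfit(xe, ye, 1)[0]
        mids[i] = xe[half]
        centers[i] = c_pos[i + half]
    return SlopeCurve(mids, slopes, centers)


def extract_plateau(
    slopes: SlopeCurve,
    max_unevenness: float = 0.4,
    min_length: int = 3,
    min_length_fraction: float | None = None,
    c_range: tuple[float, float] = (1e-4, 0.5),
) -> PlateauResult:
    """Longest contiguous slope window whose unevenness stays below the bound.

    Unevenness of a window is (max slope - min slope) / max slope.  Among all
    windows meeting the bound the longest is returned (ties broken toward
    smaller eps); D2 is the mean slope over the window.  The search is
    restricted to slope points whose central correlation-sum value lies in
    ``c_range``, excluding both the statistically starved small-eps head and
    the saturated C -> 1 tail where the slope trivially collapses to zero.
    ``min_length_fraction`` (surrogate mode) demands the plateau cover at
    least that fraction of the usable grid.
    """
    sl = slopes.slope
    usable = np.isfinite(sl) & (slopes.center_C >= c_range[0]) & (slopes.center_C <= c_range[1])
    idx = np.flatnonzero(usable)
    if min_length_fraction is not None:
        min_length = max(min_length, int(np.ceil(min_length_fraction * sl.size)))
    result = PlateauResult(failure_reason="no_plateau")
    if idx.size < min_length:
        return result
    # scan maximal contiguous runs of usable points
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    best = None  # (length, -start) ordering
    for run in runs:
        n = run.size
        if n < min_length:
            continue
        s = sl[run]
        for length in range(n, min_length - 1, -1):
            if best is not None and length < best[0]:
                break
            for start in range(0, n - length + 1):
                w = s[start : start + length]
                mx = w.max()
                if mx <= 0:
                    continue
                unev = (mx - w.min()) / mx
                if unev <= max_unevenness:
                    key = (length, -run[start])
                    if best is None or key > best[:2]:
                        best = (length, -run[start], run[start], unev)
                    break  # longer-at-this-length windows: keep first (smaller eps)
    if best is None:
        return result
    _, _, start, unev = best
    length = best[0]
    end = start + length - 1
    w = sl[start : end + 1]
    ln_e = slopes.ln_eps
    return PlateauResult(
        start_index=start,
        end_index=end,
        length=length,
        unevenness=float(unev),
        D2=float(w.mean()),
        valid=True,
        failure_reason="none",
        ln_eps_mid=float(0.5 * (ln_e[start] + ln_e[end])),
        ln_eps_width=float(ln_e[end] - ln_e[start]),
    )


def epsilon_grid(series_values: np.ndarray, n_eps: int = 100,
                 rel_range: tuple[float, float] = (1e-3, 1.0)) -> np.ndarray:
    """Log-spaced thresholds spanning ``rel_range`` x the max-norm diameter.

    The Chebyshev diameter of any delay embedding of a scalar series equals
    the range of the series, so one grid serves every embedding dimension.
    """
    diam = float(np.ptp(series_values))
    if diam <= 0:
        raise ValueError("constant series has no attractor diameter")
    return diam * np.logspace(np.log10(rel_range[0]), np.log10(rel_range[1]), n_eps)


def dmax_limit(N: int, rho: float = 0.1, D2: float | None = None) -> LimitCheck:
    """Finite-sample dimension bound d_max = 2 log N / log(1/rho)."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    d_max = 2.0 * np.log10(N) / np.log10(1.0 / rho)
    exceeded = None if D2 is None else bool(D2 > d_max)
    return LimitCheck(N, rho, float(d_max), exceeded)


@dataclass
class ComplexityResult:
    """D2 at the reporting dimension plus the per-m diagnostic sweep."""

    plateau: PlateauResult
    per_m: dict[int, PlateauResult]
    limit: LimitCheck
    m_report: int
    tau: int
    W: int


def dimensional_complexity(
    series: ComponentSeries,
    m_list: tuple[int, ...] = DEFAULT_M_LIST,
    tau: int = DEFAULT_TAU,
    W: int = DEFAULT_THEILER,
    n_eps: int = 100,
    max_unevenness: float = 0.4,
    min_length_fraction: float | None = None,
    rho: float = 0.1,
    slope_window: int = 5,
) -> ComplexityResult:
    """Full D2 pipeline: embed at each m, extract plateaus, check stability.

    D2 is reported at the largest embedding dimension.  If the plateau's
    eps-location drifts across the m sweep by more than half the mean plateau
    width the result is flagged ``unstable_across_m`` -- detected plateaus
    that move with m cannot be trusted as a dimension.
    """
    eps = epsilon_grid(series.values, n_eps)
    per_m: dict[int, PlateauResult] = {}
    for m in sorted(m_list):
        emb = embed(series, m, tau)
        curve = correlation_sum(emb, eps, W)
        try:
            sl = slope_curve(curve, slope_window)
        except LengthError:
            per_m[m] = PlateauResult(failure_reason="no_plateau")
            continue
        per_m[m] = extract_plateau(
            sl, max_unevenness=max_unevenness, min_length_fraction=min_length_fraction
        )
    m_report = max(m_list)
    plateau = PlateauResult(**vars(per_m[m_report]))
    mids = [p.ln_eps_mid for p in per_m.values() if p.valid]
    widths = [p.ln_eps_width for p in per_m.values() if p.valid]
    if plateau.valid and len(mids) >= 2:
        drift = max(mids) - min(mids)
        tol = 0.5 * float(np.mean(widths))
        if drift > max(tol, 1e-12):
            plateau.valid = False
            plateau.failure_reason = "unstable_across_m"
    limit = dmax_limit(series.n_samples, rho, plateau.D2 if np.isfinite(plateau.D2) else None)
    return ComplexityResult(plateau, per_m, limit, m_report, tau, W)


def iaaft_surrogate(
    series: ComponentSeries,
    max_iter: int = 200,
    seed: int | np.random.Generator | None = None,
) -> ComponentSeries:
    """IAAFT surrogate: exact amplitude distribution, near-exact power spectrum.

    Alternates spectrum adjustment (impose the original Fourier amplitudes)
    with rank-ordering (impose the original value multiset) until the rank
    permutation stops changing or ``max_iter`` is reached.
    """
    x = series.values
    if x.size < 8:
        raise LengthError("need at least 8 samples for an IAAFT surrogate")
    if np.ptp(x) == 0:
        warnings.warn("constant series: IAAFT surrogate returned unchanged")
        return replace(series, values=x.copy())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    y = rng.permutation(x)
    prev_ranks = None
    for _ in range(max_iter):
        spec = np.fft.rfft(y)
        mag = np.abs(spec)
        phase = np.where(mag > 0, spec / np.where(mag > 0, mag, 1.0), 1.0)
        y = np.fft.irfft(target_amp * phase, n=x.size)
        ranks = np.argsort(np.argsort(y, kind="stable"), kind="stable")
        y = sorted_x[ranks]
        if prev_ranks is not None and np.array_equal(ranks, prev_ranks):
            break
        prev_ranks = ranks
    return replace(series, values=y)


def surrogate_test(
    series: ComponentSeries,
    n_surrogates: int = 100,
    level: float = 0.99,
    seed: int | np.random.Generator | None = None,
    m: int = 26,
    tau: int = DEFAULT_TAU,
    W: int = DEFAULT_THEILER,
    n_eps: int = 100,
    min_valid_fraction: float = 0.9,
    bare: PlateauResult | None = None,
) -> SurrogateTestResult:
    """One-sided rank test of the bare D2 against IAAFT-surrogate D2 values.

    Determinism lowers D2 relative to linear-stochastic surrogates, so the
    null is rejected when the bare D2 lies below every valid surrogate D2;
    with 100 surrogates the attained one-sided p-value is 1/101 < 0.01.
    Surrogate plateaus use the relaxed criteria (unevenness < 0.4 and length
    at least 10% of the grid) and the test is declared non-evaluable when
    fewer than ``min_valid_fraction`` of surrogates yield a plateau.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _d2(s: ComponentSeries, relaxed: bool) -> PlateauResult:
        eps = epsilon_grid(s.values, n_eps)
        emb = embed(s, m, tau)
        curve = correlation_sum(emb, eps, W)
        try:
            sl = slope_curve(curve)
        except LengthError:
            return PlateauResult(failure_reason="no_plateau")
        return extract_plateau(
            sl, min_length_fraction=0.1 if relaxed else None
        )

    if bare is None:
        bare = _d2(series, relaxed=False)
    if not bare.valid or not np.isfinite(bare.D2):
        raise ValueError("bare series has no valid D2; surrogate test undefined")
    stats = []
    for _ in range(n_surrogates):
        surr = iaaft_surrogate(series, seed=rng)
        res = _d2(surr, relaxed=True)
        if res.valid and np.isfinite(res.D2):
            stats.append(res.D2)
    stats_arr = np.asarray(stats)
    n_valid = stats_arr.size
    evaluable = n_valid >= int(np.ceil(min_valid_fraction * n_surrogates))
    rejected = bool(evaluable and n_valid > 0 and bare.D2 < stats_arr.min())
    return SurrogateTestResult(
        bare_statistic=bare.D2,
        surrogate_statistics=stats_arr,
        n_requested=n_surrogates,
        n_valid=int(n_valid),
        level=level,
        rejected=rejected,
        evaluable=evaluable,
    )
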