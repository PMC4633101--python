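"""Delay embedding, correlation sums, plateau extraction, d_max and IAAFT."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from armdyn.complexity import (
    CorrelationCurve,
    DelayEmbedding,
    SlopeCurve,
    correlation_sum,
    dmax_limit,
    embed,
    epsilon_grid,
    extract_plateau,
    iaaft_surrogate,
    slope_curve,
)
from armdyn.io_preprocess import ComponentSeries, LengthError


def brute_force_correlation_sum(vectors, epsilons, W):
    """Independent O(N^2) oracle: explicit loop over every admissible pair."""
    n = len(vectors)
    counts = np.zeros(len(epsilons), dtype=int)
    n_pairs = 0
    for t1 in range(n):
        for t2 in range(t1 + 1 + W, n):
            d = np.max(np.abs(vectors[t1] - vectors[t2]))
            counts += d <= epsilons
            n_pairs += 1
    return counts, n_pairs


class TestEmbed:
    def test_reproduces_defining_coordinates(self):
        series = np.arange(1.0, 11.0)
        emb = embed(series, m=2, tau=1)
        assert emb.n_vectors == 9
        np.testing.assert_array_equal(emb.vectors[0], [1.0, 2.0])
        np.testing.assert_array_equal(emb.vectors[-1], [9.0, 10.0])

    def test_m_equal_one_returns_the_series(self):
        series = np.arange(5.0)
        emb = embed(series, m=1, tau=3)
        np.testing.assert_array_equal(emb.vectors[:, 0], series)

    def test_vector_count_formula(self):
        emb = embed(np.zeros(2000), m=26, tau=5)
        assert emb.n_vectors == 1875

    def test_insufficient_length_rejected(self):
        with pytest.raises(LengthError):
            embed(np.zeros(10), m=5, tau=3)


class TestCorrelationSum:
    def test_identical_points_saturate_at_one(self):
        emb = DelayEmbedding(np.zeros((3, 1)), 1, 1)
        curve = correlation_sum(emb, np.array([0.5, 1.0]), W=0)
        np.testing.assert_array_equal(curve.C, [1.0, 1.0])

    def test_three_point_hand_count(self):
        # points {0, 1, 3}: pairs within 1.5 -> only (0,1); C = 2/(3*2) * 1 = 1/3
        emb = DelayEmbedding(np.array([[0.0], [1.0], [3.0]]), 1, 1)
        curve = correlation_sum(emb, np.array([1.5]), W=0)
        assert curve.C[0] == pytest.approx(1.0 / 3.0)

    def test_threshold_beyond_diameter_gives_one(self):
        rng = np.random.default_rng(0)
        emb = DelayEmbedding(rng.normal(size=(40, 3)), 3, 1)
        diam = np.max(
            [np.max(np.abs(a - b)) for a in emb.vectors for b in emb.vectors]
        )
        curve = correlation_sum(emb, np.array([diam / 2, diam + 1e-9]), W=0)
        assert curve.C[-1] == 1.0

    @pytest.mark.parametrize("seed,n,m,w", [(0, 50, 2, 0), (1, 120, 3, 5), (2, 200, 4, 5)])
    def test_matches_brute_force_pair_count_exactly(self, seed, n, m, w):
        rng = np.random.default_rng(seed)
        emb = embed(rng.standard_normal(n + (m - 1)), m=m, tau=1)
        eps = np.sort(rng.uniform(0.05, 4.0, 12))
        curve = correlation_sum(emb, eps, W=w)
        counts, n_pairs = brute_force_correlation_sum(emb.vectors, eps, w)
        nv = emb.n_vectors
        assert n_pairs == (nv - w) * (nv - 1 - w) // 2
        np.testing.assert_allclose(curve.C, counts / n_pairs, rtol=0, atol=1e-15)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=1000))
    def test_monotone_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        emb = embed(rng.standard_normal(80), m=3, tau=2)
        eps = np.logspace(-2, 1, 30)
        curve = correlation_sum(emb, eps, W=3)
        assert np.all(np.diff(curve.C) >= 0)
        assert curve.C.min() >= 0 and curve.C.max() <= 1


class TestSlopeCurve:
    def _curve(self, eps, C):
        return CorrelationCurve(eps, C, W=0, m=2, tau=1)

    @pytest.mark.parametrize("exponent", [2.0, 0.0, 1.22])
    def test_exact_power_law_recovered(self, exponent):
        eps = np.logspace(-2, 0, 40)
        sl = slope_curve(self._curve(eps, eps**exponent), window=5)
        np.testing.assert_allclose(sl.slope, exponent, atol=1e-6)

    def test_too_few_positive_points_rejected(self):
        eps = np.logspace(-2, 0, 10)
        C = np.zeros(10)
        C[-2:] = [0.5, 1.0]
        with pytest.raises(LengthError):
            slope_curve(self._curve(eps, C), window=5)


class TestExtractPlateau:
    def _slopes(self, values, C=None):
        v = np.asarray(values, float)
        ln_eps = np.linspace(-5, 0, v.size)
        c = np.full(v.size, 0.01) if C is None else np.asarray(C)
        return SlopeCurve(ln_eps, v, c)

    def test_flat_curve_spans_full_range(self):
        res = extract_plateau(self._slopes(np.full(30, 2.5)))
        assert res.valid
        assert res.length == 30
        assert res.unevenness == 0.0
        assert res.D2 == pytest.approx(2.5)

    def test_step_curve_confined_to_one_level(self):
        values = np.r_[np.full(15, 2.0), np.full(15, 5.0)]
        res = extract_plateau(self._slopes(values))
        # both halves are admissible; tie broken toward smaller epsilon
        assert res.length == 15
        assert res.start_index == 0
        assert res.D2 == pytest.approx(2.0)

    def test_brute_force_window_selection_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0.5, 5.0, 40)
        res = extract_plateau(self._slopes(values), max_unevenness=0.4, min_length=3)
        # enumerate every window explicitly
        best = None
        for i in range(40):
            for j in range(i + 2, 40):
                w = values[i : j + 1]
                unev = (w.max() - w.min()) / w.max()
                if unev <= 0.4:
                    key = (j - i + 1, -i)
                    if best is None or key > best[0]:
                        best = (key, i, j)
        assert res.valid
        _, i, j = best
        assert (res.start_index, res.end_index) == (i, j)
        assert res.D2 == pytest.approx(values[i : j + 1].mean())

    def test_everywhere_uneven_curve_fails(self):
        values = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        res = extract_plateau(self._slopes(values), min_length=3)
        assert not res.valid
        assert res.failure_reason == "no_plateau"

    def test_saturated_tail_not_mistaken_for_plateau(self):
        # slope collapses to ~0 where C ~ 1; that region must be excluded
        values = np.r_[np.full(10, 3.0), np.full(10, 0.01)]
        C = np.r_[np.full(10, 0.01), np.full(10, 0.99)]
        res = extract_plateau(self._slopes(values, C))
        assert res.valid
        assert res.D2 == pytest.approx(3.0)


class TestDmaxLimit:
    def test_published_reference_point(self):
        chk = dmax_limit(2000, 0.1)
        assert chk.d_max == pytest.approx(6.60, abs=0.005)

    def test_small_sample_value(self):
        assert dmax_limit(10, 0.1).d_max == pytest.approx(2.0)

    def test_other_rho(self):
        assert dmax_limit(1000, 0.01).d_max == pytest.approx(3.0)

    def test_exceeded_flag(self):
        assert dmax_limit(2000, 0.1, D2=7.0).exceeded is True
        assert dmax_limit(2000, 0.1, D2=5.0).exceeded is False

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            dmax_limit(2000, 1.0)


class TestIAAFT:
    def test_constant_series_returned_unchanged(self):
        s = ComponentSeries(np.full(32, 3.0), 100.0)
        with pytest.warns(UserWarning):
            out = iaaft_surrogate(s, seed=0)
        np.testing.assert_array_equal(out.values, s.values)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_value_multiset_preserved_exactly(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(256) * rng.uniform(0.5, 5)
        s = ComponentSeries(x, 100.0)
        out = iaaft_surrogate(s, seed=seed + 1)
        np.testing.assert_array_equal(np.sort(out.values), np.sort(x))

    def test_spectrum_and_autocorrelation_match(self):
        from conftest import ar2_series

        from armdyn.spectral import power_phase_spectrum

        x = ar2_series(2048, 3)
        s = ComponentSeries(x, 100.0)
        ref = power_phase_spectrum(s).power
        ac_ref = np.array([np.corrcoef(x[:-k], x[k:])[0, 1] for k in range(1, 11)])
        acs = []
        rels = []
        for seed in range(50):
            surr = iaaft_surrogate(s, seed=seed)
            p = power_phase_spectrum(surr).power
            rels.append(np.sqrt(np.mean((p - ref) ** 2)) / np.sqrt(np.mean(ref**2)))
            y = surr.values
            acs.append([np.corrcoef(y[:-k], y[k:])[0, 1] for k in range(1, 11)])
        assert np.mean(rels) < 0.01
        np.testing.assert_allclose(np.mean(acs, axis=0), ac_ref, atol=0.05)


class TestEpsilonGrid:
    def test_grid_spans_relative_range_of_diameter(self):
        x = np.array([0.0, 2.0, 4.0])
        grid = epsilon_grid(x, n_eps=10)
        assert grid[0] == pytest.approx(4.0 * 1e-3)
        assert grid[-1] == pytest.approx(4.0)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            epsilon_grid(np.ones(10))
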