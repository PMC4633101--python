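"""Hilbert phases, synchrony order parameters and Granger causality."""

import warnings

import numpy as np
import pytest

from armdyn.coupling import (
    analytic_phase,
    component_coupling_table,
    granger_conditional,
    granger_pairwise,
    joint_coupling_table,
    phase_synchrony,
)
from armdyn.io_preprocess import ComponentSeries

FS = 100.0


def _tone(freq, n=2000, phase=0.0):
    t = np.arange(n) / FS
    return np.cos(2 * np.pi * freq * t + phase)


def normal_equation_granger(u, v, q):
    """Independent oracle: both OLS fits solved via the normal equations."""
    u = (u - u.mean()) / u.std()
    v = (v - v.mean()) / v.std()
    n = u.size
    y = u[q:]
    X_full = np.column_stack(
        [u[q - k : n - k] for k in range(1, q + 1)]
        + [v[q - k : n - k] for k in range(1, q + 1)]
    )
    X_red = np.column_stack([u[q - k : n - k] for k in range(1, q + 1)])

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return r @ r

    return np.log(rss(X_red) / rss(X_full))


class TestAnalyticPhase:
    def test_cosine_phase_advances_linearly(self):
        p = analytic_phase(ComponentSeries(_tone(2.0), FS))
        inner = slice(200, 1800)
        dphi = np.diff(np.unwrap(p.phases[inner]))
        assert np.allclose(dphi, 2 * np.pi * 2.0 / FS, atol=1e-3)

    def test_sine_lags_cosine_by_half_pi(self):
        pc = analytic_phase(ComponentSeries(_tone(3.0), FS))
        ps = analytic_phase(ComponentSeries(_tone(3.0, phase=-np.pi / 2), FS))
        diff = np.angle(np.exp(1j * (pc.phases - ps.phases)))[200:1800]
        assert np.allclose(diff, np.pi / 2, atol=1e-3)

    def test_unit_tone_envelope_near_one_away_from_edges(self):
        p = analytic_phase(ComponentSeries(_tone(5.0), FS))
        inner = p.amplitude[100:1900]
        assert np.all(np.abs(inner - 1.0) < 0.01)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            analytic_phase(ComponentSeries(np.ones(100), FS))


class TestPhaseSynchrony:
    def test_identical_series_fully_synchronized(self):
        p = analytic_phase(ComponentSeries(_tone(2.0), FS))
        res = phase_synchrony(p, p)
        assert res.psi1 == pytest.approx(1.0)
        assert res.psi2 == pytest.approx(1.0)
        assert res.phi1 == pytest.approx(0.0, abs=1e-12)

    def test_sign_flip_keeps_out_of_phase_order_parameter(self):
        rng = np.random.default_rng(0)
        x = _tone(2.0) + 0.1 * rng.standard_normal(2000)
        a = analytic_phase(ComponentSeries(x, FS))
        b = analytic_phase(ComponentSeries(-x, FS))
        res = phase_synchrony(a, b)
        assert res.psi2 == pytest.approx(1.0, abs=1e-6)
        assert abs(res.phi1) == pytest.approx(np.pi, abs=1e-6)

    def test_psi2_exactly_invariant_under_sign_flip(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        a = analytic_phase(ComponentSeries(x, FS))
        b = analytic_phase(ComponentSeries(y, FS))
        b_neg = analytic_phase(ComponentSeries(-y, FS))
        assert phase_synchrony(a, b).psi2 == pytest.approx(
            phase_synchrony(a, b_neg).psi2, abs=1e-12
        )

    def test_independent_noise_gives_small_order_parameter(self):
        small = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = analytic_phase(ComponentSeries(rng.standard_normal(2000), FS))
            b = analytic_phase(ComponentSeries(rng.standard_normal(2000), FS))
            small += phase_synchrony(a, b).psi1 < 0.1
        assert small >= 48  # Rayleigh: resultant ~ N^(-1/2) ~ 0.022

    def test_order_parameters_bounded(self):
        rng = np.random.default_rng(2)
        a = analytic_phase(ComponentSeries(rng.standard_normal(500), FS))
        b = analytic_phase(ComponentSeries(rng.standard_normal(500), FS))
        res = phase_synchrony(a, b)
        assert 0 <= res.psi1 <= 1 and 0 <= res.psi2 <= 1

    def test_length_mismatch_rejected(self):
        a = analytic_phase(ComponentSeries(_tone(2.0, n=100), FS))
        b = analytic_phase(ComponentSeries(_tone(2.0, n=101), FS))
        with pytest.raises(ValueError):
            phase_synchrony(a, b)


class TestGrangerPairwise:
    def test_independent_noise_has_small_causality(self):
        below = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            u = rng.standard_normal(2000)
            v = rng.standard_normal(2000)
            g = granger_pairwise(u, v, max_order=5)
            below += g.G < 0.05
        assert below >= 48

    def test_lagged_coupling_detected_in_right_direction(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            v = rng.standard_normal(2000)
            u = np.zeros(2000)
            u[2:] = 0.5 * v[:-2]
            u += 0.5 * rng.standard_normal(2000)
            fwd = granger_pairwise(u, v, max_order=10).G
            back = granger_pairwise(v, u, max_order=10).G
            hits += fwd > back
        assert hits >= 19

    def test_identical_series_flagged_degenerate(self):
        rng = np.random.default_rng(3)
        u = rng.standard_normal(1000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = granger_pairwise(u, u, max_order=5)
        assert g.degenerate

    def test_matches_normal_equation_oracle(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 400 + 20 * seed
            v = rng.standard_normal(n)
            u = np.zeros(n)
            u[1:] = 0.4 * v[:-1]
            u += rng.standard_normal(n)
            got = granger_pairwise(u, v, max_order=6)
            want = normal_equation_granger(u, v, got.order_q)
            assert got.G == pytest.approx(want, rel=1e-8)

    def test_causality_never_negative(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            g = granger_pairwise(
                rng.standard_normal(600), rng.standard_normal(600), max_order=8
            )
            assert g.G >= 0

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            granger_pairwise(np.ones(500), np.random.default_rng(0).standard_normal(500))


class TestGrangerConditional:
    def test_conditioning_removes_indirect_chain(self):
        removed = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            v = rng.standard_normal(2000)
            z = np.zeros(2000)
            z[1:] = 0.8 * v[:-1]
            z += 0.3 * rng.standard_normal(2000)
            u = np.zeros(2000)
            u[1:] = 0.8 * z[:-1]
            u += 0.3 * rng.standard_normal(2000)
            pair = granger_pairwise(u, v, max_order=6).G
            cond = granger_conditional(u, v, z, max_order=6).G
            removed += cond < 0.2 * pair
        assert removed >= 9

    def test_direct_coupling_survives_conditioning(self):
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            v = rng.standard_normal(2000)
            z = rng.standard_normal(2000)
            u = np.zeros(2000)
            u[2:] = 0.6 * v[:-2]
            u += 0.6 * rng.standard_normal(2000)
            pair = granger_pairwise(u, v, max_order=6).G
            cond = granger_conditional(u, v, z, max_order=6).G
            ratios.append(cond / pair)
        assert 0.8 < np.mean(ratios) < 1.25

    def test_constant_conditioner_falls_back_to_pairwise(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(1000)
        u = np.zeros(1000)
        u[1:] = 0.5 * v[:-1]
        u += rng.standard_normal(1000)
        with pytest.warns(UserWarning, match="constant"):
            cond = granger_conditional(u, v, np.zeros(1000), max_order=5)
        pair = granger_pairwise(u, v, max_order=5)
        assert cond.G == pytest.approx(pair.G, rel=1e-9)


class TestRecordingTables:
    def test_joint_table_has_nine_rows(self, filtered_normal):
        rows = joint_coupling_table(filtered_normal, max_order=10)
        assert len(rows) == 9
        labels = {r.label for r in rows}
        assert labels == {
            f"{j}_{c}" for j in ("Δf", "Δw", "Δe") for c in ("X", "Y", "Z")
        }

    def test_component_table_counts(self, filtered_normal):
        tab = component_coupling_table(filtered_normal, max_order=10)
        assert len(tab["synchrony"]) == 3
        assert len(tab["causality"]) == 8  # 6 ordered pairs + 2 conditional

    def test_patient_joints_more_synchronized_than_normal(
        self, filtered_normal, filtered_patient
    ):
        rows_n = joint_coupling_table(filtered_normal, max_order=10)
        rows_p = joint_coupling_table(filtered_patient, max_order=10)
        psi_n = np.mean([r.synchrony.psi1 for r in rows_n if r.synchrony])
        psi_p = np.mean([r.synchrony.psi1 for r in rows_p if r.synchrony])
        assert psi_p > psi_n

    def test_dead_channel_row_flagged_others_computed(self, filtered_normal):
        import copy

        rec = copy.deepcopy(filtered_normal)
        rec.series[1, 0] = rec.series[0, 0]  # finger X == rod X -> Δf_X constant
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = joint_coupling_table(rec, max_order=5)
        by_label = {r.label: r for r in rows}
        assert by_label["Δf_X"].failed
        assert not by_label["Δw_Y"].failed
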