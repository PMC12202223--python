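"""Orthogonal subspace projection: delay matrix, projection, dFf and Pr."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fwavetilt.freq import FrequencyTrend
from fwavetilt.modulation import (OSPResult, build_delay_matrix, default_q,
                                  delta_ff, phase_modulation, project,
                                  relative_power)
from fwavetilt.respiration import RespirationEstimate


class TestDelayMatrix:
    def test_documented_small_example(self):
        V = build_delay_matrix(np.array([1.0, 2, 3, 4, 5]), q=2)
        assert V.shape == (3, 3)
        assert np.array_equal(V[:, 0], [1, 2, 3])
        assert np.array_equal(V[:, 1], [2, 3, 4])
        assert np.array_equal(V[:, 2], [3, 4, 5])

    def test_q_zero_single_column(self):
        r = np.arange(10.0)
        V = build_delay_matrix(r, 0)
        assert V.shape == (10, 1)
        assert np.array_equal(V[:, 0], r)

    def test_constant_signal_rank_one(self):
        V = build_delay_matrix(np.ones(50), q=5)
        assert np.linalg.matrix_rank(V) == 1

    def test_oversized_q_rejected(self):
        with pytest.raises(ValueError, match="q"):
            build_delay_matrix(np.arange(10.0), q=5)


class TestProjection:
    def test_vector_in_subspace_unchanged(self, rng):
        V = build_delay_matrix(rng.standard_normal(60), q=4)
        f = V[:, 2].copy()
        assert np.allclose(project(f, V), f, atol=1e-10)

    def test_orthogonal_vector_projects_to_zero(self, rng):
        V = build_delay_matrix(rng.standard_normal(60), q=3)
        Q, _ = np.linalg.qr(V)
        f = rng.standard_normal(V.shape[0])
        f -= Q @ (Q.T @ f)
        assert np.max(np.abs(project(f, V))) < 1e-10

    def test_idempotence(self, rng):
        V = build_delay_matrix(rng.standard_normal(120), q=8)
        f = rng.standard_normal(V.shape[0])
        fr = project(f, V)
        assert np.allclose(project(fr, V), fr, atol=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            M = int(rng.integers(40, 200))
            q = int(rng.integers(0, 15))
            r = rng.standard_normal(M)
            V = build_delay_matrix(r, q)
            f = rng.standard_normal(M - q)
            fr = project(f, V)
            oracle = V @ np.linalg.solve(V.T @ V, V.T @ f)
            assert np.linalg.norm(fr - oracle) <= 1e-8 * np.linalg.norm(f)

    def test_rank_deficient_handled(self):
        V = build_delay_matrix(np.ones(40), q=3)
        f = np.ones(V.shape[0])
        fr = project(f, V)
        assert np.allclose(fr, f, atol=1e-10)


class TestDeltaFfAndPr:
    def test_sinusoid_amplitude_identity(self):
        t = np.arange(50000) / 50.0  # whole cycles of 0.14 Hz within 0.1 %
        fr = 0.25 * np.sin(2 * np.pi * 0.14 * t)
        assert delta_ff(fr) == pytest.approx(0.25, rel=1e-3)

    def test_zero_and_constant(self):
        assert delta_ff(np.zeros(100)) == 0.0
        assert delta_ff(np.full(100, -0.3)) == pytest.approx(np.sqrt(2) * 0.3)

    def test_pr_identities(self, rng):
        f = rng.standard_normal(500)
        assert relative_power(f, f) == pytest.approx(100.0)
        assert relative_power(np.zeros(500), f) == 0.0
        with pytest.warns(UserWarning, match="Pr undefined"):
            assert np.isnan(relative_power(np.zeros(5), np.zeros(5)))

    def test_equal_energy_orthogonal_split_gives_fifty(self, rng):
        fr = rng.standard_normal(400)
        noise = rng.standard_normal(400)
        noise -= (noise @ fr) / (fr @ fr) * fr
        noise *= np.linalg.norm(fr) / np.linalg.norm(noise)
        assert relative_power(fr, fr + noise) == pytest.approx(50.0, abs=1e-6)

    def test_energy_split_complement(self, rng):
        V = build_delay_matrix(np.sin(0.3 * np.arange(300)), q=10)
        f = rng.standard_normal(V.shape[0])
        fr = project(f, V)
        assert relative_power(fr, f) + relative_power(f - fr, f) == pytest.approx(
            100.0, abs=1e-6)

    @given(st.floats(0.01, 1.0))
    @settings(max_examples=20, deadline=None)
    def test_delta_ff_scales_linearly(self, a):
        t = np.arange(3000) / 50.0
        base = np.sin(2 * np.pi * 0.14 * t)
        assert delta_ff(a * base) == pytest.approx(a * delta_ff(base), rel=1e-9)


class TestPhaseModulation:
    def _trend(self, f, valid=None):
        f = np.asarray(f, float)
        valid = np.ones(f.size, bool) if valid is None else valid
        return FrequencyTrend(f=f, valid=valid, s_blocks=np.ones(4), f0=6.7)

    def _resp(self, n, frr=0.14):
        t = np.arange(n) / 50.0
        r = np.sin(2 * np.pi * frr * t)
        return RespirationEstimate(r=r / r.std(), frr=frr, weights=np.ones(2),
                                   epsilon=0.0, t0=0.0)

    def test_constant_trend_degenerate(self):
        n = 9000
        with pytest.warns(UserWarning, match="Pr undefined"):
            res = phase_modulation(self._trend(np.full(n, 6.7)), self._resp(n),
                                   (0.0, 180.0))
        assert res.delta_ff == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(res.pr)

    def test_known_modulation_recovered(self):
        n = 9000
        t = np.arange(n) / 50.0
        f = 6.7 + 0.08 * np.sin(2 * np.pi * 0.14 * t)
        res = phase_modulation(self._trend(f), self._resp(n), (0.0, 180.0))
        assert res.delta_ff == pytest.approx(0.08, rel=0.02)
        assert res.pr > 95.0

    def test_short_valid_run_missing(self):
        n = 9000
        valid = np.zeros(n, bool)
        valid[:2000] = True  # 40 s < 60 s
        with pytest.warns(UserWarning, match="usable run"):
            res = phase_modulation(self._trend(np.full(n, 6.7), valid),
                                   self._resp(n), (0.0, 180.0))
        assert res is None

    def test_small_gaps_bridged_and_reported(self):
        n = 9000
        t = np.arange(n) / 50.0
        f = 6.7 + 0.08 * np.sin(2 * np.pi * 0.14 * t)
        valid = np.ones(n, bool)
        valid[3000:3100] = False  # 2-s gap
        res = phase_modulation(self._trend(f, valid), self._resp(n), (0.0, 180.0))
        assert res.frac_interpolated == pytest.approx(100 / 9000, rel=0.01)
        assert res.delta_ff == pytest.approx(0.08, rel=0.05)

    def test_default_q_quarter_period(self):
        assert default_q(0.14) == round(50 / (4 * 0.14))
        assert default_q(0.25) == 50
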