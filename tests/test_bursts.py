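"""Burst theory: transcription competition, linearity, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lacswitch import (burst_duration, burst_size,
                       calibrate_from_single_molecule,
                       equilibrium_repressor_fractions, mean_burst_from_p,
                       p_transcribe)
from lacswitch.bursts import BurstTable, CalibrationError, binding_rate


class TestPTranscribe:
    def test_no_competition(self):
        assert p_transcribe(0.5, 0.0) == 1.0

    def test_symmetry(self):
        assert p_transcribe(0.3, 0.3) == 0.5

    def test_table_rates(self):
        # k_ts from the rate table against 10 dimers in 0.8 fL
        assert p_transcribe(0.126, 0.0504) == pytest.approx(0.714, abs=5e-4)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            p_transcribe(0.0, 0.0)


class TestMeanBurst:
    @pytest.mark.parametrize("p,expected", [(0.0, 1.0), (0.5, 2.0)])
    def test_values(self, p, expected):
        assert mean_burst_from_p(p) == expected

    def test_identity_with_rates(self):
        # 1/(1-p) with p = k/(k+lam) equals 1 + k/lam
        k, lam = 0.126, 0.05
        assert mean_burst_from_p(p_transcribe(k, lam)) == pytest.approx(
            1 + k / lam)

    def test_divergent_rejected(self):
        with pytest.raises(ValueError):
            mean_burst_from_p(1.0)


class TestRepressorFractions:
    def test_no_inducer(self):
        assert equilibrium_repressor_fractions(0.0, 17.6e-6) == (1.0, 0, 0)

    def test_half_saturation_is_binomial(self):
        f = equilibrium_repressor_fractions(17.6e-6, 17.6e-6)
        assert f == pytest.approx((0.25, 0.5, 0.25))

    @given(st.floats(min_value=0.0, max_value=1e-2))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalization(self, conc):
        assert sum(equilibrium_repressor_fractions(conc, 17.6e-6)) == \
            pytest.approx(1.0)

    def test_matches_four_state_chain(self, tmg_rates):
        # brute-force stationary solve of one dimer's two-site chain
        I = 30e-6
        kon1 = tmg_rates.inducer_on_free_1 * I
        kon2 = tmg_rates.inducer_on_free_2 * I
        koff1 = tmg_rates.inducer_off_free_1
        koff2 = tmg_rates.inducer_off_free_2
        Q = np.array([
            [-kon1, kon1, 0.0],
            [koff1, -(koff1 + kon2), kon2],
            [0.0, koff2, -koff2]])
        M = np.vstack([Q.T, np.ones(3)])
        pi, *_ = np.linalg.lstsq(M, np.concatenate([np.zeros(3), [1.0]]),
                                 rcond=None)
        # tabulated on-rates carry 3-figure rounding, so the binomial
        # closed form agrees to the table's printed precision
        assert equilibrium_repressor_fractions(I, tmg_rates.K_ID) == \
            pytest.approx(tuple(pi), rel=5e-3)


class TestBurstSizeDuration:
    def test_linear_for_equal_affinity(self, tmg_rates):
        K = tmg_rates.K_ID
        b0 = burst_size(0.0, tmg_rates)
        b1 = burst_size(K, tmg_rates)
        assert b1 - 1 == pytest.approx(2 * (b0 - 1), rel=1e-9)

    def test_second_difference_vanishes(self, tmg_rates):
        grid = np.linspace(0, 200e-6, 41)
        B = burst_size(grid, tmg_rates)
        d2 = np.diff(B, 2)
        assert np.max(np.abs(d2)) / np.max(np.abs(B)) < 1e-9

    def test_low_proportionality_is_convex(self, tmg_rates):
        import dataclasses
        low = dataclasses.replace(tmg_rates, C=0.01)
        grid = np.linspace(0, 200e-6, 41)
        d2 = np.diff(burst_size(grid, low), 2)
        assert np.all(d2 > 0)  # visible positive curvature

    def test_monotone_increasing(self, tmg_rates):
        grid = np.linspace(0, 500e-6, 30)
        assert np.all(np.diff(burst_size(grid, tmg_rates)) > 0)

    def test_duration_at_zero(self, tmg_rates):
        # 1 / (k_rb * 10 dimers / (N_A V))
        assert burst_duration(0.0, tmg_rates) == pytest.approx(19.8, abs=0.1)

    def test_duration_at_200uM_is_5pct_of_lifetime(self, tmg_rates):
        frac = burst_duration(200e-6, tmg_rates) / tmg_rates.tau_p
        assert frac == pytest.approx(0.05, rel=0.05)

    def test_duration_linearity(self, tmg_rates):
        K = tmg_rates.K_ID
        ratio = burst_duration(2 * K, tmg_rates) / burst_duration(0, tmg_rates)
        assert ratio == pytest.approx(3.0, rel=1e-9)


class TestCalibration:
    @staticmethod
    def _noiseless_table(rates):
        conc = np.array([0, 20, 40, 50, 75, 100, 200]) * 1e-6
        sizes = 4.0 * burst_size(conc, rates)
        return BurstTable(conc, np.full(conc.size, 3.0), sizes)

    def test_round_trip_recovers_table_rates(self, tmg_rates):
        table = self._noiseless_table(tmg_rates)
        cal = calibrate_from_single_molecule(
            table, base_rates=tmg_rates,
            target_duration=burst_duration(200e-6, tmg_rates))
        assert cal.K_ID == pytest.approx(tmg_rates.K_ID, rel=0.01)
        assert cal.k_ts == pytest.approx(tmg_rates.k_ts, rel=0.01)
        assert cal.k_rb == pytest.approx(tmg_rates.k_rb, rel=0.01)

    def test_burst_frequency_sets_release_rate(self, tmg_rates):
        table = self._noiseless_table(tmg_rates)
        cal = calibrate_from_single_molecule(table, base_rates=tmg_rates)
        # a = 3 per lifetime of 1/2.1e-4 s -> 6.3e-4 per second
        assert cal.k_ro_off == pytest.approx(6.3e-4, rel=1e-6)

    def test_flat_table_rejected(self, tmg_rates):
        conc = np.array([0, 50e-6, 100e-6])
        table = BurstTable(conc, np.full(3, 3.0), np.full(3, 14.0))
        with pytest.raises(CalibrationError):
            calibrate_from_single_molecule(table, base_rates=tmg_rates)


def test_binding_rate_decreases_with_inducer(tmg_rates):
    grid = np.linspace(0, 1e-3, 20)
    lam = np.array([binding_rate(c, tmg_rates) for c in grid])
    assert np.all(np.diff(lam) < 0)
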