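"""Analytic stationary laws against independent brute-force oracles."""

import dataclasses

import numpy as np
import pytest

from lacswitch import (BurstParams, TwoStateParams, gamma_pdf, negbin_pmf,
                       operator_subsystem_solve, stationary_moments,
                       twostate_pmf)
from lacswitch.analytic import twostate_cme_oracle, twostate_mean


class TestNegBin:
    def test_normalization(self):
        p = BurstParams(a=3, b=100)
        n = np.arange(0, 6000)
        assert negbin_pmf(n, p).sum() == pytest.approx(1.0, abs=1e-10)

    def test_mean_identity(self):
        p = BurstParams(a=3, b=100)
        n = np.arange(0, 8000)
        assert (n * negbin_pmf(n, p)).sum() == pytest.approx(300.0, rel=1e-6)

    def test_geometric_special_case(self):
        p = BurstParams(a=1, b=50)
        assert negbin_pmf(0, p) == pytest.approx(1 / 51.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BurstParams(a=-1, b=2)


class TestGammaPdf:
    def test_moments(self):
        from scipy.integrate import quad
        p = BurstParams(a=3, b=100)
        mean, _ = quad(lambda x: x * gamma_pdf(x, p), 0, 5000)
        assert mean == pytest.approx(300.0, rel=1e-6)

    def test_mode(self):
        p = BurstParams(a=3, b=100)
        x = np.linspace(1, 1500, 3000)
        assert x[np.argmax(gamma_pdf(x, p))] == pytest.approx((3 - 1) * 100,
                                                              rel=0.01)

    def test_matches_negbin_envelope_over_bulk(self):
        # continuous limit: discrete and continuous laws agree over the
        # bulk of the distribution (tails diverge as exp(n (1/b - ln(1+1/b))))
        p = BurstParams(a=3, b=100)
        n = np.arange(50, 601)
        ratio = negbin_pmf(n, p) / gamma_pdf(n, p)
        assert np.all(np.abs(ratio - 1) < 0.035)


class TestTwoState:
    @pytest.mark.parametrize("params", [
        TwoStateParams(3, 10, 2, 5),
        TwoStateParams(15, 4, 2, 5),
        TwoStateParams(5, 8, 0.05, 10),
        TwoStateParams(2, 30, 0.3, 0.7),
    ])
    def test_matches_cme_oracle(self, params):
        n_max = int(params.a * params.b * 6 + 300)
        pmf = twostate_pmf(np.arange(n_max + 1), params)
        oracle = twostate_cme_oracle(params, n_max)
        assert 0.5 * np.abs(pmf - oracle).sum() < 1e-6

    def test_negbin_limit(self):
        # vanishing inactivation -> gene always active -> negative binomial
        params = TwoStateParams(3, 10, 2, 1e-7)
        n = np.arange(0, 300)
        nb = negbin_pmf(n, BurstParams(3, 10))
        assert np.max(np.abs(twostate_pmf(n, params) - nb)) < 1e-6

    def test_rare_activation_concentrates_at_zero(self):
        params = TwoStateParams(3, 10, 1e-6, 5)
        assert twostate_pmf(0, params) == pytest.approx(1.0, abs=1e-4)

    def test_normalization_grid(self):
        # coarse sweep of the parameter box used in fitting
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = 10 ** rng.uniform(np.log10(0.5), np.log10(50))
            b = 10 ** rng.uniform(np.log10(0.5), np.log10(50))
            kon = 10 ** rng.uniform(np.log10(0.05), np.log10(50))
            koff = 10 ** rng.uniform(np.log10(0.05), np.log10(50))
            p = TwoStateParams(a, b, kon, koff)
            n_max = int(a * b * 8 + 60 * np.sqrt(a * b * (1 + b)) + 200)
            total = twostate_pmf(np.arange(n_max + 1), p).sum()
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_mean_identity(self):
        p = TwoStateParams(15, 4, 2, 5)
        n = np.arange(0, 600)
        assert (n * twostate_pmf(n, p)).sum() == pytest.approx(
            twostate_mean(p), rel=1e-8)


class TestOperatorSubsystem:
    def test_complex_lifetime_without_inducer(self, tmg_rates):
        sol = operator_subsystem_solve(0.0, tmg_rates)
        assert sol.mean_complex_lifetime == pytest.approx(1 / 6.3e-4,
                                                          rel=1e-6)

    def test_burst_frequency_near_three(self, tmg_rates):
        sol = operator_subsystem_solve(0.0, tmg_rates)
        assert sol.burst_frequency == pytest.approx(3.0, abs=0.15)

    def test_saturating_inducer_frees_operator(self, tmg_rates):
        sol = operator_subsystem_solve(0.1, tmg_rates)  # 100 mM
        assert sol.f_active > 0.99

    def test_burst_frequency_monotone_below_knockoff(self, tmg_rates):
        freqs = [operator_subsystem_solve(c, tmg_rates).burst_frequency
                 for c in (0.0, 50e-6, 100e-6, 200e-6)]
        assert np.all(np.diff(freqs) > 0) or freqs[0] == pytest.approx(
            min(freqs), rel=0.01)

    def test_probabilities_normalized(self, tmg_rates):
        sol = operator_subsystem_solve(50e-6, tmg_rates)
        assert sol.probabilities.sum() == pytest.approx(1.0)


class TestStationaryMoments:
    def test_saturating_mean_protein(self, tmg_rates):
        # k_ts * (k_tl / k_mdeg) / k_pdeg = 2400 with full activity
        m = stationary_moments(0.1, tmg_rates)
        closed = (tmg_rates.k_ts * tmg_rates.proteins_per_mrna
                  / tmg_rates.k_pdeg)
        assert closed == pytest.approx(2400, rel=1e-9)
        assert m.mean_protein == pytest.approx(closed * m.f_active, rel=1e-6)

    def test_fano_at_least_one(self, tmg_rates):
        for conc in (0.0, 20e-6, 100e-6, 500e-6, 2e-3):
            m = stationary_moments(conc, tmg_rates)
            assert m.fano_protein >= 1.0

    def test_always_active_limit_matches_birth_death_theory(self, tmg_rates):
        # with the operator effectively always free, protein Fano equals
        # 1 + k_tl/(k_mdeg + k_pdeg) (translation bursts from mRNA noise)
        m = stationary_moments(1.0, tmg_rates)  # 1 M: fully induced
        expected = 1 + tmg_rates.k_tl / (tmg_rates.k_mdeg + tmg_rates.k_pdeg)
        assert m.fano_protein == pytest.approx(expected, rel=0.02)

    def test_permanently_repressed_limit(self, tmg_rates):
        frozen = dataclasses.replace(tmg_rates, k_ro_off=1e-12,
                                     k_iro_off=1e-12)
        m = stationary_moments(0.0, frozen)
        assert m.mean_protein < 0.1

    def test_pfb_unsupported(self, tmg_rates):
        with pytest.raises(ValueError):
            stationary_moments(0.0, tmg_rates, variant="PFB")
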