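"""Maximum-likelihood parameter recovery on exact-sampler data."""

import numpy as np
import pytest

from lacswitch import (BurstModel, TwoStateModel, gen_negbin_counts,
                       gen_twostate_counts, resample_ci)
from lacswitch.analytic import TwoStateParams


class TestBurstModel:
    @pytest.fixture(scope="class")
    def nb_data(self):
        return gen_negbin_counts(3.0, 100.0, 10000, seed=42)

    def test_recovery_within_5pct(self, nb_data):
        fit = BurstModel(nb_data).fit()
        assert fit.params["a"] == pytest.approx(3.0, rel=0.05)
        assert fit.params["b"] == pytest.approx(100.0, rel=0.05)
        assert fit.converged

    def test_permutation_invariance(self, nb_data):
        fit1 = BurstModel(nb_data).fit()
        rng = np.random.default_rng(0)
        fit2 = BurstModel(rng.permutation(nb_data.protein)).fit()
        assert fit1.params == pytest.approx(fit2.params)

    def test_mean_consistency(self, nb_data):
        fit = BurstModel(nb_data).fit()
        ab = fit.params["a"] * fit.params["b"]
        assert ab == pytest.approx(nb_data.protein.mean(), rel=0.02)

    def test_consistency_with_sample_size(self):
        errs = []
        for n in (1000, 10000):
            d = gen_negbin_counts(3.0, 50.0, n, seed=7)
            fit = BurstModel(d).fit()
            errs.append(abs(fit.params["a"] - 3.0) / 3.0)
        assert errs[1] < max(errs[0], 0.02)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            BurstModel(np.zeros(100, dtype=int))

    def test_summary_mentions_parameters(self, nb_data):
        text = BurstModel(nb_data).fit().summary()
        assert "a" in text and "n cells" in text


class TestTwoStateModel:
    TRUTH = TwoStateParams(15.0, 4.0, 2.0, 5.0)

    @pytest.fixture(scope="class")
    def ts_data(self):
        return gen_twostate_counts(self.TRUTH, 10000, seed=4)

    @pytest.fixture(scope="class")
    def induced_ref(self):
        # fully induced condition: telegraph law reduces to NB(a, b)
        return gen_negbin_counts(15.0, 4.0, 10000, seed=5)

    def test_two_stage_recovery(self, ts_data, induced_ref):
        fit = TwoStateModel(ts_data, induced_reference=induced_ref).fit()
        assert fit.model_kind == "two-state"
        assert fit.params["a"] == pytest.approx(15.0, rel=0.10)
        assert fit.params["b"] == pytest.approx(4.0, rel=0.10)
        assert fit.params["k_on_hat"] == pytest.approx(2.0, rel=0.35)
        assert fit.params["k_off_hat"] == pytest.approx(5.0, rel=0.35)

    def test_slow_inactivation_reduces_to_negbin(self):
        nearly_on = gen_twostate_counts(
            TwoStateParams(10.0, 6.0, 5.0, 0.01), 5000, seed=9)
        ref = gen_negbin_counts(10.0, 6.0, 5000, seed=10)
        fit = TwoStateModel(nearly_on, induced_reference=ref).fit()
        nb = BurstModel(nearly_on).fit()
        # switching adds (almost) nothing: likelihoods agree closely and
        # the inactivation estimate is pinned near zero
        assert fit.nll == pytest.approx(nb.nll, abs=3.0)
        assert fit.params["k_off_hat"] < 0.3


class TestResampleCI:
    @pytest.fixture(scope="class")
    def nb_data(self):
        return gen_negbin_counts(3.0, 100.0, 4000, seed=2)

    def test_degenerate_full_resample(self, nb_data):
        point = BurstModel(nb_data).fit()
        ci = resample_ci(nb_data, BurstModel, subset_size=4000,
                         n_resamples=1, seed=0,
                         fit_kwargs={"n_starts": 1})
        for name in ("a", "b"):
            lo, hi, _ = ci[name]
            assert lo == pytest.approx(hi)
            assert lo == pytest.approx(point.params[name], rel=0.01)

    def test_ci_narrows_with_subset_size(self, nb_data):
        widths = {}
        for size in (50, 200):
            ci = resample_ci(nb_data, BurstModel, subset_size=size,
                             n_resamples=120, seed=1)
            widths[size] = ci["a"][1] - ci["a"][0]
        assert widths[200] < widths[50]

    def test_seed_stability(self, nb_data):
        cis = [resample_ci(nb_data, BurstModel, subset_size=200,
                           n_resamples=150, seed=s)["a"] for s in (1, 2)]
        width = cis[0][1] - cis[0][0]
        assert abs(cis[0][0] - cis[1][0]) < 0.5 * width
        assert abs(cis[0][1] - cis[1][1]) < 0.5 * width

    def test_oversized_subset_rejected(self, nb_data):
        with pytest.raises(ValueError):
            resample_ci(nb_data, BurstModel, subset_size=10 ** 6)
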