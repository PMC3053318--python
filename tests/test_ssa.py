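"""Exactness and reproducibility of the Gillespie engine."""

import numpy as np
import pytest
from scipy import stats

from lacswitch import (extract_operator_events, run_ensemble, ssa_run,
                       stationary_moments, stationary_sample)
from lacswitch.bursts import binding_rate, burst_size
from lacswitch.network import Reaction, ReactionNetwork


def toy_network(reactions, species):
    return ReactionNetwork(species=species, reactions=reactions,
                           clamped=set(), volume=1.0, variant="toy",
                           inducer_kind="-")


class TestExactness:
    def test_pure_decay_follows_exponential(self):
        net = toy_network([Reaction("d", {"A": 1}, {}, 0.02, 1)], ["A"])
        means = []
        for seed in range(40):
            tr = ssa_run(net, np.array([1000]), t_end=50.0,
                         sample_interval=50.0, seed=seed)
            means.append(tr.series("A")[-1])
        expected = 1000 * np.exp(-0.02 * 50)
        sigma = np.sqrt(1000 * np.exp(-1) * (1 - np.exp(-1)) / 40)
        assert abs(np.mean(means) - expected) < 3 * sigma

    def test_birth_death_stationary_poisson(self):
        # k_in/gamma = 40; one long trajectory, decorrelated samples
        net = toy_network([Reaction("in", {}, {"A": 1}, 4.0, 0),
                           Reaction("out", {"A": 1}, {}, 0.1, 1)], ["A"])
        tr = ssa_run(net, np.array([0]), t_end=4000.0, sample_interval=40.0,
                     seed=3)
        samples = tr.series("A")[25:]  # discard transient
        edges = np.arange(15, 70, 5)
        obs, _ = np.histogram(samples, bins=edges)
        pk = np.diff(stats.poisson.cdf(edges - 1, 40))
        pk = pk / pk.sum()
        chi2 = stats.chisquare(obs, pk * obs.sum(), ddof=0)
        assert chi2.pvalue > 0.005

    def test_npf_moments_match_exact_oracle(self, npf_network, tmg_rates):
        conc = 50e-6
        d = stationary_sample(npf_network, conc, n_cells=250, seed=21,
                              burn_in=8)
        oracle = stationary_moments(conc, tmg_rates)
        se = np.sqrt(oracle.var_protein / 250)
        assert abs(d.protein.mean() - oracle.mean_protein) < 3 * se


class TestReproducibility:
    def test_same_master_seed_bitwise_identical(self, npf_network):
        init = npf_network.initial_state(inducer_conc=10e-6)
        kw = dict(n_cells=10, t_end=5000.0, seed=99, sample_interval=500.0)
        e1 = run_ensemble(npf_network, init, **kw)
        e2 = run_ensemble(npf_network, init, **kw)
        for t1, t2 in zip(e1.trajectories, e2.trajectories):
            np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_distinct_cell_seeds(self, npf_network):
        init = npf_network.initial_state()
        ens = run_ensemble(npf_network, init, 50, 100.0, seed=5)
        assert len(set(ens.seeds.tolist())) == 50

    def test_per_cell_initial_states_respected(self, npf_network):
        inits = [npf_network.initial_state(protein=k) for k in (0, 7, 21)]
        ens = run_ensemble(npf_network, inits, 3, 10.0, seed=1,
                           sample_interval=10.0)
        first = [tr.series("Y")[0] for tr in ens.trajectories]
        assert first == [0, 7, 21]


class TestStationarySample:
    def test_birth_death_fano_one(self):
        net = toy_network([Reaction("in", {}, {"A": 1}, 4.0, 0),
                           Reaction("out", {"A": 1}, {}, 0.1, 1)], ["A"])
        finals = [ssa_run(net, np.array([0]), 80.0, 80.0, seed=s
                          ).series("A")[-1] for s in range(300)]
        finals = np.array(finals)
        fano = finals.var(ddof=1) / finals.mean()
        assert fano == pytest.approx(1.0, abs=0.25)

    def test_burn_in_insensitivity(self, npf_network, tmg_rates):
        d1 = stationary_sample(npf_network, 0.0, n_cells=150, seed=4,
                               burn_in=6)
        d2 = stationary_sample(npf_network, 0.0, n_cells=150, seed=5,
                               burn_in=12)
        se = np.sqrt(stationary_moments(0.0, tmg_rates).var_protein
                     * (1 / 150 + 1 / 150))
        assert abs(d1.protein.mean() - d2.protein.mean()) < 3 * se

    def test_rejects_short_burn_in(self, npf_network):
        with pytest.raises(ValueError):
            stationary_sample(npf_network, 0.0, n_cells=2, seed=0, burn_in=2)


class TestOperatorEvents:
    @pytest.fixture(scope="class")
    def logged_run(self, npf_network):
        init = npf_network.initial_state(inducer_conc=0.0)
        logs = ["release_RO", "release_IRO", "release_I2RO",
                "bind_R2", "bind_IR2", "bind_I2R2", "transcription"]
        return ssa_run(npf_network, init, t_end=4e5, sample_interval=1e4,
                       seed=17, log_reactions=logs)

    def test_requires_event_log(self, npf_network):
        tr = ssa_run(npf_network, npf_network.initial_state(), 10.0, 10.0,
                     seed=0)
        with pytest.raises(ValueError):
            extract_operator_events(tr)

    def test_burst_sizes_geometric(self, logged_run, tmg_rates):
        events = extract_operator_events(logged_run)
        sizes = np.array([n for *_, n in events if n > 0])
        assert sizes.size > 50
        expected_mean = burst_size(0.0, tmg_rates)
        se = (expected_mean - 1) / np.sqrt(sizes.size)  # geometric sd ~ b-1
        assert abs(sizes.mean() - expected_mean) < 4 * se

    def test_free_intervals_exponential(self, logged_run, tmg_rates):
        events = extract_operator_events(logged_run)
        durations = np.array([t1 - t0 for t0, t1, _ in events])
        lam = binding_rate(0.0, tmg_rates)
        ks = stats.kstest(durations, "expon", args=(0, 1 / lam))
        assert ks.pvalue > 0.005
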