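"""TE copy-number dynamics: seeding, stepping, stop criteria, conservation."""

import numpy as np
import pytest

from httnet import (
    SimConfig,
    init_state,
    replay_event_log,
    run_single_family,
    run_to_htt_count,
    step,
)
from httnet.dynamics import ConfigError, EventLog


class TestConfig:
    def test_validation(self):
        with pytest.raises(ConfigError):
            SimConfig(u_transposition=1.5)
        with pytest.raises(ConfigError):
            SimConfig(htt_ratio=0.5)
        with pytest.raises(ConfigError):
            SimConfig(target_htt_count=0)
        with pytest.raises(ConfigError):
            SimConfig(capacity_mode="per_planet")

    def test_htt_probability_is_ratio_scaled(self):
        cfg = SimConfig(u_transposition=0.02, htt_ratio=200)
        assert cfg.u_htt == pytest.approx(1e-4)


class TestInit:
    def test_one_copy_per_family(self, sf20):
        cfg = SimConfig()  # 20 species, 30 families
        state = init_state(cfg, sf20)
        assert state.copies.sum() == 30
        assert (state.copies.sum(axis=0) == 1).all()

    def test_single_family_start(self, tiny_network):
        cfg = SimConfig(n_species=6, n_families=1)
        state = init_state(cfg, tiny_network, start_species=5)
        assert state.copies[4, 0] == 1
        assert state.copies.sum() == 1

    def test_same_seed_same_seeding(self, sf20):
        cfg = SimConfig(seed=9)
        s1 = init_state(cfg, sf20)
        s2 = init_state(cfg, sf20)
        assert (s1.copies == s2.copies).all()

    def test_species_mismatch(self, tiny_network):
        with pytest.raises(ConfigError):
            init_state(SimConfig(n_species=20), tiny_network)


class TestStep:
    def test_zero_rates_only_clock_advances(self, tiny_network):
        cfg = SimConfig(n_species=6, n_families=8, u_transposition=0.0)
        state = init_state(cfg, tiny_network)
        before = state.copies.copy()
        step(state, tiny_network, cfg)
        assert state.iteration == 1
        assert (state.copies == before).all()
        assert state.htt_count == 0

    def test_isolated_node_never_transfers(self):
        import networkx as nx

        from httnet.topology import HTTNetwork

        g = nx.Graph()
        g.add_nodes_from([1, 2])  # no edges at all
        net = HTTNetwork(g)
        cfg = SimConfig(n_species=2, n_families=3, u_transposition=0.5,
                        htt_ratio=1, seed=0)
        state = init_state(cfg, net)
        for _ in range(50):
            step(state, net, cfg)
        assert state.htt_count == 0

    def test_capacity_blocks_duplication(self, two_node_net):
        cfg = SimConfig(n_species=2, n_families=1, capacity=10,
                        u_transposition=1.0, htt_ratio=1e9, seed=0)
        state = init_state(cfg, two_node_net, start_species=1)
        for _ in range(30):
            step(state, two_node_net, cfg)
        assert state.copies[0, 0] == 10  # pinned at capacity, never beyond

    def test_per_copy_growth_matches_bernoulli_rate(self, two_node_net):
        """Mean growth of one unsaturated copy over replicates ~ u."""
        u = 0.3
        cfg = SimConfig(n_species=2, n_families=1, capacity=1000,
                        u_transposition=u, htt_ratio=1e9)
        gains = []
        for seed in range(2000):
            state = init_state(cfg, two_node_net, start_species=1,
                               rng=np.random.default_rng(seed))
            step(state, two_node_net, cfg)
            gains.append(state.copies[0, 0] - 1)
        assert np.mean(gains) == pytest.approx(u, abs=3 * 0.46 / np.sqrt(2000))

    def test_per_species_capacity_mode(self, two_node_net):
        cfg = SimConfig(n_species=2, n_families=4, capacity=10,
                        u_transposition=1.0, htt_ratio=1e9,
                        capacity_mode="per_species", seed=1)
        state = init_state(cfg, two_node_net)
        for _ in range(20):
            step(state, two_node_net, cfg)
        assert (state.copies.sum(axis=1) <= 10).all()


class TestRunToHttCount:
    def test_defaults_reach_exact_target(self, sf20):
        res = run_to_htt_count(SimConfig(seed=2), sf20)
        assert res.state.htt_count == 150
        assert not res.truncated
        assert res.log.count("htt") == 150

    def test_target_one_two_nodes(self, two_node_net):
        cfg = SimConfig(n_species=2, n_families=2, capacity=10,
                        target_htt_count=1, seed=0)
        res = run_to_htt_count(cfg, two_node_net)
        assert res.state.htt_count == 1
        assert res.log.count("htt") == 1

    def test_determinism_bit_identical_logs(self, sf20):
        cfg = SimConfig(seed=13)
        r1 = run_to_htt_count(cfg, sf20)
        r2 = run_to_htt_count(cfg, sf20)
        assert r1.log.events == r2.log.events
        assert (r1.copies == r2.copies).all()

    def test_event_log_replay_conserves_copies(self, tiny_network, small_config):
        res = run_to_htt_count(small_config, tiny_network)
        replayed = replay_event_log(res.initial_copies, res.log)
        assert (replayed == res.copies).all()

    def test_replay_with_loss(self, tiny_network):
        cfg = SimConfig(n_species=6, n_families=8, capacity=20,
                        target_htt_count=10, loss_prob=0.002, seed=5,
                        max_iterations=50_000)
        res = run_to_htt_count(cfg, tiny_network)
        assert (replay_event_log(res.initial_copies, res.log) == res.copies).all()
        assert res.log.count("loss") > 0

    def test_monotone_presence_without_loss(self, tiny_network, small_config):
        """With loss off, a family once present stays present."""
        state = init_state(small_config, tiny_network,
                           rng=np.random.default_rng(1))
        seen = state.copies > 0
        for _ in range(500):
            step(state, tiny_network, small_config)
            now = state.copies > 0
            assert (now | ~seen).all()  # seen implies now
            seen = now

    def test_event_log_roundtrip(self, tiny_network, small_config, tmp_path):
        res = run_to_htt_count(small_config, tiny_network)
        p = tmp_path / "events.tsv"
        res.log.to_tsv(p)
        back = EventLog.from_tsv(p)
        assert back.events == res.log.events


class TestSingleFamily:
    def test_isolated_start_truncates_at_one(self):
        import networkx as nx

        from httnet.topology import HTTNetwork

        g = nx.Graph()
        g.add_nodes_from([1, 2, 3])
        g.add_edge(2, 3, weight=1.0)
        net = HTTNetwork(g)
        cfg = SimConfig(n_species=3, n_families=1, capacity=5,
                        max_iterations=200)
        traj = run_single_family(cfg, net, start_species=1, rng=0)
        assert traj.max_infected() == 1
        assert traj.status == "truncated"

    def test_first_passage_geometric_oracle(self, two_node_net):
        """With capacity 1 the founding copy cannot duplicate, so the time
        to infect the second species is geometric with p = u/rho; the mean
        first-passage iteration must match 1/p."""
        u, rho = 0.5, 5.0
        p = u / rho
        cfg = SimConfig(n_species=2, n_families=1, capacity=1,
                        u_transposition=u, htt_ratio=rho, max_iterations=2000)
        times = []
        for seed in range(1500):
            traj = run_single_family(cfg, two_node_net, 1, rng=seed)
            assert traj.status == "completed"
            times.append(traj.first_passage[1])
        sd = np.sqrt((1 - p) / p**2)
        assert np.mean(times) == pytest.approx(1 / p, abs=3 * sd / np.sqrt(1500))

    def test_infection_count_monotone_and_recorded(self, tiny_network):
        cfg = SimConfig(n_species=6, n_families=1, capacity=20,
                        max_iterations=20_000, seed=0)
        traj = run_single_family(cfg, tiny_network, 1, rng=42)
        fp = traj.first_passage
        assert fp[0] == 0
        got = fp[~np.isnan(fp)]
        assert (np.diff(got) >= 0).all()
        assert traj.status == "completed"  # connected net, no loss
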