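"""Serialization, fixtures, pipeline and the command-line surface."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from httnet import BetaMatrix, SimConfig, generate_network, run_pipeline
from httnet.cli import main as cli_main
from httnet.fixtures import make_fixtures, tiny_net
from httnet.io import (
    load_sim_config,
    read_edgelist_tsv,
    read_graphml,
    save_sim_config,
    write_edgelist_tsv,
    write_graphml,
)
from httnet.pipeline import PipelineError

PIPE_CFG = {
    "seed": 42,
    "topology": {"topology": "scale_free", "mean_degree": 3},
    "sim": {"n_species": 10, "n_families": 12, "capacity": 30,
            "target_htt_count": 40},
    "cluster": {"n_blocks": 3},
}


class TestIO:
    def test_graphml_roundtrip(self, tmp_path):
        net = generate_network("modular", 12, n_modules=3, p_within=0.7,
                               p_between=0.1, capacity=17, seed=4)
        p = tmp_path / "net.graphml"
        write_graphml(net, p)
        back = read_graphml(p)
        assert back.edge_set() == net.edge_set()
        assert back.capacities == net.capacities
        assert back.module_assignment == net.module_assignment
        assert back.topology_label == "modular"
        assert back.species_ids == net.species_ids

    def test_edgelist_roundtrip(self, tmp_path):
        net = generate_network("random", 8, mean_degree=3, seed=1)
        p = tmp_path / "net.tsv"
        write_edgelist_tsv(net, p)
        back = read_edgelist_tsv(p, n_species=8)
        assert back.edge_set() == net.edge_set()

    def test_config_roundtrip(self, tmp_path):
        cfg = SimConfig(n_species=7, n_families=5, htt_ratio=250.0, seed=9)
        for name in ("cfg.yaml", "cfg.json"):
            path = tmp_path / name
            save_sim_config(cfg, path)
            assert load_sim_config(path) == cfg

    def test_beta_phylip_export(self, tmp_path, block_beta_matrix):
        p = tmp_path / "beta.phy"
        block_beta_matrix.to_phylip(p)
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "4"
        assert len(lines) == 5


class TestFixtures:
    def test_tiny_net_definition(self):
        net = tiny_net()
        assert net.n_species == 6
        assert net.is_connected()
        mods = net.module_assignment
        assert sorted(mods.values()).count(1) == 3

    def test_make_fixtures_files(self, tmp_path):
        paths = make_fixtures("all", seed=0, outdir=tmp_path)
        assert len(paths) == 3
        assert all(p.exists() for p in paths)

    def test_toy_presence_tsv_roundtrip(self, tmp_path):
        from httnet.diversity import PresenceMatrix

        (p,) = make_fixtures("toy-presence", seed=0, outdir=tmp_path)
        first = p.read_bytes()
        m = PresenceMatrix.from_tsv(p)
        m.to_tsv(p)
        assert p.read_bytes() == first

    def test_unknown_kind(self, tmp_path):
        with pytest.raises(ValueError):
            make_fixtures("nope", outdir=tmp_path)


class TestPipeline:
    def test_full_run_and_manifest(self, tmp_path):
        man = run_pipeline(PIPE_CFG, tmp_path / "run")
        assert man.stages_completed == ["generate", "simulate", "beta", "cluster"]
        assert man.failure is None
        for name in ("network.graphml", "presence.tsv", "beta.tsv",
                     "clustering.tsv", "events.tsv"):
            assert name in man.outputs
            assert (tmp_path / "run" / name).exists()
        assert man.event_counts["htts"] == 40
        data = json.loads((tmp_path / "run" / "manifest.json").read_text())
        assert data["seed"] == 42

    def test_rerun_reproduces_checksums(self, tmp_path):
        m1 = run_pipeline(PIPE_CFG, tmp_path / "a")
        m2 = run_pipeline(PIPE_CFG, tmp_path / "b")
        assert m1.outputs == m2.outputs

    def test_unknown_topology_fails_before_stages(self, tmp_path):
        bad = dict(PIPE_CFG, topology={"topology": "hypercube"})
        with pytest.raises(Exception):
            run_pipeline(bad, tmp_path / "bad")
        assert not (tmp_path / "bad" / "network.graphml").exists()

    def test_config_from_yaml_file(self, tmp_path):
        cfg_path = tmp_path / "pipe.yaml"
        cfg_path.write_text(yaml.safe_dump(PIPE_CFG))
        man = run_pipeline(cfg_path, tmp_path / "run")
        assert man.failure is None


class TestPlots:
    def test_figures_render(self, tmp_path, block_beta_matrix):
        from httnet import SimConfig, propagation_experiment, shuffle_experiment
        from httnet.plots import (
            plot_beta_heatmap,
            plot_propagation,
            plot_shuffle_experiment,
        )

        cfg = SimConfig(n_species=8, n_families=8, capacity=15,
                        target_htt_count=15)
        tab = shuffle_experiment(cfg, {"topology": "scale_free",
                                       "mean_degree": 3},
                                 shuffle_levels=(0, 4), n_networks=2,
                                 n_reps=2, seed=1)
        plot_shuffle_experiment(tab, tmp_path / "shuffle.png")
        net = generate_network("complete", 8, seed=0)
        prop = propagation_experiment(
            SimConfig(n_species=8, n_families=1, capacity=15,
                      u_transposition=0.05, htt_ratio=10,
                      max_iterations=2000),
            {"c": net}, n_reps_per_start=2, seed=2)
        plot_propagation(prop["c"], tmp_path / "prop.png")
        plot_beta_heatmap(block_beta_matrix, tmp_path / "beta.png", 2)
        for name in ("shuffle.png", "prop.png", "beta.png"):
            assert (tmp_path / name).stat().st_size > 0


class TestCLI:
    def test_generate_and_simulate(self, tmp_path):
        runner = CliRunner()
        net_path = tmp_path / "net.graphml"
        res = runner.invoke(cli_main, [
            "generate", "--topology", "scale_free", "--n", "10",
            "--mean-degree", "3", "--seed", "7", "-o", str(net_path),
        ])
        assert res.exit_code == 0, res.output
        assert net_path.exists()

        cfg_path = tmp_path / "sim.yaml"
        save_sim_config(
            SimConfig(n_species=10, n_families=8, capacity=20,
                      target_htt_count=25), cfg_path,
        )
        res = runner.invoke(cli_main, [
            "simulate", "--net", str(net_path), "--config", str(cfg_path),
            "--seed", "1", "-o", str(tmp_path / "run"),
        ])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "run" / "presence.tsv").exists()

        res = runner.invoke(cli_main, [
            "beta", "--presence", str(tmp_path / "run" / "presence.tsv"),
            "-o", str(tmp_path / "beta.tsv"),
        ])
        assert res.exit_code == 0, res.output
        b = BetaMatrix.from_tsv(tmp_path / "beta.tsv")
        assert b.n_species == 10

        res = runner.invoke(cli_main, [
            "cluster", "--beta", str(tmp_path / "beta.tsv"), "--blocks", "3",
        ])
        assert res.exit_code == 0, res.output

    def test_mantel_command(self, tmp_path, block_beta_matrix):
        runner = CliRunner()
        a = tmp_path / "a.tsv"
        block_beta_matrix.to_tsv(a)
        res = runner.invoke(cli_main, ["mantel", str(a), str(a),
                                       "--permutations", "49"])
        assert res.exit_code == 0, res.output
        out = json.loads(res.output)
        assert out["r"] == pytest.approx(1.0)

    def test_fixtures_command(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["fixtures", "all", "-o", str(tmp_path)])
        assert res.exit_code == 0, res.output

    def test_pipeline_command(self, tmp_path):
        runner = CliRunner()
        cfg_path = tmp_path / "pipe.yaml"
        cfg_path.write_text(yaml.safe_dump(PIPE_CFG))
        res = runner.invoke(cli_main, ["pipeline", str(cfg_path), "-o",
                                       str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "manifest.json").exists()
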