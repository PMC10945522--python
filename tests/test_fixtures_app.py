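"""Fixture generation, the YAML pipeline, and CLI round trips."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from chromion import colvars
from chromion.app import ConfigError, RunConfig, pipeline
from chromion.cli import main as cli_main
from chromion.fixtures import make_fixture
from chromion.topology import CGTopology


class TestFixtures:
    def test_ion_box_deterministic_under_seed(self):
        a, sa, _ = make_fixture("ion_box", {"n_na": 20, "n_cl": 20}, seed=7)
        b, sb, _ = make_fixture("ion_box", {"n_na": 20, "n_cl": 20}, seed=7)
        assert np.array_equal(a.positions, b.positions)
        c, _, _ = make_fixture("ion_box", {"n_na": 20, "n_cl": 20}, seed=8)
        assert not np.array_equal(a.positions, c.positions)

    def test_short_duplex_counts(self):
        top, _, _ = make_fixture("short_duplex", {"n_bp": 20})
        assert top.n_beads == 118
        assert sum(s == "P" for s in top.species) == 38

    def test_toy_dinucleosome_invariants(self):
        top, state, extras = make_fixture("toy_dinucleosome")
        assert len(top.rigid_groups) == 2
        r, theta = colvars.pair_cv(state.positions, extras["assembly1"],
                                   extras["assembly2"])
        assert np.isfinite(r) and np.isfinite(theta)
        assert r == pytest.approx(60.0, abs=1.0)

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            make_fixture("nope")

    def test_unused_params_rejected(self):
        with pytest.raises(ValueError, match="unused"):
            make_fixture("ion_box", {"bogus": 1})


class TestPipeline:
    def test_doublewell_umbrella_end_to_end(self, tmp_path):
        cfg = RunConfig(workflow="doublewell_umbrella", seed=4,
                        outdir=str(tmp_path / "dw"),
                        workflow_params={"n_total": 60000})
        summary = pipeline(cfg)
        assert (tmp_path / "dw" / "profile.tsv").exists()
        assert summary["profile_rmse_kT"] <= 0.15

    def test_rerun_same_seed_byte_identical(self, tmp_path):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        for out in (out1, out2):
            pipeline(RunConfig(workflow="doublewell_umbrella", seed=11,
                               outdir=str(out),
                               workflow_params={"n_total": 20000}))
        assert (out1 / "profile.tsv").read_bytes() == \
            (out2 / "profile.tsv").read_bytes()

    def test_md_workflow_writes_artifacts(self, tmp_path):
        cfg = RunConfig(workflow="md", fixture="ion_box",
                        fixture_params={"n_na": 8, "n_cl": 8},
                        box_edge_A=60.0, n_steps=50, report_every=25,
                        outdir=str(tmp_path / "md"), seed=1)
        summary = pipeline(cfg)
        assert (tmp_path / "md" / "trajectory.xyz").exists()
        top = CGTopology.from_json((tmp_path / "md" / "topology.json").read_text())
        assert top.n_beads == 16
        assert "mean_temperature_K" in summary

    def test_invalid_workflow_is_config_error(self):
        with pytest.raises(ConfigError):
            RunConfig(workflow="frobnicate")

    def test_missing_config_file_is_config_error(self, tmp_path):
        with pytest.raises(ConfigError, match="not found"):
            RunConfig.from_yaml(tmp_path / "nope.yaml")

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("workflow: md\nnonsense_key: 3\n")
        with pytest.raises(ConfigError, match="unknown config keys"):
            RunConfig.from_yaml(p)


class TestCLI:
    def setup_method(self):
        self.runner = CliRunner()

    def test_build_from_sequence_roundtrips(self, tmp_path):
        out = tmp_path / "dna.json"
        res = self.runner.invoke(cli_main, ["build", "--sequence", "ATCGATCG",
                                            "-o", str(out)])
        assert res.exit_code == 0, res.output
        top = CGTopology.from_json(out.read_text())
        assert top.n_beads == 2 * (3 * 8 - 1)
        assert out.with_suffix(".pdb").exists()

    def test_solvate_emits_counts_and_topology(self, tmp_path):
        dna = tmp_path / "dna.json"
        self.runner.invoke(cli_main, ["build", "--sequence", "ATCG" * 5,
                                      "-o", str(dna)])
        out = tmp_path / "solv.json"
        res = self.runner.invoke(cli_main, [
            "solvate", "--box-nm3", "216", "--nacl-mm", "150",
            "--solute", str(dna), "-o", str(out)])
        assert res.exit_code == 0, res.output
        top = CGTopology.from_json(out.read_text())
        assert top.total_charge == 0
        tsv = out.with_suffix(".tsv").read_text().splitlines()
        assert tsv[0].startswith("box_nm3")

    def test_fixture_and_run_and_cv_and_analyze(self, tmp_path):
        cfg = tmp_path / "run.yaml"
        outdir = tmp_path / "run_out"
        yaml.safe_dump({"workflow": "md", "fixture": "ion_box",
                        "fixture_params": {"n_na": 6, "n_cl": 6},
                        "box_edge_A": 50.0, "n_steps": 40, "report_every": 20,
                        "outdir": str(outdir), "seed": 2}, cfg.open("w"))
        res = self.runner.invoke(cli_main, ["run", "--config", str(cfg)])
        assert res.exit_code == 0, res.output
        summary = json.loads((outdir / "summary.json").read_text())
        assert "provenance" in summary

        res = self.runner.invoke(cli_main, [
            "analyze", "--traj", str(outdir / "trajectory.xyz"),
            "--topology", str(outdir / "topology.json"),
            "--obs", "condensation", "--box", "50",
            "-o", str(tmp_path / "an.tsv")])
        assert res.exit_code == 0, res.output
        lines = (tmp_path / "an.tsv").read_text().splitlines()
        assert lines[0].split("\t")[0] == "time_ps"

        res = self.runner.invoke(cli_main, [
            "cv", "--traj", str(outdir / "trajectory.xyz"),
            "--topology", str(outdir / "topology.json"),
            "--cv", "r", "--group-a", "IN", "--group-b", "IC",
            "-o", str(tmp_path / "cv.tsv")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "cv.tsv").read_text().startswith("time_ps\tr")

    def test_wham_subcommand_from_window_files(self, tmp_path):
        rng = np.random.default_rng(0)
        recs = []
        for c in (-1.0, 0.0, 1.0):
            f = tmp_path / f"w{c}.txt"
            np.savetxt(f, rng.normal(c, 0.8, 4000))
            recs.append({"k": 0.2, "center": float(c), "file": str(f)})
        wy = tmp_path / "windows.yaml"
        yaml.safe_dump(recs, wy.open("w"))
        out = tmp_path / "prof.tsv"
        res = self.runner.invoke(cli_main, [
            "wham", "--windows", str(wy), "--bins", "-4:4:0.25",
            "-o", str(out)])
        assert res.exit_code == 0, res.output
        assert out.read_text().startswith("# cv")

    def test_bad_config_exits_with_config_code(self, tmp_path):
        res = self.runner.invoke(cli_main, ["run", "--config",
                                            str(tmp_path / "missing.yaml")])
        assert res.exit_code == 2

    def test_build_without_inputs_is_config_error(self):
        res = self.runner.invoke(cli_main, ["build"])
        assert res.exit_code == 2
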