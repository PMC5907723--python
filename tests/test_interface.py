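"""Configuration round-trips, pipeline orchestration contracts and the
command-line interface."""

import dataclasses
import filecmp
import json
from pathlib import Path

import pytest
from click.testing import CliRunner

from satarscan.cli import main
from satarscan.io import (ConfigurationError, RunConfig, read_config,
                          read_fasta, write_config, write_fasta)
from satarscan.pipeline import run_pipeline
from satarscan.simulate import FamilySpec, SimulationSpec, simulate

SMALL_SPEC = SimulationSpec(n_scaffolds=2, scaffold_length=150_000,
                            families=(FamilySpec(400, 40, n_copies=10),
                                      FamilySpec(440, 50, n_copies=8)),
                            n_arrays=2, n_fusions=1, seed=5)


@pytest.fixture(scope="module")
def small_sim():
    return simulate(SMALL_SPEC)


class TestConfig:
    def test_round_trip_is_lossless(self, tmp_path):
        config = RunConfig(assembly_a="a.fasta", seed=42)
        config = dataclasses.replace(
            config,
            discovery=dataclasses.replace(config.discovery, max_len=2000),
            ssr=dataclasses.replace(
                config.ssr, targeting_motifs=frozenset({"AT", "AG"})))
        path = tmp_path / "run.cfg"
        write_config(config, path)
        assert read_config(path) == config

    def test_defaults_round_trip(self, tmp_path):
        path = tmp_path / "defaults.cfg"
        write_config(RunConfig(), path)
        assert read_config(path) == RunConfig()

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("no_such_parameter = 3\n")
        with pytest.raises(ConfigurationError):
            read_config(path)

    def test_fasta_errors(self, tmp_path):
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(ConfigurationError):
            read_fasta(empty)


class TestPipeline:
    def test_outputs_written_and_reproducible(self, small_sim, tmp_path):
        out1, out2 = tmp_path / "run1", tmp_path / "run2"
        for out in (out1, out2):
            config = RunConfig(out_dir=str(out))
            run_pipeline(config, assembly_a=small_sim.assembly_a)
        produced = sorted(p.name for p in out1.iterdir())
        assert {"families.tsv", "families.fasta", "occurrences.gff3",
                "ssrs.gff3", "arrays.tsv", "manifest.json"} <= set(produced)
        for name in produced:
            if name == "manifest.json":
                continue  # records the differing output paths
            assert filecmp.cmp(out1 / name, out2 / name, shallow=False), name
        m1 = json.loads((out1 / "manifest.json").read_text())
        m2 = json.loads((out2 / "manifest.json").read_text())
        for m in (m1, m2):
            m["config"].pop("out_dir")
        assert m1 == m2

    def test_family_summary_row_per_family(self, small_sim, tmp_path):
        config = RunConfig(out_dir=str(tmp_path / "out"))
        result = run_pipeline(config, assembly_a=small_sim.assembly_a)
        lines = (tmp_path / "out" / "families.tsv").read_text().splitlines()
        header = lines[0].split("\t")
        assert header[:4] == ["family", "n_elements", "size_bp", "tir_len"]
        assert "pct_microsatellite" in header and "pct_tsd" in header
        assert len(lines) - 1 == len(result.summaries) == 2

    def test_degenerate_gc_filter_gives_empty_valid_outputs(self, small_sim,
                                                           tmp_path):
        config = RunConfig(out_dir=str(tmp_path / "out"))
        config = dataclasses.replace(
            config, discovery=dataclasses.replace(config.discovery,
                                                  min_gc=1.0))
        result = run_pipeline(config, assembly_a=small_sim.assembly_a)
        assert result.candidates == [] and result.families == []
        assert (tmp_path / "out" / "manifest.json").exists()

    def test_gff_output_is_one_based_inclusive(self, small_sim, tmp_path):
        config = RunConfig(out_dir=str(tmp_path / "out"))
        result = run_pipeline(config, assembly_a=small_sim.assembly_a)
        occ = result.occurrences[0]
        for line in (tmp_path / "out" / "occurrences.gff3").read_text().splitlines():
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == occ.scaffold_id and int(fields[3]) == occ.start + 1:
                assert int(fields[4]) == occ.end
                break
        else:
            pytest.fail("occurrence not found in GFF3 output")

    def test_flank_probe_fallback_when_no_candidates(self, small_sim):
        # an impossible length filter suppresses the inter-satellite
        # scan; flank probing still yields clusterable segments
        config = RunConfig(out_dir="")
        config = dataclasses.replace(
            config,
            discovery=dataclasses.replace(config.discovery,
                                          min_len=9000, max_len=9001),
            flank_probe_window=450)
        result = run_pipeline(config, assembly_a=small_sim.assembly_a,
                              write_outputs=False, flank_probe=True)
        assert result.candidates
        assert all(c.flank_probe for c in result.candidates)
        assert result.families  # the planted families are still found


class TestCLI:
    def test_simulate_then_run(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        result = runner.invoke(main, [
            "simulate", "--out-dir", str(sim_dir), "--seed", "5",
            "--n-scaffolds", "2", "--scaffold-length", "120000",
            "--n-copies", "8", "--n-arrays", "2"])
        assert result.exit_code == 0, result.output
        assert (sim_dir / "assembly_A.fasta").exists()
        out_dir = tmp_path / "out"
        result = runner.invoke(main, [
            "run", str(sim_dir / "assembly_A.fasta"),
            "--out-dir", str(out_dir)])
        assert result.exit_code == 0, result.output
        assert "families" in result.output
        assert (out_dir / "occurrences.gff3").exists()

    def test_ssr_subcommand(self, tmp_path):
        fasta = tmp_path / "toy.fasta"
        write_fasta(fasta, {"s1": "GCGTTGACCA" * 3 + "TA" * 10 + "GCGTTGACCA" * 3})
        runner = CliRunner()
        result = runner.invoke(main, ["ssr", str(fasta), "--out-dir",
                                      str(tmp_path / "out")])
        assert result.exit_code == 0, result.output
        gff = (tmp_path / "out" / "ssrs.gff3").read_text()
        assert "satellite_DNA" in gff and "motif=AT" in gff

    def test_init_config_round_trip(self, tmp_path):
        runner = CliRunner()
        path = tmp_path / "cfg.txt"
        result = runner.invoke(main, ["init-config", str(path)])
        assert result.exit_code == 0, result.output
        assert read_config(path) == RunConfig()
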