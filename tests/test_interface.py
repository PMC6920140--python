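"""File I/O round trips, configuration, pipeline, and CLI behavior."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from peptidogenomics.cli import main as cli_main
from peptidogenomics.config import PipelineConfig
from peptidogenomics.io import (
    InputFormatError,
    read_candidates,
    read_mgf,
    read_nucleotide_fasta,
    read_peaks_csv,
    write_mgf,
    write_peaks_csv,
)
from peptidogenomics.pipeline import (
    IdentificationError,
    report_markdown,
    run_identify,
)
from peptidogenomics.spectral import Spectrum
from peptidogenomics.synthetic import (
    SimulationConfig,
    simulate_fragment_spectrum,
    simulate_genome_with_gene,
    simulate_precursor_spectrum,
)
from peptidogenomics.validation import CandidateSequence

from conftest import HEPCIDIN, RECOMBINANT


class TestIO:
    def test_mgf_round_trip(self, tmp_path):
        spec = Spectrum(
            peaks=((556.42, 100.0), (556.62, 150.0)),
            source="test",
            retention_time=3.1,
        )
        path = tmp_path / "spec.mgf"
        write_mgf(path, [spec])
        (back,) = read_mgf(path)
        assert np.allclose(back.mz, spec.mz)
        assert np.allclose(back.intensity, spec.intensity)
        assert back.retention_time == pytest.approx(3.1)

    def test_peaks_csv_round_trip(self, tmp_path):
        spec = Spectrum(peaks=((100.0, 1.0), (200.0, 2.0)))
        path = tmp_path / "peaks.csv"
        write_peaks_csv(path, spec)
        back = read_peaks_csv(path)
        assert back.peaks == spec.peaks

    def test_peaks_csv_bad_line_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("mz,intensity\n100.0,1.0\nnot,numbers\n")
        with pytest.raises(InputFormatError, match="line 3"):
            read_peaks_csv(path)

    def test_candidates_csv(self, tmp_path):
        path = tmp_path / "candidates.csv"
        path.write_text(
            "id,sequence,provenance\n"
            f"this-study,{HEPCIDIN},peptide\n"
            f"recombinant,{RECOMBINANT},recombinant\n"
        )
        cands = read_candidates(path)
        assert [c.id for c in cands] == ["this-study", "recombinant"]
        assert cands[1].provenance == "recombinant"

    def test_candidates_fasta(self, tmp_path):
        path = tmp_path / "candidates.fasta"
        path.write_text(f">this-study\n{HEPCIDIN}\n")
        (cand,) = read_candidates(path)
        assert cand.sequence == HEPCIDIN

    def test_candidates_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(InputFormatError):
            read_candidates(path)

    def test_nucleotide_fasta(self, tmp_path):
        path = tmp_path / "genome.fasta"
        path.write_text(">chr1\nACGTACGT\nACGT\n")
        (nuc,) = read_nucleotide_fasta(path)
        assert nuc.sequence == "ACGTACGTACGT"


class TestPipelineConfig:
    def test_defaults(self):
        cfg = PipelineConfig()
        assert cfg.precursor_tol_ppm == 20.0
        assert cfg.cys_hydrogen is None

    def test_legacy_mode(self):
        cfg = PipelineConfig(constants_mode="legacy-1.00794")
        assert cfg.cys_hydrogen == pytest.approx(1.00794)

    def test_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig(precursor_tol_ppm=5.0, seed=7)
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        assert PipelineConfig.from_yaml(path) == cfg

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("precursor_tol_ppm: 5\ntypo_key: 1\n")
        with pytest.raises(ValueError, match="typo_key"):
            PipelineConfig.from_yaml(path)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(constants_mode="imaginary")


@pytest.fixture
def synthetic_inputs(table1_candidates):
    cfg = SimulationConfig(seed=5)
    precursor, _ = simulate_precursor_spectrum(cfg)
    msms, _ = simulate_fragment_spectrum(cfg.with_seed(6))
    genome, _ = simulate_genome_with_gene(
        SimulationConfig(seed=7, genome_length=30_000)
    )
    return precursor, msms, genome, table1_candidates


class TestRunIdentify:
    def test_full_synthetic_identification(self, synthetic_inputs):
        precursor, msms, genome, candidates = synthetic_inputs
        report = run_identify(precursor, msms, candidates, [genome])
        assert report["any_candidate_passes"]
        assert report["top_candidate"] == "this-study"
        assert report["inferred_neutral_mass"] == pytest.approx(
            2777.06, abs=0.05
        )
        assert report["genomic_hits"]
        assert report["conservation"]["variant_columns"] == [21, 24]
        md = report_markdown(report)
        assert "this-study" in md

    def test_only_wrong_candidate_fails_filter(self, synthetic_inputs):
        precursor, msms, _, _ = synthetic_inputs
        report = run_identify(
            precursor,
            msms,
            [CandidateSequence("recombinant", RECOMBINANT, "recombinant")],
        )
        assert not report["any_candidate_passes"]
        assert report["top_candidate"] is None
        assert "No candidate" in report_markdown(report)

    def test_empty_msms_falls_back_to_precursor(self, synthetic_inputs):
        precursor, _, _, candidates = synthetic_inputs
        report = run_identify(precursor, None, candidates)
        assert report["ranking_basis"] == "precursor-only"
        assert report["top_candidate"] == "this-study"

    def test_unusable_precursor_raises(self, table1_candidates):
        flat = Spectrum(peaks=((100.0, 1.0), (500.0, 1.0)))
        with pytest.raises(IdentificationError):
            run_identify(flat, None, table1_candidates)


class TestCli:
    def test_mass_command(self):
        runner = CliRunner()
        result = runner.invoke(
            cli_main, ["mass", HEPCIDIN, "--disulfides", "4"]
        )
        assert result.exit_code == 0
        assert "C117H172N32O31S8" in result.output
        assert "2777.06" in result.output

    def test_mass_command_bad_sequence_exit_2(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["mass", "XYZ123"])
        assert result.exit_code == 2

    def test_simulate_and_identify_round_trip(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        result = runner.invoke(
            cli_main,
            ["simulate", "--seed", "3", "--out-dir", str(sim_dir)],
        )
        assert result.exit_code == 0, result.output
        candidates = tmp_path / "candidates.csv"
        candidates.write_text(
            "id,sequence,provenance\n"
            f"this-study,{HEPCIDIN},peptide\n"
            f"recombinant,{RECOMBINANT},recombinant\n"
        )
        out_dir = tmp_path / "report"
        result = runner.invoke(
            cli_main,
            [
                "identify",
                "--precursor", str(sim_dir / "precursor.mgf"),
                "--msms", str(sim_dir / "msms.mgf"),
                "--candidates", str(candidates),
                "--nucleotides", str(sim_dir / "genome.fasta"),
                "--out-dir", str(out_dir),
            ],
        )
        assert result.exit_code == 0, result.output
        report = json.loads((out_dir / "report.json").read_text())
        assert report["top_candidate"] == "this-study"
        truth = json.loads((sim_dir / "truth.json").read_text())
        truth_exons = [list(e) for e in truth["genome"]["exons"]]
        assert any(h["exons"] == truth_exons for h in report["genomic_hits"])

    def test_identify_no_pass_exit_3(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        runner.invoke(
            cli_main, ["simulate", "--seed", "4", "--out-dir", str(sim_dir)]
        )
        candidates = tmp_path / "candidates.csv"
        candidates.write_text(
            f"id,sequence,provenance\nrecombinant,{RECOMBINANT},recombinant\n"
        )
        result = runner.invoke(
            cli_main,
            [
                "identify",
                "--precursor", str(sim_dir / "precursor.mgf"),
                "--candidates", str(candidates),
                "--out-dir", str(tmp_path / "report"),
            ],
        )
        assert result.exit_code == 3
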