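"""Configuration, structured output, and the command-line interface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from polyocc import (
    BindingEnergies,
    CurveRequest,
    ElementLayout,
    Mode,
    OffDnaParams,
    occupancy_curve,
    occupancy_window,
)
from polyocc.cli import main
from polyocc.config import ConfigError, DEFAULTS, load_config
from polyocc.output import curve_to_frame, write_results
from polyocc.presets import PRESETS, get_preset


class TestConfig:
    def test_empty_file_yields_documented_defaults(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        cfg = load_config(path)
        e = cfg.energies()
        assert (e.alpha, e.beta) == (-9.955, -5.837)
        assert cfg.layout().n_sites == 24
        off = cfg.offdna()
        assert off.n_max == 50 and off.m_species == 1
        assert cfg.thermo().rt == 0.593

    def test_no_file_equals_empty_file(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        assert load_config(None).resolved() == load_config(path).resolved()

    def test_unknown_key_rejected_by_name(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("offdna:\n  nmax: 10\n")
        with pytest.raises(ConfigError, match="offdna.nmax"):
            load_config(path)

    def test_bound_violation_reported_at_load(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("offdna:\n  n_max: 0\n")
        with pytest.raises(ConfigError, match="n_max"):
            load_config(path)

    def test_default_valued_override_is_idempotent(self, tmp_path):
        path = tmp_path / "same.yaml"
        path.write_text("thermo:\n  rt_kcal_per_mol: 0.593\n")
        assert load_config(path).resolved() == load_config(None).resolved()

    def test_json_config_accepted(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text(json.dumps({"energies": {"gamma_sam": -7.0}}))
        assert load_config(path).energies().gamma_sam == -7.0

    def test_provenance_carries_version_and_full_config(self):
        prov = load_config(None).provenance()
        assert prov["tool"] == "polyocc"
        assert set(prov["config"]) == set(DEFAULTS)


def small_curve():
    e = BindingEnergies(gamma_sam=-7.0)
    off = OffDnaParams.from_energies(e)
    lay = ElementLayout.default()
    grid = np.logspace(-10, -4, 13)
    return occupancy_curve(CurveRequest(lay, e, off, grid, Mode.ON_OFF))


class TestOutput:
    def test_tsv_round_trip_is_bit_exact(self, tmp_path):
        import pandas as pd

        curve = small_curve()
        path = write_results(curve, tmp_path / "curve.tsv", fmt="tsv")
        back = pd.read_csv(path, sep="\t")
        # 12-significant-digit scientific notation round-trips doubles to ~1e-12
        assert back["theta_on_off"].to_numpy() == pytest.approx(
            curve.theta, rel=1e-11, abs=1e-280
        )
        assert len(back) == curve.c_total.size

    def test_identical_inputs_give_byte_identical_files(self, tmp_path):
        a = write_results(small_curve(), tmp_path / "a.tsv")
        b = write_results(small_curve(), tmp_path / "b.tsv")
        assert a.read_bytes() == b.read_bytes()

    def test_json_embeds_provenance(self, tmp_path):
        path = write_results(
            small_curve(), tmp_path / "c.json", fmt="json",
            provenance={"tool": "polyocc"},
        )
        payload = json.loads(path.read_text())
        assert payload["provenance"]["tool"] == "polyocc"
        assert len(payload["c_total_molar"]) == 13

    def test_tsv_provenance_sidecar(self, tmp_path):
        write_results(small_curve(), tmp_path / "c.tsv", provenance={"k": 1})
        assert json.loads((tmp_path / "c.tsv.params.json").read_text()) == {"k": 1}

    def test_empty_window_row(self, tmp_path):
        w = occupancy_window(
            BindingEnergies(alpha=10, beta=10, gamma_sam=0.0), mode=Mode.ON_ONLY
        )
        path = write_results(w, tmp_path / "w.tsv")
        text = path.read_text().splitlines()
        assert len(text) == 2  # header + one row
        assert "\t0" in text[1]  # n_intervals = 0

    def test_paired_curve_columns(self):
        e = BindingEnergies(gamma_sam=-7.0)
        off = OffDnaParams.from_energies(e)
        lay = ElementLayout.default()
        grid = np.logspace(-10, -4, 7)
        on = occupancy_curve(CurveRequest(lay, e, off, grid, Mode.ON_ONLY))
        both = occupancy_curve(CurveRequest(lay, e, off, grid, Mode.ON_OFF))
        frame = curve_to_frame(on, both)
        assert list(frame.columns) == [
            "c_total_molar", "theta_on_only", "theta_on_off", "c_eff_molar"
        ]


class TestCli:
    def test_curve_to_stdout(self):
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["curve", "--gamma", "-7.0", "--cmin", "1e-9", "--cmax", "1e-6",
             "--points-per-decade", "5"],
        )
        assert result.exit_code == 0, result.output
        lines = result.output.strip().splitlines()
        assert lines[0].split("\t") == [
            "c_total_molar", "theta_on_only", "theta_on_off", "c_eff_molar"
        ]
        assert len(lines) == 17  # header + 3 decades * 5 + 1 points

    def test_window_scan_writes_tsv_with_manifest(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "win.tsv"
        result = runner.invoke(
            main,
            ["window", "--gamma-min", "-8", "--gamma-max", "-6",
             "--gamma-step", "1", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        lines = out.read_text().splitlines()
        assert len(lines) == 4  # header + gammas -6, -7, -8
        sidecar = json.loads((tmp_path / "win.tsv.params.json").read_text())
        assert sidecar["command"]["subcommand"] == "window"

    def test_species_distribution_tsv(self):
        runner = CliRunner()
        result = runner.invoke(
            main, ["species", "--kd", "7e-6", "--n", "50", "--conc", "7e-6"]
        )
        assert result.exit_code == 0, result.output
        lines = result.output.strip().splitlines()
        assert lines[0] == "term_index\tspecies_size\tmass_fraction"
        assert len(lines) == 52
        first = lines[1].split("\t")
        assert float(first[2]) == pytest.approx(1 / 51, rel=1e-9)

    def test_figure1_preset_emits_manifest(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main, ["figure1", "--scenario", "figure1A", "--out", str(tmp_path)]
        )
        assert result.exit_code == 0, result.output
        manifest = json.loads((tmp_path / "figure1A_manifest.json").read_text())
        assert manifest["preset"]["name"] == "figure1A"
        assert "reconstructed" in manifest["preset"]["note"]
        assert (tmp_path / "figure1A_curve.tsv").exists()

    def test_presets_listing_flags_reconstructions(self):
        runner = CliRunner()
        result = runner.invoke(main, ["presets"])
        assert result.exit_code == 0
        for name in PRESETS:
            assert name in result.output
        assert "reconstructed" in result.output

    def test_config_file_flows_into_commands(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("element:\n  n_sites: 4\n  ets_positions: [1]\n")
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["--config", str(cfg), "curve", "--gamma", "0.0",
             "--mode", "on_only", "--cmin", "1e-9", "--cmax", "1e-8",
             "--points-per-decade", "2"],
        )
        assert result.exit_code == 0, result.output

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            get_preset("figure99")
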