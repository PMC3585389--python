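"""Configuration parsing, response ingestion and design-file round trips."""

import math

import numpy as np
import pandas as pd
import pytest

from simsens import (
    ConfigurationError,
    ParameterSpec,
    build_oat_design,
    efast_sample,
    lhs_sample,
    load_config,
    read_responses,
    write_design,
)


class TestParameterSpec:
    def test_case_study_config_loads_six_parameters(self, config_yaml):
        config = load_config(config_yaml)
        assert len(config.parameters) == 6
        by_name = {p.name: p for p in config.parameters}
        assert by_name["chemoThreshold"].lower == 0.0
        assert by_name["chemoThreshold"].upper == 1.0
        assert by_name["chemoLowerLinearAdjust"].lower == 0.015
        assert by_name["chemoLowerLinearAdjust"].upper == 0.08
        assert by_name["maxVCAMeffectProbabilityCutoff"].upper == 1.0
        assert config.responses == ("Velocity", "Displacement")

    def test_degenerate_range_rejected(self):
        with pytest.raises(ConfigurationError, match="lower bound"):
            ParameterSpec("p", 1.0, 1.0, 1.0)

    def test_calibrated_outside_bounds_rejected(self):
        with pytest.raises(ConfigurationError, match="calibrated"):
            ParameterSpec("p", 0.0, 1.0, 1.5)

    def test_bad_increment_rejected(self):
        with pytest.raises(ConfigurationError, match="increment"):
            ParameterSpec("p", 0.0, 1.0, 0.5, increment=2.0)
        with pytest.raises(ConfigurationError, match="increment"):
            ParameterSpec("p", 0.0, 1.0, 0.5, increment=0.0)


class TestLoadConfig:
    def test_duplicate_parameter_names_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "parameters:\n"
            "  - {name: a, lower: 0, upper: 1, calibrated: 0.5}\n"
            "  - {name: a, lower: 0, upper: 2, calibrated: 1.0}\n"
            "responses: [y]\n"
        )
        with pytest.raises(ConfigurationError, match="duplicate"):
            load_config(path)

    def test_missing_field_named_in_error(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("parameters:\n  - {name: a, lower: 0, upper: 1}\nresponses: [y]\n")
        with pytest.raises(ConfigurationError, match="calibrated"):
            load_config(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(ConfigurationError, match="not found"):
            load_config(tmp_path / "absent.yaml")


class TestReadResponses:
    def test_direct_parse(self, tmp_path):
        frame = pd.DataFrame(
            {"Velocity": np.arange(500.0), "Displacement": np.arange(500.0) * 2}
        )
        path = tmp_path / "runs.csv"
        frame.to_csv(path, index=False)
        table = read_responses(path, ["Velocity", "Displacement"])
        assert table.n_runs == 500
        assert table.responses == ["Velocity", "Displacement"]

    def test_malformed_row_excluded_with_warning(self, tmp_path, caplog):
        lines = ["Velocity,Displacement"]
        lines += [f"{i}.0,{2 * i}.0" for i in range(9)]
        lines.insert(5, "oops,")  # one malformed row among ten
        path = tmp_path / "runs.csv"
        path.write_text("\n".join(lines) + "\n")
        with caplog.at_level("WARNING", logger="simsens"):
            table = read_responses(path, ["Velocity", "Displacement"])
        assert table.n_runs == 9
        assert "excluded 1 of 10" in caplog.text

    def test_missing_column_is_hard_error_listing_available(self, tmp_path):
        path = tmp_path / "runs.csv"
        pd.DataFrame({"Velocity": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="Displacement") as excinfo:
            read_responses(path, ["Velocity", "Displacement"])
        assert "Velocity" in str(excinfo.value)  # available columns listed


class TestWriteDesign:
    def test_efast_file_count_and_round_trip(self, tmp_path):
        # Seven parameters plus a dummy, three curves, 65 samples:
        # 24 files of 65 rows each.
        params = [ParameterSpec(f"p{i}", 0.0, 1.0, 0.5) for i in range(7)]
        params.append(ParameterSpec("dummy", 0.0, 1.0, 0.5))
        design = efast_sample(params, 65, 3, 4, seed=3, dummy_name="dummy")
        paths = write_design(design, tmp_path / "design")
        assert len(paths) == 24  # (7 + dummy) x 3 curves
        assert len(paths) == len(design.parameters) * design.nr
        for (poi, curve), frame in design.samples.items():
            back = pd.read_csv(tmp_path / "design" / f"curve{curve}_param{poi}.csv")
            assert len(back) == 65
            pd.testing.assert_frame_equal(back, frame)  # full-precision round trip

    def test_lhs_single_file_round_trip(self, tmp_path):
        params = [ParameterSpec(f"p{i}", 0.0, 1.0, 0.5) for i in range(6)]
        design = lhs_sample(params, 500, seed=1)
        paths = write_design(design, tmp_path)
        assert [p.name for p in paths] == ["lhs_design.csv"]
        back = pd.read_csv(paths[0])
        assert back.shape == (500, 6)
        pd.testing.assert_frame_equal(back, design.samples)

    def test_oat_single_file(self, tmp_path, case_study):
        design = build_oat_design(case_study)
        paths = write_design(design, tmp_path)
        assert [p.name for p in paths] == ["robustness_design.csv"]
        back = pd.read_csv(paths[0])
        assert len(back) == design.n_conditions

    def test_empty_design_rejected(self, tmp_path):
        class Empty:
            def design_files(self):
                return {}

        with pytest.raises(ValueError, match="empty"):
            write_design(Empty(), tmp_path)
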