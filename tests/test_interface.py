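import json
import os

import numpy as np
import pytest
from click.testing import CliRunner

from dmvg import (
    RunConfig,
    TimeSeriesPanel,
    build_dmvg,
    run_pipeline,
)
from dmvg.cli import main as cli_main
from dmvg.io import PanelInputError, export_edge_list, read_panel, read_panels, write_panel


@pytest.fixture
def panel_dir(tmp_path, rng):
    for pid in ("p000", "p001"):
        d = tmp_path / pid
        d.mkdir()
        for trial in ("t000", "t001"):
            panel = TimeSeriesPanel(rng.standard_normal((3, 40)),
                                    variable_names=["a", "b", "c"])
            write_panel(panel, str(d / f"{trial}.csv"))
    return tmp_path


class TestPanelIO:
    def test_round_trip_full_precision(self, tmp_path, rng):
        panel = TimeSeriesPanel(rng.standard_normal((4, 30)),
                                variable_names=list("wxyz"))
        path = str(tmp_path / "p.csv")
        write_panel(panel, path)
        back = read_panel(path)
        assert np.array_equal(back.values, panel.values)
        assert back.variable_names == panel.variable_names

    def test_tab_delimited_accepted(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("a\tb\n1\t2\n3\t4\n5\t6\n")
        panel = read_panel(str(path))
        assert panel.values.tolist() == [[1, 3, 5], [2, 4, 6]]

    def test_directory_convention_labels(self, panel_dir):
        panels = read_panels(str(panel_dir / "**" / "*.csv"))
        assert len(panels) == 4
        assert {p.participant_id for p in panels} == {"p000", "p001"}
        assert panels[0].sample_id == "p000/t000"

    def test_missing_value_names_file_and_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n3,\n5,6\n")
        with pytest.raises(PanelInputError, match=r"bad\.csv.*row 3"):
            read_panel(str(path))

    def test_too_short_rejected(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("a\n1\n2\n")
        with pytest.raises(PanelInputError, match="3 time points"):
            read_panel(str(path))

    def test_inconsistent_columns_rejected(self, panel_dir):
        (panel_dir / "p000" / "t999.csv").write_text("q,r,s\n1,2,3\n4,5,6\n7,8,9\n")
        with pytest.raises(PanelInputError, match="differ"):
            read_panels(str(panel_dir / "**" / "*.csv"))

    def test_no_match_rejected(self, tmp_path):
        with pytest.raises(PanelInputError, match="no files match"):
            read_panels(str(tmp_path / "*.csv"))

    def test_edge_list_is_one_based(self, tmp_path):
        g = build_dmvg(TimeSeriesPanel(np.array([[3.0, 1, 3]])))
        path = str(tmp_path / "layer.edges")
        export_edge_list(g, 0, path)
        rows = [tuple(map(int, line.split())) for line in open(path)]
        assert set(rows) == {(1, 2), (2, 3), (1, 3)}


class TestRunConfig:
    def test_exactly_one_input_source(self):
        with pytest.raises(ValueError):
            RunConfig()
        with pytest.raises(ValueError):
            RunConfig(input_glob="x/*.csv", synthetic={"n_variables": 2})

    def test_from_yaml_with_overrides(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("synthetic:\n  n_variables: 2\n  n_participants: 1\n"
                        "  n_trials: 2\n  trial_length: 50\nlevels: [1]\n")
        cfg = RunConfig.from_yaml(str(path), levels=[1, 2], seed=5)
        assert list(cfg.levels) == [1, 2]
        assert cfg.seed == 5

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("synthetic: {n_variables: 2}\nbananas: 3\n")
        with pytest.raises(ValueError, match="bananas"):
            RunConfig.from_yaml(str(path))


class TestPipeline:
    def test_six_variable_levels_1_to_5_yield_62_tuples(self):
        cfg = RunConfig(
            synthetic=dict(n_variables=6, n_participants=2, n_trials=2,
                           trial_length=120, process="iid_gaussian"),
            levels=[1, 2, 3, 4, 5], seed=1,
        )
        bundle = run_pipeline(cfg)
        counts = [len(bundle["reports"][k].entries) for k in (1, 2, 3, 4, 5)]
        assert counts == [6, 15, 20, 15, 6]
        assert sum(counts) == 62

    def test_two_variable_pair_level(self):
        cfg = RunConfig(
            synthetic=dict(n_variables=2, n_participants=1, n_trials=3,
                           trial_length=100, process="iid_gaussian"),
            levels=[2], seed=1,
        )
        bundle = run_pipeline(cfg)
        assert len(bundle["reports"][2].entries) == 1

    def test_rerun_is_byte_identical(self, tmp_path):
        def run(sub):
            out = tmp_path / sub
            cfg = RunConfig(
                synthetic=dict(n_variables=3, n_participants=2, n_trials=2,
                               trial_length=100, process="iid_gaussian"),
                levels=[1, 2], seed=3, output_dir=str(out),
                n_surrogates=19, subsample_fraction=0.5, subsample_repeats=4,
            )
            run_pipeline(cfg)
            return {f: (out / f).read_bytes() for f in sorted(os.listdir(out))}

        assert run("a") == run("b")

    def test_per_participant_reports(self, panel_dir):
        cfg = RunConfig(input_glob=str(panel_dir / "**" / "*.csv"),
                        levels=[1], per_participant=True)
        bundle = run_pipeline(cfg)
        assert set(bundle["per_participant"]) == {"p000", "p001"}

    def test_outputs_finite(self):
        cfg = RunConfig(
            synthetic=dict(n_variables=3, n_participants=2, n_trials=2,
                           trial_length=150), levels=[1, 2], seed=2,
        )
        bundle = run_pipeline(cfg)
        for rep in bundle["reports"].values():
            assert np.isfinite([s for _, s in rep.entries]).all()
            assert np.isfinite([rep.level_mean, rep.level_sd]).all()


class TestCli:
    def test_synth_build_irreversibility_round_trip(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        r = runner.invoke(cli_main, [
            "synth", "--process", "iid_gaussian", "--n-variables", "2",
            "--participants", "2", "--trials", "2", "--length", "60",
            "--seed", "4", "--out", str(data),
        ])
        assert r.exit_code == 0, r.output
        assert len(list(data.glob("*/*.csv"))) == 4

        edges = tmp_path / "edges"
        r = runner.invoke(cli_main, ["build", str(data / "**" / "*.csv"),
                                     "--out", str(edges)])
        assert r.exit_code == 0, r.output
        assert len(list(edges.glob("*.edges"))) == 8  # 4 panels x 2 layers

        out = tmp_path / "reports"
        r = runner.invoke(cli_main, [
            "irreversibility", "--input", str(data / "**" / "*.csv"),
            "--levels", "1,2", "--out", str(out),
        ])
        assert r.exit_code == 0, r.output
        assert (out / "cohort_level1.csv").exists()
        meta = json.loads((out / "cohort_level1.csv.json").read_text())
        assert meta["n_samples"] == 4

    def test_error_exits_nonzero(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["irreversibility", "--input",
                                     str(tmp_path / "none*.csv")])
        assert r.exit_code != 0
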