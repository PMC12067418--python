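import json

import matplotlib
import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from ieegflow import AnalysisConfig, PreictalFlow
from ieegflow.cli import main as cli_main
from ieegflow.pipeline import CohortSpec, PipelineConfig, run, simulate, \
    summarize
from ieegflow.recording import ValidationError
from ieegflow.synthetic import SyntheticSpec, generate_recording

matplotlib.use("Agg")


@pytest.fixture(scope="module")
def fitted():
    spec = SyntheticSpec(n_channels=8, n_soz=2, regime="outflow_dominant",
                         seed=21)
    rec, truth = generate_recording(spec)
    model = PreictalFlow(rec, AnalysisConfig(master_seed=2))
    return model.fit(), truth


class TestModelResults:
    def test_recovers_planted_regime(self, fitted):
        res, truth = fitted
        assert res.group_label == truth.regime

    def test_auc_table_complete(self, fitted):
        res, _ = fitted
        assert len(res.auc_table) == 4  # 2 methods x 2 measures, preictal
        assert res.auc_table["auc"].between(0, 1).all()
        assert res.auc("pdc", "outflow") > res.auc("pdc", "inflow")

    def test_flow_series_shapes(self, fitted):
        res, _ = fitted
        f = res.flow_series[("pdc", "inflow", "preictal")]
        assert f.values.shape == (7, 8)
        assert f.soz_mask.sum() == 2

    def test_orders_consistent_across_segments(self, fitted):
        # one generator per recording: selected order should barely move
        res, _ = fitted
        orders = res.orders["preictal"]
        assert len(orders) == 7
        assert max(orders) - min(orders) <= 4

    def test_summary_mentions_key_results(self, fitted):
        res, _ = fitted
        text = res.summary()
        assert "outflow_dominant" in text
        assert "AUC" in text
        assert "p_adjusted" in text

    def test_plot_smoke(self, fitted):
        res, _ = fitted
        ax = res.plot_flow_dynamics()
        assert len(ax.lines) == 4

    def test_invalid_recording_rejected_before_compute(self):
        rec, _ = generate_recording(
            SyntheticSpec(n_channels=6, n_soz=2, regime="null", seed=1,
                          pad_s=0.0))  # only 28 s preictal: below 30 s rule
        with pytest.raises(ValidationError, match="rejected"):
            PreictalFlow(rec).fit()

    def test_bad_window_config_rejected_before_compute(self):
        with pytest.raises(ValueError, match="multiple"):
            AnalysisConfig(window_s=5.0, epoch_s=28.0)


def tiny_config(seed=11, threshold=True):
    return PipelineConfig(
        analysis=AnalysisConfig(master_seed=seed,
                                n_surrogates=20 if threshold else 0,
                                threshold=threshold),
        synthetic=CohortSpec(n_patients=2,
                             regime_mix={"outflow_dominant": 1.0},
                             channels_range=(6, 8),
                             seizures_range=(2, 2), base_seed=seed))


class TestPipeline:
    def test_run_writes_all_artifacts(self, tmp_path):
        out = run(tiny_config(), tmp_path)
        for name in ("auc_table.csv", "group_labels.json",
                     "classification_tests.csv", "cohort_summary.csv",
                     "recording_meta.csv", "manifest.json"):
            assert (tmp_path / name).exists()
        labels = json.loads((tmp_path / "group_labels.json").read_text())
        assert len(labels) == 4
        flow_csvs = list(tmp_path.glob("*_pdc_inflow_preictal.csv"))
        assert len(flow_csvs) == 4
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["config"]["analysis"]["master_seed"] == 11
        assert out["auc_table"]["auc"].between(0, 1).all()

    def test_rerun_reproduces_numeric_outputs(self, tmp_path):
        a = run(tiny_config(), tmp_path / "a")
        b = run(tiny_config(), tmp_path / "b")
        pd.testing.assert_frame_equal(a["auc_table"], b["auc_table"])
        assert a["labels"] == b["labels"]

    def test_simulate_writes_fixtures_and_truth(self, tmp_path):
        paths = simulate(tiny_config(), tmp_path)
        assert len(paths) == 4
        truth = json.loads((tmp_path / "ground_truth.json").read_text())
        assert all(v["regime"] == "outflow_dominant" for v in truth.values())

    def test_run_on_fixture_paths(self, tmp_path):
        paths = simulate(tiny_config(), tmp_path / "fx")
        config = PipelineConfig(
            analysis=AnalysisConfig(master_seed=1, n_surrogates=0,
                                    threshold=False),
            recordings=[str(p) for p in paths[:2]])
        out = run(config, tmp_path / "res")
        assert len(out["labels"]) == 2

    def test_summarize_stratified(self, tmp_path):
        run(tiny_config(), tmp_path)
        table = summarize(tmp_path, stratify_by="implant")
        assert "stratum" in table.columns

    def test_config_requires_input(self):
        with pytest.raises(ValidationError, match="synthetic"):
            PipelineConfig(analysis=AnalysisConfig())


class TestCli:
    def test_simulate_run_summarize_round_trip(self, tmp_path):
        cfg = {
            "analysis": {"master_seed": 4, "n_surrogates": 0,
                         "threshold": False},
            "synthetic": {"n_patients": 2,
                          "regime_mix": {"inflow_dominant": 1.0},
                          "channels_range": [6, 6],
                          "seizures_range": [2, 2], "base_seed": 4},
        }
        cfg_path = tmp_path / "cohort.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        runner = CliRunner()
        sim = runner.invoke(cli_main, ["simulate", "--config", str(cfg_path),
                                       "--out", str(tmp_path / "fx")])
        assert sim.exit_code == 0, sim.output
        res = runner.invoke(cli_main, ["run", "--config", str(cfg_path),
                                       "--out", str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        assert "labels" in res.output
        summ = runner.invoke(cli_main, ["summarize", "--in",
                                        str(tmp_path / "out"),
                                        "--stratify-by", "implant"])
        assert summ.exit_code == 0, summ.output
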