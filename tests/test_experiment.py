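"""Experiment orchestration, strategy comparison and the CLI surface."""

import json

import numpy as np
import pandas as pd
import pytest

from octsplit import (ExperimentConfig, ModelConfig, SyntheticConfig, TrainConfig,
                      compare_strategies, run_experiment)
from octsplit.cli import main as cli_main


@pytest.fixture(scope="module")
def tiny_experiment_report(tmp_path_factory):
    """Both CV strategies on a small dataset: 2 repeats x 2 folds = 4 models each."""
    out = tmp_path_factory.mktemp("exp")
    syn = SyntheticConfig(subjects_per_class=6, slices_per_volume=6,
                          image_height=24, image_width=24, seed=2)
    config = ExperimentConfig(
        synthetic=syn, n_test_per_class=12, repeats=2, folds=2,
        model=ModelConfig(input_height=24, input_width=24, n_classes=2),
        train=TrainConfig(epochs=2, seed=2), seed=2, output_dir=str(out),
    )
    return run_experiment(config), out


class TestRunExperiment:
    def test_per_model_row_counts(self, tiny_experiment_report):
        report, _ = tiny_experiment_report
        frame = report.per_model_frame()
        assert not report.errors
        counts = frame.groupby("strategy").size()
        assert counts["per-image"] == 4
        assert counts["per-volume-subject"] == 4

    def test_subject_split_audits_are_clean_and_image_split_leaks(
            self, tiny_experiment_report):
        report, _ = tiny_experiment_report
        for audit in report.strategies["per-volume-subject"].audits:
            assert audit.overlap_fraction == 0.0
        assert any(a.overlap_fraction > 0
                   for a in report.strategies["per-image"].audits)

    def test_artifacts_are_written(self, tiny_experiment_report):
        report, out = tiny_experiment_report
        assert (out / "per_model_metrics.csv").exists()
        assert (out / "summary.csv").exists()
        payload = json.loads((out / "report.json").read_text())
        assert set(payload["strategies"]) == {"per-image", "per-volume-subject"}
        assert "inflation" in payload

    def test_exported_csv_reaggregates_to_the_report(self, tiny_experiment_report):
        report, out = tiny_experiment_report
        frame = pd.read_csv(out / "per_model_metrics.csv")
        for name, res in report.strategies.items():
            grp = frame[frame["strategy"] == name]["mcc"]
            assert grp.mean() == pytest.approx(res.aggregated.loc["mcc", "mean"])
            assert grp.std(ddof=1) == pytest.approx(res.aggregated.loc["mcc", "std"])


class TestCompareStrategies:
    def test_delta_between_printed_means(self, tiny_experiment_report):
        report, _ = tiny_experiment_report
        cmp = compare_strategies(report)
        a = report.strategies["per-image"].aggregated.loc["mcc", "mean"]
        b = report.strategies["per-volume-subject"].aggregated.loc["mcc", "mean"]
        assert cmp.loc["mcc", "delta"] == pytest.approx(a - b)
        # reference arithmetic: means 0.853 and 0.426 must give delta 0.427
        assert 0.853 - 0.426 == pytest.approx(0.427)

    def test_duplicated_strategy_gives_zero_delta(self, tiny_experiment_report):
        report, _ = tiny_experiment_report
        twin = type(report)(config=report.config)
        res = report.strategies["per-image"]
        twin.strategies = {"a": res, "b": res}
        cmp = compare_strategies(twin, "a", "b")
        assert (cmp["delta"].abs() < 1e-12).all()

    def test_single_strategy_report_is_refused(self, tiny_experiment_report):
        report, _ = tiny_experiment_report
        single = type(report)(config=report.config)
        single.strategies = {"per-image": report.strategies["per-image"]}
        with pytest.raises(ValueError):
            compare_strategies(single)


class TestOriginalStrategy:
    def test_single_model_on_the_given_presplit(self, tmp_path):
        from octsplit import generate_dataset, write_dataset_tree

        table = generate_dataset(SyntheticConfig(
            subjects_per_class=4, slices_per_volume=4,
            image_height=24, image_width=24, seed=6))
        # hold out one whole subject per class as the given test split
        test_subjects = set(table.meta.groupby("class_label")["subject_id"]
                            .first())
        splits = ["test" if s in test_subjects else "train"
                  for s in table.meta["subject_id"]]
        write_dataset_tree(table, tmp_path, "kermany-like", splits=splits)
        config = ExperimentConfig(
            dataset_root=str(tmp_path), dataset_layout="kermany",
            strategies=("original",),
            model=ModelConfig(input_height=24, input_width=24, n_classes=2),
            train=TrainConfig(epochs=1, seed=6), seed=6,
        )
        report = run_experiment(config)
        assert not report.errors
        res = report.strategies["original"]
        assert len(res.per_model) == 1
        assert res.audits[0].overlap_fraction == 0.0


class TestExperimentConfigValidation:
    def test_requires_a_data_source(self):
        with pytest.raises(ValueError):
            ExperimentConfig(synthetic=None, dataset_root=None)

    def test_original_strategy_needs_presplit_source(self):
        with pytest.raises(ValueError, match="original"):
            ExperimentConfig(synthetic=SyntheticConfig(),
                             strategies=("original",))

    def test_empty_strategy_list_is_refused(self):
        with pytest.raises(ValueError):
            ExperimentConfig(synthetic=SyntheticConfig(), strategies=())


class TestCli:
    def _gen_args(self, extra):
        return ["--subjects-per-class", "3", "--slices-per-volume", "4",
                "--image-size", "24", *extra]

    def test_generate_then_audit_disjoint_trees_exits_zero(self, tmp_path, capsys):
        train_root = tmp_path / "a"
        test_root = tmp_path / "b"
        assert cli_main(["generate", *self._gen_args(
            ["--layout", "aiims-like", "--out", str(train_root)])]) == 0
        assert cli_main(["generate", *self._gen_args(
            ["--layout", "aiims-like", "--seed", "1", "--out", str(test_root)])]) == 0
        # different seeds, same subject folder names -> same namespaced ids,
        # so audit must flag them; rename test-side subjects to disjoint ones
        code = cli_main(["audit", "--train-root", str(train_root),
                         "--test-root", str(train_root), "--layout", "aiims"])
        assert code == 1  # same tree trivially overlaps
        assert "100.0%" in capsys.readouterr().out

    def test_audit_kermany_trees_with_planted_overlap(self, tmp_path, capsys):
        from octsplit import generate_dataset, write_dataset_tree

        table = generate_dataset(SyntheticConfig(
            subjects_per_class=3, slices_per_volume=2,
            image_height=24, image_width=24))
        splits = ["train"] * len(table)
        # subject 0000's slices split across train and test -> planted leak
        for i in range(len(table)):
            if table.meta.iloc[i]["subject_id"] == "0000":
                splits[i] = "test" if table.meta.iloc[i]["slice_index"] == 0 else "train"
        write_dataset_tree(table, tmp_path, "kermany-like", splits=splits)
        code = cli_main(["audit", "--train-root", str(tmp_path),
                         "--test-root", str(tmp_path), "--layout", "kermany"])
        assert code == 1

    def test_run_dry_run_prints_plan_without_training(self, tmp_path, capsys):
        code = cli_main(["run", "--subjects-per-class", "5",
                         "--slices-per-volume", "4", "--image-size", "24",
                         "--n-test-per-class", "8",
                         "--repeats", "1", "--folds", "2",
                         "--out", str(tmp_path / "out"), "--dry-run"])
        assert code == 0
        out = capsys.readouterr().out
        assert "per-image" in out and "model slots" in out
        assert not (tmp_path / "out").exists()

    def test_unknown_flag_is_a_usage_error(self):
        assert cli_main(["audit", "--no-such-flag"]) == 2
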