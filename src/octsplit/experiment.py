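"""Orchestration of the full split-strategy comparison.

Runs the same classifier under repeated cross-validation for each requested
split strategy on one dataset, audits train/test subject overlap for every
repeat, aggregates metrics as pooled mean ± std over models and classes,
and exports per-model metric rows (one CSV row per trained model) from
which box-plot style summaries can be rebuilt.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import leakage, metrics, model as model_mod, splitting
from .synthetic import SyntheticConfig, generate_dataset
from .table import DatasetTable

log = logging.getLogger("octsplit")

STRATEGIES = ("per-image", "per-volume-subject")


@dataclass
class ExperimentConfig:
    """One experiment = one dataset x a set of split strategies."""

    synthetic: SyntheticConfig | None = None
    dataset_root: str | None = None
    dataset_layout: str | None = None  # 'kermany' | 'aiims' | 'srinivasan'
    strategies: tuple = STRATEGIES
    n_test_per_class: int = 60
    repeats: int = 2
    folds: int = 5
    unit: str = "subject"
    model: model_mod.ModelConfig = field(default_factory=model_mod.ModelConfig)
    train: model_mod.TrainConfig = field(default_factory=model_mod.TrainConfig)
    output_dir: str | None = None
    seed: int = 0
    run_leakage_test: bool = False

    def __post_init__(self) -> None:
        if not self.strategies:
            raise ValueError("at least one split strategy is required")
        for s in self.strategies:
            if s not in (*STRATEGIES, "original"):
                raise ValueError(f"unknown strategy {s!r}")
        if "original" in self.strategies and self.dataset_layout not in ("kermany",):
            raise ValueError("'original' strategy requires a pre-split (kermany) source")
        if self.synthetic is None and self.dataset_root is None:
            raise ValueError("either a synthetic config or a dataset root is required")


@dataclass
class StrategyResult:
    strategy: str
    per_model: list[metrics.MetricsReport]
    aggregated: pd.DataFrame
    audits: list[splitting.OverlapReport]
    leakage_result: leakage.LeakageTestResult | None = None

    @property
    def mean_mcc(self) -> float:
        return float(np.mean([r.mcc for r in self.per_model]))


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    strategies: dict[str, StrategyResult] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def per_model_frame(self) -> pd.DataFrame:
        rows = []
        for name, res in self.strategies.items():
            for i, rep in enumerate(res.per_model):
                row = {"strategy": name, "model_slot": i, **rep.to_row()}
                rows.append(row)
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        frames = []
        for name, res in self.strategies.items():
            agg = res.aggregated.copy()
            agg.insert(0, "strategy", name)
            frames.append(agg.reset_index())
        return pd.concat(frames, ignore_index=True)


def _load_table(config: ExperimentConfig) -> DatasetTable:
    if config.synthetic is not None:
        return generate_dataset(config.synthetic)
    from . import dataset_io

    h, w = config.model.input_height, config.model.input_width
    if config.dataset_layout == "kermany":
        tables = dataset_io.load_kermany_split(config.dataset_root, h, w)
        from .table import concat_tables

        return concat_tables(list(tables.values()))
    return dataset_io.load_subjectwise_tree(config.dataset_root,
                                            layout=config.dataset_layout or "aiims",
                                            target_height=h, target_width=w)


def _run_cv_strategy(table: DatasetTable, strategy: str,
                     config: ExperimentConfig) -> StrategyResult:
    plan = splitting.make_fold_plan(
        table, strategy, config.n_test_per_class,
        repeats=config.repeats, folds=config.folds,
        base_seed=config.seed, unit=config.unit,
    )
    audits = []
    for r in range(config.repeats):
        entry = plan.entries[r * config.folds]
        pool = np.concatenate([entry["train"], entry["validation"]])
        audits.append(splitting.audit_overlap(table.subset(pool),
                                              table.subset(entry["test"])))
        log.info("strategy=%s repeat=%d %s", strategy, r, audits[-1].summary())
    reports = []
    for slot, entry in enumerate(plan.entries):
        t0 = time.perf_counter()
        net = model_mod.build_lightoct(config.model, seed=config.seed * 7919 + slot)
        tc = model_mod.TrainConfig(**{**config.train.__dict__,
                                      "seed": config.seed * 104729 + slot})
        model_mod.train_classifier(net, table.subset(entry["train"]),
                                   table.subset(entry["validation"]), tc)
        test_tbl = table.subset(entry["test"])
        probs = net.predict_probabilities(test_tbl)
        report = metrics.evaluate(test_tbl.labels, probs, table.class_set)
        reports.append(report)
        log.info("strategy=%s slot=%d/%d mcc=%.3f (%.1fs)", strategy, slot + 1,
                 len(plan), report.mcc, time.perf_counter() - t0)
    result = StrategyResult(strategy=strategy, per_model=reports,
                            aggregated=metrics.aggregate_reports(reports),
                            audits=audits)
    if config.run_leakage_test:
        result.leakage_result = leakage.run_random_label_experiment(
            table, plan, config.model, config.train,
            n_null_samples=2000, seed=config.seed,
        )
    return result


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run every requested strategy; a failing strategy is logged, not fatal."""
    table = _load_table(config)
    report = ExperimentReport(config=config)
    for strategy in config.strategies:
        try:
            if strategy == "original":
                report.strategies[strategy] = _run_original_strategy(config)
            else:
                report.strategies[strategy] = _run_cv_strategy(table, strategy, config)
        except Exception as exc:  # isolate per strategy to keep long runs useful
            log.exception("strategy %s failed", strategy)
            report.errors[strategy] = f"{type(exc).__name__}: {exc}"
    if config.output_dir:
        write_report(report, config.output_dir)
    return report


def _run_original_strategy(config: ExperimentConfig) -> StrategyResult:
    """Single model trained on the given train split, tested on the given test split."""
    from . import dataset_io

    h, w = config.model.input_height, config.model.input_width
    tables = dataset_io.load_kermany_split(config.dataset_root, h, w)
    if "train" not in tables or "test" not in tables:
        raise ValueError("original strategy needs both train and test split directories")
    train_tbl, test_tbl = tables["train"], tables["test"]
    audit = splitting.audit_overlap(train_tbl, test_tbl)
    log.info("strategy=original %s", audit.summary())
    net = model_mod.build_lightoct(config.model, seed=config.seed)
    model_mod.train_classifier(net, train_tbl, tables.get("val"), config.train)
    probs = net.predict_probabilities(test_tbl)
    report = metrics.evaluate(test_tbl.labels, probs, train_tbl.class_set)
    return StrategyResult(strategy="original", per_model=[report],
                          aggregated=metrics.aggregate_reports([report]),
                          audits=[audit])


def compare_strategies(report: ExperimentReport,
                       a: str = "per-image",
                       b: str = "per-volume-subject") -> pd.DataFrame:
    """Per-metric inflation Δ = mean(a) − mean(b) with pooled standard error.

    The pooled SE combines the two per-model standard deviations as
    sqrt(s_a²/n_a + s_b²/n_b) on whatever pooling each metric uses.
    """
    if len(report.strategies) < 2:
        raise ValueError("need at least two strategies to compare")
    if a not in report.strategies or b not in report.strategies:
        raise ValueError(f"strategies {a!r} and {b!r} must both be present")
    agg_a = report.strategies[a].aggregated
    agg_b = report.strategies[b].aggregated
    rows = []
    for metric in agg_a.index:
        if metric not in agg_b.index:
            continue
        ma, sa, na = agg_a.loc[metric, ["mean", "std", "n"]]
        mb, sb, nb = agg_b.loc[metric, ["mean", "std", "n"]]
        se = float(np.sqrt(sa ** 2 / max(na, 1) + sb ** 2 / max(nb, 1)))
        rows.append({"metric": metric, f"mean_{a}": ma, f"mean_{b}": mb,
                     "delta": float(ma - mb), "pooled_se": se})
    return pd.DataFrame(rows).set_index("metric")


def write_report(report: ExperimentReport, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_model_frame().to_csv(out / "per_model_metrics.csv", index=False)
    report.summary_frame().to_csv(out / "summary.csv", index=False)
    audits = {
        name: [json.loads(a.to_json()) for a in res.audits]
        for name, res in report.strategies.items()
    }
    (out / "audit.json").write_text(json.dumps(audits, indent=2) + "\n")
    payload = {
        "seed": report.config.seed,
        "strategies": {
            name: {
                "mean_mcc": res.mean_mcc,
                "n_models": len(res.per_model),
                "mean_overlap_fraction": float(np.mean(
                    [a.overlap_fraction for a in res.audits])),
            }
            for name, res in report.strategies.items()
        },
        "errors": report.errors,
    }
    if len(report.strategies) >= 2 and all(
            s in report.strategies for s in STRATEGIES):
        cmp = compare_strategies(report)
        payload["inflation"] = {
            "mcc_delta": float(cmp.loc["mcc", "delta"]),
            "mcc_pooled_se": float(cmp.loc["mcc", "pooled_se"]),
        }
    (out / "report.json").write_text(json.dumps(payload, indent=2) + "\n")
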