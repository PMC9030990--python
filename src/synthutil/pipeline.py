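"""End-to-end validation experiment.

For each simulated (or loaded) dataset and each synthesizer, a number of
synthetic replicates is generated; the six broad utility metrics and the
workload AUROC/AUPRC differences are computed per replicate and averaged.
Per utility metric the three synthesizers are then grouped H/M/L on every
dataset, the Page trend test is run against both workload differences with
a Bonferroni adjustment, and a footrule-aggregate ranking (excluding
predictionMSE, which is strongly related to propensityMSE) is tested the
same way.  Everything derives from one base seed, so any cell can be
recomputed in isolation.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import METRIC_NAMES, MetricConfig, compute_all_metrics, fit_copula
from .ranking import (
    AggregateRanking,
    PageTestResult,
    aggregate_ranking,
    assign_groups,
    build_rank_matrix,
    page_test,
)
from .simulate import random_real_spec, simulate_real
from .synthesizers import DEFAULT_METHODS, SynthesizerSpec, derive_seed, fit_and_sample
from .tabular import TabularDataset, encode, read_dataset
from .workload import cv_prediction_scores, workload_difference

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "export_boxplot_data", "leave_one_out_aggregate", "plot_group_boxplots"]

WORKLOADS = ("auroc_diff", "auprc_diff")
AGGREGATE_EXCLUDES = ("prediction_mse",)


@dataclass
class ExperimentConfig:
    """Experiment grid and knobs; everything derives from ``base_seed``.

    The default scale (10 datasets x 3 methods x 5 replicates at ~500
    rows) is a quick profile; ``repro_profile`` returns the full design
    with 30 datasets at 500-2,000 rows.
    """

    n_datasets: int = 10
    n_rows: int | None = 500
    n_rows_range: tuple[int, int] = (500, 2000)
    dataset_paths: list[tuple[str, str]] = field(default_factory=list)
    methods: tuple[SynthesizerSpec, ...] = DEFAULT_METHODS
    replicates: int = 5
    folds: int = 3
    alpha: float = 0.05
    base_seed: int = 0
    metric_config: MetricConfig = field(default_factory=MetricConfig)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.methods) < 3:
            raise ValueError("ranking requires >= 3 methods")

    @classmethod
    def repro_profile(cls, base_seed: int = 0) -> "ExperimentConfig":
        return cls(n_datasets=30, n_rows=None, n_rows_range=(500, 2000),
                   replicates=5, base_seed=base_seed)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        methods = doc.pop("methods", None)
        mc = doc.pop("metric_config", None)
        cfg = cls(**{k: v for k, v in doc.items() if k in cls.__dataclass_fields__})
        if methods is not None:
            cfg.methods = tuple(
                SynthesizerSpec(m["method_name"], m["fidelity_rank"],
                                m.get("hyperparameters", {}))
                for m in methods
            )
        if mc is not None:
            cfg.metric_config = MetricConfig(**mc)
        return cfg


@dataclass
class ExperimentResult:
    cells: pd.DataFrame          # one row per dataset x method (replicate means)
    page_tests: pd.DataFrame     # one row per metric x workload (+ aggregate)
    aggregate: pd.DataFrame      # per-dataset aggregate ranking
    manifest: dict


def _load_datasets(cfg: ExperimentConfig) -> list[TabularDataset]:
    if cfg.dataset_paths:
        return [read_dataset(c, m, name=f"ds{i}")
                for i, (c, m) in enumerate(cfg.dataset_paths)]
    datasets = []
    for i in range(cfg.n_datasets):
        spec = random_real_spec(
            seed=derive_seed(cfg.base_seed, "dataset", i),
            n_rows=cfg.n_rows,
            n_rows_range=cfg.n_rows_range,
            name=f"ds{i:02d}",
        )
        datasets.append(simulate_real(spec))
    return datasets


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the full validation experiment; optionally write result tables.

    Returns replicate-averaged cell means, Page-test results for every
    utility metric and the aggregate ranking (both workloads, Bonferroni
    m = number of utility metrics), and the per-dataset aggregate
    rankings.  Failed cells are logged in the manifest and excluded, with
    the affected tests marked incomplete.
    """
    t0 = time.time()
    datasets = _load_datasets(cfg)
    manifest: dict = {"base_seed": cfg.base_seed, "cells": [], "failures": [],
                      "n_datasets": len(datasets), "replicates": cfg.replicates}

    cell_rows = []
    for ds in datasets:
        real_enc = encode(ds, include_outcome=True)
        real_cop = fit_copula(real_enc)
        wl_seed = derive_seed(cfg.base_seed, ds.name, "workload")
        real_scores = cv_prediction_scores(ds, cfg.folds, wl_seed)
        for method in cfg.methods:
            t_cell = time.time()
            metric_sums = {m: [] for m in METRIC_NAMES}
            auroc_diffs, auprc_diffs = [], []
            completed = 0
            for rep in range(cfg.replicates):
                rep_seed = derive_seed(cfg.base_seed, ds.name,
                                       method.method_name, rep)
                try:
                    syn = fit_and_sample(method, ds, replicate_seed=rep_seed)
                    mc = MetricConfig(**{**cfg.metric_config.__dict__,
                                         "seed": rep_seed})
                    scores = compute_all_metrics(
                        ds, syn, mc, dataset_name=ds.name,
                        method_name=method.method_name, replicate_index=rep,
                        real_enc=real_enc, real_copula=real_cop,
                    )
                    wl = workload_difference(
                        ds, syn, cfg.folds, wl_seed, dataset_name=ds.name,
                        method_name=method.method_name, replicate_index=rep,
                        real_scores=real_scores,
                    )
                except Exception as exc:  # auditable, not silent
                    manifest["failures"].append(
                        {"dataset": ds.name, "method": method.method_name,
                         "replicate": rep, "error": repr(exc)}
                    )
                    continue
                for s in scores:
                    metric_sums[s.metric_name].append(s.value)
                auroc_diffs.append(wl.auroc_abs_diff)
                auprc_diffs.append(wl.auprc_abs_diff)
                completed += 1
            row = {"dataset": ds.name, "method": method.method_name,
                   "replicates_completed": completed,
                   "auroc_real": real_scores[0], "auprc_real": real_scores[1]}
            for m in METRIC_NAMES:
                row[m] = float(np.mean(metric_sums[m])) if metric_sums[m] else np.nan
            row["auroc_diff"] = float(np.mean(auroc_diffs)) if auroc_diffs else np.nan
            row["auprc_diff"] = float(np.mean(auprc_diffs)) if auprc_diffs else np.nan
            cell_rows.append(row)
            manifest["cells"].append(
                {"dataset": ds.name, "method": method.method_name,
                 "seconds": round(time.time() - t_cell, 3),
                 "replicates_completed": completed}
            )
    cells = pd.DataFrame(cell_rows)

    page_rows, agg_rows = _rank_and_test(cells, cfg, manifest)
    page_tests = pd.DataFrame(page_rows)
    aggregate = pd.DataFrame(agg_rows)
    manifest["seconds_total"] = round(time.time() - t0, 3)

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        cells.to_csv(out / "cells.csv", index=False)
        page_tests.to_csv(out / "page_tests.csv", index=False)
        aggregate.to_csv(out / "aggregate.csv", index=False)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
    return ExperimentResult(cells=cells, page_tests=page_tests,
                            aggregate=aggregate, manifest=manifest)


def _complete_datasets(cells: pd.DataFrame, n_methods: int) -> pd.DataFrame:
    """Keep datasets with a complete, non-NaN cell row for every method."""
    ok_names = []
    for name, grp in cells.groupby("dataset"):
        if len(grp) == n_methods and not grp[list(METRIC_NAMES) +
                                             ["auroc_diff", "auprc_diff"]].isna().any().any():
            ok_names.append(name)
    return cells[cells["dataset"].isin(ok_names)]


def _rank_and_test(cells: pd.DataFrame, cfg: ExperimentConfig, manifest: dict):
    n_methods = len(cfg.methods)
    usable = _complete_datasets(cells, n_methods)
    dropped = sorted(set(cells["dataset"]) - set(usable["dataset"]))
    if dropped:
        manifest["incomplete_datasets"] = dropped

    diffs: dict[str, dict[str, dict[str, float]]] = {w: {} for w in WORKLOADS}
    metric_means: dict[str, dict[str, dict[str, float]]] = {m: {} for m in METRIC_NAMES}
    for name, grp in usable.groupby("dataset"):
        for w in WORKLOADS:
            diffs[w][name] = dict(zip(grp["method"], grp[w]))
        for m in METRIC_NAMES:
            metric_means[m][name] = dict(zip(grp["method"], grp[m]))

    m_tests = len(METRIC_NAMES)
    page_rows = []
    groups_by_metric: dict[str, dict[str, tuple[str, str, str]]] = {}
    for m in METRIC_NAMES:
        groups = {}
        any_tie = False
        for name, means in metric_means[m].items():
            g, tie = assign_groups(means)
            groups[name] = g
            any_tie = any_tie or tie
        groups_by_metric[m] = groups
        for w in WORKLOADS:
            rm = build_rank_matrix(groups, diffs[w], workload_name=w, metric_name=m)
            res = page_test(rm, alpha=cfg.alpha, m=m_tests,
                            mc_seed=derive_seed(cfg.base_seed, "mc", m, w))
            page_rows.append({
                "metric": m, "workload": w, "L": res.L, "n": res.n_rows,
                "p_value": res.p_value, "significant": res.significant,
                "alpha_adjusted": res.alpha_adjusted, "exact": res.exact,
                "grouping_ties": any_tie,
            })

    # aggregate ranking per dataset over the non-excluded metrics
    agg_metrics = [m for m in METRIC_NAMES if m not in AGGREGATE_EXCLUDES]
    agg_rows = []
    agg_groups: dict[str, tuple[str, str, str]] = {}
    for name in metric_means[METRIC_NAMES[0]]:
        inputs = []
        for m in agg_metrics:
            means = metric_means[m][name]
            order = sorted(means, key=lambda k: (means[k], k))
            inputs.append({meth: i + 1 for i, meth in enumerate(order)})
        agg = aggregate_ranking(inputs)
        ordered = sorted(agg.ranking, key=agg.ranking.get)
        agg_groups[name] = tuple(ordered)
        agg_rows.append({"dataset": name, "total_footrule_cost": agg.total_cost,
                         "tie_broken": agg.tie_broken,
                         **{f"rank_{meth}": r for meth, r in agg.ranking.items()}})
    for w in WORKLOADS:
        rm = build_rank_matrix(agg_groups, diffs[w], workload_name=w,
                               metric_name="aggregate")
        res = page_test(rm, alpha=cfg.alpha, m=m_tests,
                        mc_seed=derive_seed(cfg.base_seed, "mc", "agg", w))
        page_rows.append({
            "metric": "aggregate", "workload": w, "L": res.L, "n": res.n_rows,
            "p_value": res.p_value, "significant": res.significant,
            "alpha_adjusted": res.alpha_adjusted, "exact": res.exact,
            "grouping_ties": False,
        })
    return page_rows, agg_rows


def export_boxplot_data(cells: pd.DataFrame, grouping_metric: str,
                        n_methods: int = 3) -> pd.DataFrame:
    """Long-format (dataset, group, workload, value) table: workload
    differences of each method binned into the H/M/L group that
    ``grouping_metric`` assigns them — the descriptive trend view."""
    if grouping_metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {grouping_metric!r}")
    usable = _complete_datasets(cells, n_methods)
    rows = []
    for name, grp in usable.groupby("dataset"):
        means = dict(zip(grp["method"], grp[grouping_metric]))
        (h, m_, l), tie = assign_groups(means)
        diffs = {w: dict(zip(grp["method"], grp[w])) for w in WORKLOADS}
        for g_label, meth in zip(("H", "M", "L"), (h, m_, l)):
            for w in WORKLOADS:
                rows.append({"dataset": name, "group": g_label, "workload": w,
                             "value": diffs[w][meth], "tie_flag": tie})
    return pd.DataFrame(rows)


def plot_group_boxplots(long_table: pd.DataFrame, out_path,
                        title: str = "") -> None:
    """Boxplots of workload differences by H/M/L group, one panel per
    workload (the descriptive trend figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    workloads = sorted(long_table["workload"].unique())
    fig, axes = plt.subplots(1, len(workloads), figsize=(4 * len(workloads), 4))
    if len(workloads) == 1:
        axes = [axes]
    for ax, w in zip(axes, workloads):
        sub = long_table[long_table["workload"] == w]
        data = [sub[sub["group"] == g]["value"].to_numpy() for g in ("H", "M", "L")]
        ax.boxplot(data, tick_labels=["H", "M", "L"])
        ax.set_xlabel("utility group")
        ax.set_ylabel(w)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def leave_one_out_aggregate(cells: pd.DataFrame, cfg: ExperimentConfig) -> pd.DataFrame:
    """Post-hoc: drop each aggregated metric in turn, recompute the
    footrule-aggregate ranking and its Page test for both workloads."""
    n_methods = len(cfg.methods)
    usable = _complete_datasets(cells, n_methods)
    agg_metrics = [m for m in METRIC_NAMES if m not in AGGREGATE_EXCLUDES]
    rows = []
    for left_out in agg_metrics:
        kept = [m for m in agg_metrics if m != left_out]
        agg_groups = {}
        for name, grp in usable.groupby("dataset"):
            inputs = []
            for m in kept:
                means = dict(zip(grp["method"], grp[m]))
                order = sorted(means, key=lambda k: (means[k], k))
                inputs.append({meth: i + 1 for i, meth in enumerate(order)})
            agg = aggregate_ranking(inputs)
            agg_groups[name] = tuple(sorted(agg.ranking, key=agg.ranking.get))
        diffs = {w: {name: dict(zip(grp["method"], grp[w]))
                     for name, grp in usable.groupby("dataset")}
                 for w in WORKLOADS}
        for w in WORKLOADS:
            rm = build_rank_matrix(agg_groups, diffs[w], workload_name=w,
                                   metric_name=f"aggregate-minus-{left_out}")
            res = page_test(rm, alpha=cfg.alpha, m=len(METRIC_NAMES),
                            mc_seed=derive_seed(cfg.base_seed, "loo", left_out, w))
            rows.append({"left_out": left_out, "workload": w, "L": res.L,
                         "n": res.n_rows, "p_value": res.p_value,
                         "significant": res.significant})
    return pd.DataFrame(rows)
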