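"""End-to-end pipeline orchestration: simulate -> select -> ffl -> validate
-> classify -> network, with all artifacts written to a run directory and a
machine-readable summary."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import data_io
from .data_io import ParallelDataset, PriorCatalog, TFRoster
from .ffl_builder import count_by_class, enumerate_ffls, ffl_feature_ids, write_ffls
from .filter_mrmr import DiscretizationScheme
from .wrapper_regression import identify_edges, identified_edge_set
from .validation_stats import null_ffl_test, pcc_shift_test
from .classification_eval import loocv_svm, permutation_baseline
from .coreg_network import (
    build_network,
    degree_and_hub,
    export_graphml,
    export_sif,
    occurrence_ranking,
)
from .synthetic_data import SimulationConfig, preset, simulate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs of the full pipeline; defaults follow the method's constants."""

    out_dir: str = "ffloops_run"
    simulate_preset: str = "pan_cancer_like"
    mrna_path: str | None = None  # when set, load instead of simulating
    mirna_path: str | None = None
    priors_path: str | None = None
    labels_path: str | None = None
    tf_roster: list[str] = field(default_factory=list)
    alpha: float = 0.01
    max_candidates: int = 20
    mi_scheme: str = "mean_sd_3state"
    mi_bins: int = 3
    mi_sd_factor: float = 0.5
    n_perm: int = 100
    n_null_draws: int = 1000
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    n_label_perm: int = 100
    seed: int = 0


def _load_inputs(
    cfg: PipelineConfig,
) -> tuple[ParallelDataset, PriorCatalog, TFRoster]:
    if cfg.mrna_path is None:
        sim_cfg = preset(cfg.simulate_preset)
        sim_cfg = SimulationConfig(**{**asdict_cfg(sim_cfg), "seed": cfg.seed})
        dataset, priors, roster, _ = simulate(sim_cfg)
        return dataset, priors, roster
    for name in ("mrna_path", "mirna_path", "priors_path"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"{name} missing or not found: {p}")
    mrna = data_io.load_expression(cfg.mrna_path, data_io.GENE)
    mirna = data_io.load_expression(cfg.mirna_path, data_io.MIRNA)
    labels = data_io.load_labels(cfg.labels_path) if cfg.labels_path else None
    dataset = data_io.align_parallel(mrna, mirna, labels)
    roster = TFRoster(tf_ids=frozenset(cfg.tf_roster))
    priors = data_io.load_prior_catalog(cfg.priors_path, roster)
    return dataset, priors, roster


def asdict_cfg(sim_cfg: SimulationConfig) -> dict:
    d = asdict(sim_cfg)
    return d


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages, write artifacts under ``cfg.out_dir``, return summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = DiscretizationScheme(
        method=cfg.mi_scheme, n_bins=cfg.mi_bins, sd_factor=cfg.mi_sd_factor
    )
    summary: dict = {"stages": [], "seed": cfg.seed}

    def stage(name):
        t0 = time.time()
        logger.info("stage %s started", name)
        summary["stages"].append(name)
        return t0

    t0 = stage("load")
    dataset, priors, roster = _load_inputs(cfg)
    summary["n_samples"] = dataset.n_samples
    summary["n_prior_edges"] = len(priors)

    stage("select")
    selections = identify_edges(
        dataset, priors, scheme=scheme, alpha=cfg.alpha,
        max_candidates=cfg.max_candidates,
    )
    edges = identified_edge_set(selections)
    stats = {e: sel.stats[e] for sel in selections.values() for e in sel.edges}
    data_io.write_edges(edges, out / "identified_edges.tsv", extra=stats)
    summary["n_identified_edges"] = len(edges)

    stage("ffl")
    ffls = enumerate_ffls(edges, roster)
    write_ffls(ffls, out / "ffls.tsv")
    summary["ffl_counts"] = count_by_class(ffls)

    stage("validate")
    per_type = {}
    for pair in (("TF", "gene"), ("TF", "miRNA"), ("miRNA", "gene")):
        k = sum(
            1 for e in edges
            if (e.regulator_type, e.target_type) == pair
        )
        if k:
            per_type[pair] = k
    if ffls and per_type:
        null_report = null_ffl_test(
            count_by_class(ffls), priors, per_type, roster,
            n_draws=cfg.n_null_draws, seed=cfg.seed,
        )
        summary["null_ffl_pvalues"] = null_report.t_pvalue
        summary["null_ffl_means"] = null_report.null_mean
    before_pairs, after_pairs = [], []
    for e in priors:
        reg, tgt = dataset.profile(e.regulator_id), dataset.profile(e.target_id)
        if reg is None or tgt is None:
            continue
        before_pairs.append((reg, tgt))
        if e in edges:
            after_pairs.append((reg, tgt))
    if before_pairs and after_pairs:
        _, _, u_p = pcc_shift_test(before_pairs, after_pairs)
        summary["pcc_shift_u_pvalue"] = u_p

    if dataset.labels is not None and ffls:
        stage("classify")
        features = [f for f in ffl_feature_ids(ffls) if dataset.has_feature(f)]
        report = loocv_svm(dataset, features, kernel=cfg.svm_kernel, C=cfg.svm_c)
        baseline = permutation_baseline(
            dataset, features, n_perm=cfg.n_label_perm, seed=cfg.seed,
            kernel=cfg.svm_kernel, C=cfg.svm_c,
        )
        summary["classification"] = {
            "acc": report.acc, "sn": report.sn, "sp": report.sp,
            "mcc": report.mcc, "auc": report.auc,
            "baseline_acc": baseline.acc, "baseline_mcc": baseline.mcc,
        }

    if ffls:
        stage("network")
        net = build_network(ffls)
        degrees, hub = degree_and_hub(net)
        export_sif(net, out / "network.sif")
        export_graphml(net, out / "network.graphml")
        occurrence_ranking({"run": ffls}).to_csv(out / "occurrence.tsv", sep="\t")
        summary["network"] = {
            "n_nodes": len(net.nodes), "n_edges": net.n_edges,
            "hub": hub, "hub_degree": degrees[hub],
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
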