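"""Synthetic parallel expression data with planted regulatory structure.

The generator emulates the kind of input the pipeline expects from real
parallel microarray studies: an mRNA matrix (TFs plus other genes), a miRNA
matrix over the same samples, a prior catalog of candidate interactions, and
optionally two-class sample labels.

The statistical structure follows the linear regulatory model the selection
method assumes: root regulator profiles are i.i.d. standard normal and every
regulated feature is a linear combination of its regulators' profiles plus
Gaussian noise. TF regulation carries positive coefficients, miRNA regulation
negative ones (repression). Planted feed-forward loops of all three classes
supply true edges; decoy prior edges with zero effect emulate the false
positives of target-prediction databases. With ``class_shift > 0`` every
planted-FFL member feature receives a mean shift in the first class, giving
labeled two-class data for classifier evaluation.

Presets scale the two study designs the pipeline targets: a 60-sample
pan-cancer cell-line panel (unlabeled) and a 139-sample prostate cohort with
a 111 tumor / 28 normal split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import (
    Edge,
    ExpressionMatrix,
    ParallelDataset,
    PriorCatalog,
    TFRoster,
    GENE,
    MIRNA,
    TF,
)
from .ffl_builder import FFL, COMPOSITE_FFL, MIRNA_FFL, TF_FFL, enumerate_ffls


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 60
    n_tfs: int = 8
    n_mirnas: int = 8
    n_genes: int = 30
    n_tf_ffls: int = 3
    n_mirna_ffls: int = 3
    n_composite_ffls: int = 1
    effect_size_range: tuple[float, float] = (0.6, 1.2)
    mirna_sign: int = -1
    noise_sd: float = 0.5
    decoy_edges_per_true: float = 4.0
    class_shift: float = 0.0
    class_sizes: tuple[int, int] | None = None  # (positive, negative)
    class_names: tuple[str, str] = ("cancer", "normal")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_tfs, self.n_mirnas, self.n_genes) <= 0:
            raise ValueError("all counts must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.decoy_edges_per_true < 0:
            raise ValueError("decoy ratio must be >= 0")
        n_ffls = self.n_tf_ffls + self.n_mirna_ffls + self.n_composite_ffls
        if n_ffls > min(self.n_tfs, self.n_mirnas, self.n_genes):
            raise ValueError("not enough features for disjoint planted FFLs")
        if self.class_sizes is not None and sum(self.class_sizes) != self.n_samples:
            raise ValueError("class sizes must sum to n_samples")


@dataclass
class GroundTruth:
    true_edges: dict[Edge, float]  # edge -> generative coefficient
    planted_ffls: list[FFL]
    decoy_edges: frozenset[Edge]
    shifted_features: list[str] = field(default_factory=list)


def preset(name: str) -> SimulationConfig:
    """Named study-design presets.

    ``pan_cancer_like``: 60 unlabeled samples (cell-line-panel scale).
    ``prostate_like``: 139 samples labeled 111 cancer / 28 normal, with a
    2-sigma class shift on planted-FFL features.
    """
    if name == "pan_cancer_like":
        return SimulationConfig(n_samples=60)
    if name == "prostate_like":
        return SimulationConfig(
            n_samples=139, class_sizes=(111, 28), class_shift=2.0
        )
    raise ValueError(f"unknown preset {name!r}")


def _effect(rng: np.random.Generator, cfg: SimulationConfig, sign: int) -> float:
    lo, hi = cfg.effect_size_range
    return sign * float(rng.uniform(lo, hi))


def simulate(
    config: SimulationConfig,
) -> tuple[ParallelDataset, PriorCatalog, TFRoster, GroundTruth]:
    """Generate a parallel dataset, prior catalog, TF roster and ground truth.

    Fully reproducible from ``config.seed``. Planted FFLs use disjoint TF /
    miRNA / target-gene triples so each regulated feature has an unambiguous
    generative model; composite loops couple the TF and miRNA negatively (the
    repressive direction dominates) and record both mutual edges as true.
    """
    rng = np.random.default_rng(config.seed)
    tf_ids = [f"TF{i:03d}" for i in range(1, config.n_tfs + 1)]
    mirna_ids = [f"miR{i:03d}" for i in range(1, config.n_mirnas + 1)]
    gene_ids = [f"G{i:03d}" for i in range(1, config.n_genes + 1)]
    n = config.n_samples

    # plant FFLs on disjoint triples, class by class
    planted: list[FFL] = []
    classes = (
        [TF_FFL] * config.n_tf_ffls
        + [MIRNA_FFL] * config.n_mirna_ffls
        + [COMPOSITE_FFL] * config.n_composite_ffls
    )
    for i, cls in enumerate(classes):
        planted.append(FFL(cls, tf_ids[i], mirna_ids[i], gene_ids[i]))

    true_edges: dict[Edge, float] = {}
    profiles: dict[str, np.ndarray] = {}

    def noise() -> np.ndarray:
        return rng.normal(0.0, config.noise_sd, size=n)

    # roots first: every TF except those repressed in miRNA-FFLs, free miRNAs
    for f in planted:
        if f.ffl_class == MIRNA_FFL:
            profiles[f.mirna_id] = rng.standard_normal(n)
    for tid in tf_ids:
        if tid not in profiles and not any(
            f.ffl_class == MIRNA_FFL and f.tf_id == tid for f in planted
        ):
            profiles[tid] = rng.standard_normal(n)

    for f in planted:
        if f.ffl_class == TF_FFL:
            b = _effect(rng, config, +1)
            profiles[f.mirna_id] = b * profiles[f.tf_id] + noise()
            true_edges[Edge(TF, f.tf_id, MIRNA, f.mirna_id, "planted")] = b
        elif f.ffl_class == MIRNA_FFL:
            b = _effect(rng, config, config.mirna_sign)
            profiles[f.tf_id] = b * profiles[f.mirna_id] + noise()
            true_edges[Edge(MIRNA, f.mirna_id, GENE, f.tf_id, "planted")] = b
        else:  # composite: negative mutual coupling, TF drawn as the root
            b = _effect(rng, config, config.mirna_sign)
            profiles[f.mirna_id] = b * profiles[f.tf_id] + noise()
            true_edges[Edge(TF, f.tf_id, MIRNA, f.mirna_id, "planted")] = b
            true_edges[Edge(MIRNA, f.mirna_id, GENE, f.tf_id, "planted")] = b
    for mid in mirna_ids:
        if mid not in profiles:
            profiles[mid] = rng.standard_normal(n)

    # planted target genes: two regulators each; free genes pure noise
    for f in planted:
        b_tf = _effect(rng, config, +1)
        b_mi = _effect(rng, config, config.mirna_sign)
        profiles[f.target_gene_id] = (
            b_tf * profiles[f.tf_id] + b_mi * profiles[f.mirna_id] + noise()
        )
        true_edges[Edge(TF, f.tf_id, GENE, f.target_gene_id, "planted")] = b_tf
        true_edges[Edge(MIRNA, f.mirna_id, GENE, f.target_gene_id, "planted")] = b_mi
    for gid in gene_ids:
        if gid not in profiles:
            profiles[gid] = rng.standard_normal(n)

    # decoy prior edges: allowed-type pairs with zero generative effect
    mrna_features = tf_ids + gene_ids
    possible: list[Edge] = []
    for t in tf_ids:
        for g in mrna_features:
            if g != t:
                possible.append(Edge(TF, t, GENE, g, "decoy"))
        for m in mirna_ids:
            possible.append(Edge(TF, t, MIRNA, m, "decoy"))
    for m in mirna_ids:
        for g in mrna_features:
            possible.append(Edge(MIRNA, m, GENE, g, "decoy"))
    taken = {(e.regulator_id, e.target_id) for e in true_edges}
    pool = sorted(e for e in possible if (e.regulator_id, e.target_id) not in taken)
    n_decoys = int(round(config.decoy_edges_per_true * len(true_edges)))
    if n_decoys > len(pool):
        raise ValueError(f"cannot place {n_decoys} decoys: only {len(pool)} pairs free")
    idx = rng.choice(len(pool), size=n_decoys, replace=False)
    decoys = frozenset(pool[i] for i in sorted(idx))

    # labels and class shift
    sample_ids = [f"S{i:03d}" for i in range(1, n + 1)]
    labels: dict[str, str] | None = None
    shifted: list[str] = []
    if config.class_sizes is not None:
        n_pos, _ = config.class_sizes
        pos_name, neg_name = config.class_names
        labels = {
            s: (pos_name if i < n_pos else neg_name)
            for i, s in enumerate(sample_ids)
        }
        if config.class_shift > 0:
            mask = np.array([i < n_pos for i in range(n)], dtype=float)
            for f in planted:
                for fid in (f.tf_id, f.mirna_id, f.target_gene_id):
                    if fid not in shifted:
                        sign = -1.0 if fid in mirna_ids else 1.0
                        profiles[fid] = profiles[fid] + sign * config.class_shift * mask
                        shifted.append(fid)

    mrna = ExpressionMatrix(
        data=pd.DataFrame(
            np.array([profiles[fid] for fid in mrna_features]),
            index=mrna_features, columns=sample_ids,
        ),
        feature_type=GENE,
    )
    mirna = ExpressionMatrix(
        data=pd.DataFrame(
            np.array([profiles[mid] for mid in mirna_ids]),
            index=mirna_ids, columns=sample_ids,
        ),
        feature_type=MIRNA,
    )
    dataset = ParallelDataset(mrna=mrna, mirna=mirna, labels=labels)
    priors = PriorCatalog(edges=frozenset(true_edges) | decoys)
    roster = TFRoster(tf_ids=frozenset(tf_ids))
    truth = GroundTruth(
        true_edges=true_edges,
        planted_ffls=sorted(planted),
        decoy_edges=decoys,
        shifted_features=shifted,
    )
    # construction consistency: the planted loops are recoverable from truth
    assert set(truth.planted_ffls) <= set(enumerate_ffls(true_edges, roster))
    return dataset, priors, roster, truth
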