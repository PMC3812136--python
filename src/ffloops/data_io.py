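"""Input/output for expression matrices, prior interaction catalogs and labels.

File conventions
----------------
Expression: TSV, features in rows, samples in columns; header row carries the
sample ids and the first column the feature ids. Empty cells are missing values.

Prior catalog / identified edges: TSV edge list with columns
``regulator_type, regulator_id, target_type, target_id, source_tag``
(identified edges carry extra model-statistics columns).

Labels: two-column TSV ``sample_id<TAB>class``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE = "gene"
MIRNA = "miRNA"
TF = "TF"

#: the regulator->target type pairs a catalog may contain. miRNA->TF regulation
#: is represented as a miRNA->gene edge whose target sits in the TF roster.
ALLOWED_TYPE_PAIRS = {(TF, GENE), (TF, MIRNA), (MIRNA, GENE)}

EDGE_COLUMNS = ["regulator_type", "regulator_id", "target_type", "target_id", "source_tag"]


class ValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Named features x named samples of real expression values.

    ``feature_type`` tags the whole matrix as gene or miRNA expression; values
    are treated as-is (log-intensity assumed but not enforced).
    """

    data: pd.DataFrame  # index = feature ids, columns = sample ids
    feature_type: str

    def __post_init__(self) -> None:
        if self.feature_type not in (GENE, MIRNA):
            raise ValidationError(f"unknown feature_type {self.feature_type!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if self.data.isna().any().any():
            raise ValidationError("expression matrix contains missing values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def profile(self, feature_id: str) -> np.ndarray:
        return self.data.loc[feature_id].to_numpy(dtype=float)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.data.index


@dataclass
class ParallelDataset:
    """mRNA and miRNA expression over the same samples, in the same order."""

    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.mrna.sample_ids != self.mirna.sample_ids:
            raise ValidationError("mRNA and miRNA sample ids differ; use align_parallel")
        if self.labels is not None:
            if set(self.labels) != set(self.mrna.sample_ids):
                raise ValidationError("labels must cover exactly the shared samples")

    @property
    def sample_ids(self) -> list[str]:
        return self.mrna.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.mrna.sample_ids)

    def profile(self, feature_id: str) -> np.ndarray | None:
        """Expression profile of a feature from whichever matrix holds it."""
        if feature_id in self.mirna:
            return self.mirna.profile(feature_id)
        if feature_id in self.mrna:
            return self.mrna.profile(feature_id)
        return None

    def has_feature(self, feature_id: str) -> bool:
        return feature_id in self.mirna or feature_id in self.mrna


@dataclass(frozen=True, order=True)
class Edge:
    """One typed directed candidate interaction."""

    regulator_type: str
    regulator_id: str
    target_type: str
    target_id: str
    source_tag: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        return (self.regulator_id, self.target_id)


@dataclass
class TFRoster:
    """Gene identifiers designated as transcription factors."""

    tf_ids: frozenset[str]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.tf_ids


@dataclass
class PriorCatalog:
    """Deduplicated candidate edges of the three allowed interaction types."""

    edges: frozenset[Edge]
    n_rejected: int = 0

    def __post_init__(self) -> None:
        for e in self.edges:
            if (e.regulator_type, e.target_type) not in ALLOWED_TYPE_PAIRS:
                raise ValidationError(
                    f"disallowed type pair {e.regulator_type}->{e.target_type}"
                )
            if e.regulator_id == e.target_id:
                raise ValidationError(f"self-edge on {e.regulator_id}")

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(sorted(self.edges))

    def regulators_of(self, target_id: str) -> list[Edge]:
        return sorted(e for e in self.edges if e.target_id == target_id)

    def targets(self) -> list[str]:
        return sorted({e.target_id for e in self.edges})

    def edges_of_type(self, regulator_type: str, target_type: str) -> list[Edge]:
        return sorted(
            e
            for e in self.edges
            if e.regulator_type == regulator_type and e.target_type == target_type
        )


def load_expression(
    path, feature_type: str, missing_policy: str = "drop_feature"
) -> ExpressionMatrix:
    """Read a features-x-samples TSV into an :class:`ExpressionMatrix`.

    ``missing_policy`` is ``drop_feature`` (rows with any missing cell are
    removed) or ``impute_feature_mean`` (missing cells filled with the row
    mean). Non-numeric body cells raise with row/column coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids in {path}: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    # cells that fail conversion but were not empty are parse errors
    bad = numeric.isna() & df.notna() & (df.astype(str).apply(lambda s: s.str.strip()) != "")
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric cell at feature {df.index[r]!r}, sample {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    if missing_policy == "drop_feature":
        numeric = numeric.dropna(axis=0, how="any")
    elif missing_policy == "impute_feature_mean":
        numeric = numeric.apply(lambda row: row.fillna(row.mean()), axis=1)
        numeric = numeric.dropna(axis=0, how="any")  # fully-missing rows stay NaN
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    return ExpressionMatrix(data=numeric.astype(float), feature_type=feature_type)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id")


def load_prior_catalog(path, tf_roster: TFRoster | None = None) -> PriorCatalog:
    """Read a typed edge-list TSV, dedupe, and reject disallowed type pairs.

    Rows whose (regulator_type, target_type) pair is not one of TF->gene,
    TF->miRNA, miRNA->gene are dropped and counted in ``n_rejected``; an
    unknown type tag raises.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in EDGE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValidationError(f"prior catalog missing columns {missing}")
    if "source_tag" not in df.columns:
        df["source_tag"] = ""
    known = {GENE, MIRNA, TF}
    unknown = (set(df["regulator_type"]) | set(df["target_type"])) - known
    if unknown:
        raise ValidationError(f"unknown type tags: {sorted(unknown)}")
    edges: set[Edge] = set()
    seen_pairs: set[tuple[str, str]] = set()
    n_rejected = 0
    for row in df.itertuples(index=False):
        pair_types = (row.regulator_type, row.target_type)
        if pair_types not in ALLOWED_TYPE_PAIRS or row.regulator_id == row.target_id:
            n_rejected += 1
            continue
        if (row.regulator_id, row.target_id) in seen_pairs:
            continue
        seen_pairs.add((row.regulator_id, row.target_id))
        edges.add(
            Edge(row.regulator_type, row.regulator_id, row.target_type, row.target_id,
                 row.source_tag)
        )
    if n_rejected:
        logger.warning("rejected %d prior rows with disallowed types", n_rejected)
    return PriorCatalog(edges=frozenset(edges), n_rejected=n_rejected)


def write_edges(edges: Iterable[Edge], path, extra: Mapping[Edge, Mapping] | None = None) -> None:
    """Write edges as TSV; ``extra`` maps an edge to extra stat columns."""
    rows = []
    for e in sorted(set(edges)):
        row = {
            "regulator_type": e.regulator_type,
            "regulator_id": e.regulator_id,
            "target_type": e.target_type,
            "target_id": e.target_id,
            "source_tag": e.source_tag,
        }
        if extra and e in extra:
            row.update(extra[e])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "label"], dtype=str)
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in label file")
    return dict(zip(df["sample_id"], df["label"]))


def write_labels(labels: Mapping[str, str], path) -> None:
    pd.DataFrame(sorted(labels.items())).to_csv(path, sep="\t", header=False, index=False)


def align_parallel(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    labels: Mapping[str, str] | None = None,
) -> ParallelDataset:
    """Intersect samples of the two matrices and build a parallel dataset.

    If the sample sets are identical the mRNA matrix's order is preserved;
    otherwise the intersection is taken in sorted order. Labels, when given,
    are restricted to the shared samples.
    """
    shared = set(mrna.sample_ids) & set(mirna.sample_ids)
    if not shared:
        raise ValidationError("no shared samples between mRNA and miRNA matrices")
    if set(mrna.sample_ids) == set(mirna.sample_ids):
        order = mrna.sample_ids
    else:
        order = sorted(shared)
    dropped = (len(mrna.sample_ids) - len(order)) + (len(mirna.sample_ids) - len(order))
    if dropped:
        logger.warning("align_parallel dropped %d unshared sample columns", dropped)
    sub_labels = None
    if labels is not None:
        sub_labels = {s: labels[s] for s in order if s in labels}
        if set(sub_labels) != set(order):
            missing = sorted(set(order) - set(sub_labels))
            raise ValidationError(f"labels missing for samples: {missing}")
    return ParallelDataset(
        mrna=ExpressionMatrix(mrna.data[order], mrna.feature_type),
        mirna=ExpressionMatrix(mirna.data[order], mirna.feature_type),
        labels=sub_labels,
    )
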