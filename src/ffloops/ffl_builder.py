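"""Enumeration of TF-miRNA co-regulatory feed-forward loops.

Three 3-vertex motif classes over identified regulatory edges:

* TF-FFL:        TF -> miRNA, TF -> gene, miRNA -> gene
* miRNA-FFL:     miRNA -> TF, miRNA -> gene, TF -> gene
* composite-FFL: TF <-> miRNA mutually, plus TF -> gene and miRNA -> gene

miRNA -> TF regulation is a miRNA -> gene edge whose target sits in the TF
roster. A motif with mutual TF/miRNA regulation is reported only as composite,
never double-counted in the TF-/miRNA-FFL lists, so class counts are additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .data_io import Edge, TFRoster, GENE, MIRNA, TF

TF_FFL = "TF_FFL"
MIRNA_FFL = "miRNA_FFL"
COMPOSITE_FFL = "composite_FFL"
FFL_CLASSES = (TF_FFL, MIRNA_FFL, COMPOSITE_FFL)


@dataclass(frozen=True, order=True)
class FFL:
    """One feed-forward loop instance: its class and three distinct vertices."""

    ffl_class: str
    tf_id: str
    mirna_id: str
    target_gene_id: str

    def __post_init__(self) -> None:
        if self.ffl_class not in FFL_CLASSES:
            raise ValueError(f"unknown FFL class {self.ffl_class!r}")
        if len({self.tf_id, self.mirna_id, self.target_gene_id}) != 3:
            raise ValueError("FFL vertices must be distinct")

    @property
    def regulator_ids(self) -> tuple[str, str]:
        return (self.tf_id, self.mirna_id)


def enumerate_ffls(edges: Iterable[Edge], tf_roster: TFRoster) -> list[FFL]:
    """Exhaustively enumerate all FFL instances in a typed edge set.

    Implemented as an indexed adjacency join over (TF, miRNA) regulator pairs
    sharing a target gene; output is sorted by (class, tf, mirna, gene).
    """
    tf_to_gene: dict[str, set[str]] = {}
    tf_to_mirna: dict[str, set[str]] = {}
    mirna_to_gene: dict[str, set[str]] = {}
    for e in edges:
        if e.regulator_type == TF and e.target_type == GENE:
            tf_to_gene.setdefault(e.regulator_id, set()).add(e.target_id)
        elif e.regulator_type == TF and e.target_type == MIRNA:
            tf_to_mirna.setdefault(e.regulator_id, set()).add(e.target_id)
        elif e.regulator_type == MIRNA and e.target_type == GENE:
            mirna_to_gene.setdefault(e.regulator_id, set()).add(e.target_id)

    out: list[FFL] = []
    for tf_id, tf_genes in tf_to_gene.items():
        for mirna_id, mi_genes in mirna_to_gene.items():
            if tf_id == mirna_id:
                continue
            tf_regulates_mirna = mirna_id in tf_to_mirna.get(tf_id, ())
            mirna_regulates_tf = tf_id in mi_genes and tf_id in tf_roster
            if not (tf_regulates_mirna or mirna_regulates_tf):
                continue
            if tf_regulates_mirna and mirna_regulates_tf:
                cls = COMPOSITE_FFL
            elif tf_regulates_mirna:
                cls = TF_FFL
            else:
                cls = MIRNA_FFL
            for gene in tf_genes & mi_genes:
                if gene in (tf_id, mirna_id):
                    continue
                out.append(FFL(cls, tf_id, mirna_id, gene))
    out.sort()
    return out


def count_by_class(ffls: Iterable[FFL]) -> dict[str, int]:
    counts = {cls: 0 for cls in FFL_CLASSES}
    for f in ffls:
        counts[f.ffl_class] += 1
    return counts


def common_ffls(a: Iterable[FFL], b: Iterable[FFL]) -> list[FFL]:
    """Intersection of two FFL lists by (class, tf, mirna, gene) identity."""
    return sorted(set(a) & set(b))


def ffl_feature_ids(ffls: Iterable[FFL]) -> list[str]:
    """All distinct gene/TF/miRNA ids participating in a set of FFLs."""
    ids: set[str] = set()
    for f in ffls:
        ids.update((f.tf_id, f.mirna_id, f.target_gene_id))
    return sorted(ids)


def write_ffls(ffls: Iterable[FFL], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "ffl_class": f.ffl_class,
                "tf_id": f.tf_id,
                "mirna_id": f.mirna_id,
                "target_gene_id": f.target_gene_id,
            }
            for f in sorted(set(ffls))
        ],
        columns=["ffl_class", "tf_id", "mirna_id", "target_gene_id"],
    ).to_csv(path, sep="\t", index=False)


def load_ffls(path) -> list[FFL]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return sorted(
        FFL(r.ffl_class, r.tf_id, r.mirna_id, r.target_gene_id)
        for r in df.itertuples(index=False)
    )
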