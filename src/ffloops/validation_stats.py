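"""Statistical validation of identified edges and reconstructed FFLs.

Four procedures:

* permutation false-discovery-rate for any edge-identification procedure —
  expression values of every feature are shuffled independently across
  samples, destroying regulator/target covariation while preserving marginal
  distributions; FDR = mean discoveries on permuted data / discoveries on
  real data, repeated and averaged;
* a random-interaction null for FFL counts — the same number of edges per
  interaction type is drawn uniformly from the prior pool, FFLs re-enumerated,
  and the observed count per class scored one-sided against the empirical null
  via its studentized excess (observed minus null mean, in units of the null
  draws' standard deviation) on a t tail with n_draws - 1 df;
* a Pearson-correlation shift test (Mann-Whitney U, one-sided) comparing
  |PCC| of regulator/target pairs before vs after selection;
* hypergeometric enrichment of known (experimentally validated) interactions
  among selected edges, and a 2x2 Pearson chi-square without continuity
  correction for count-composition comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .data_io import Edge, ExpressionMatrix, ParallelDataset, PriorCatalog, TFRoster
from .ffl_builder import FFL_CLASSES, count_by_class, enumerate_ffls

logger = logging.getLogger(__name__)


@dataclass
class FDRReport:
    fdr_mean: float
    fdr_variance: float
    n_permutations: int
    n_repeats: int
    per_repeat_fdr: list[float]
    n_real_discoveries: int


@dataclass
class NullFFLReport:
    observed_counts: dict[str, int]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    t_pvalue: dict[str, float]
    n_draws: int


def permute_expression(matrix: ExpressionMatrix, rng: np.random.Generator) -> ExpressionMatrix:
    """Shuffle each feature's values independently across samples."""
    vals = matrix.values.copy()
    for i in range(vals.shape[0]):
        rng.shuffle(vals[i])
    import pandas as pd

    return ExpressionMatrix(
        data=pd.DataFrame(vals, index=matrix.feature_ids, columns=matrix.sample_ids),
        feature_type=matrix.feature_type,
    )


def permute_dataset(dataset: ParallelDataset, rng: np.random.Generator) -> ParallelDataset:
    return ParallelDataset(
        mrna=permute_expression(dataset.mrna, rng),
        mirna=permute_expression(dataset.mirna, rng),
        labels=dataset.labels,
    )


def estimate_fdr(
    identify: Callable[[ParallelDataset], Iterable[Edge]],
    dataset: ParallelDataset,
    n_perm: int = 100,
    n_repeat: int = 3,
    seed: int | None = None,
) -> FDRReport:
    """Permutation FDR of an edge-identification procedure.

    Per repeat: run ``identify`` on ``n_perm`` independently permuted copies
    of the dataset; FDR = (mean permuted discovery count) / (real discovery
    count). The report carries the mean and variance over repeats.
    """
    if n_perm < 1 or n_repeat < 1:
        raise ValueError("n_perm and n_repeat must be >= 1")
    real = set(identify(dataset))
    if not real:
        raise ValueError("undefined FDR: zero discoveries on the real dataset")
    rng = np.random.default_rng(seed)
    per_repeat: list[float] = []
    for _ in range(n_repeat):
        counts = []
        for _ in range(n_perm):
            permuted = permute_dataset(dataset, rng)
            counts.append(len(set(identify(permuted))))
        per_repeat.append(float(np.mean(counts)) / len(real))
    arr = np.asarray(per_repeat)
    return FDRReport(
        fdr_mean=float(arr.mean()),
        fdr_variance=float(arr.var(ddof=1)) if n_repeat > 1 else 0.0,
        n_permutations=n_perm,
        n_repeats=n_repeat,
        per_repeat_fdr=per_repeat,
        n_real_discoveries=len(real),
    )


def null_ffl_test(
    observed: Mapping[str, int],
    priors: PriorCatalog,
    identified_sizes: Mapping[tuple[str, str], int],
    tf_roster: TFRoster,
    n_draws: int = 1000,
    seed: int | None = None,
) -> NullFFLReport:
    """Random-interaction null for FFL counts.

    ``identified_sizes`` maps each (regulator_type, target_type) pair to the
    number of identified edges of that type; every draw samples that many prior
    edges of the type uniformly without replacement, enumerates FFLs and counts
    per class. Per class the observed count is tested one-sided against the
    null draws: t = (observed - null mean) / null sd, p = upper t tail with
    n_draws - 1 df, so a typical null draw scores p around 0.5 and the test is
    calibrated against the spread of a single draw.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    pools = {
        pair: priors.edges_of_type(*pair) for pair in identified_sizes
    }
    for pair, k in identified_sizes.items():
        if k > len(pools[pair]):
            raise ValueError(
                f"cannot draw {k} edges of type {pair}: pool has {len(pools[pair])}"
            )
    rng = np.random.default_rng(seed)
    counts = {cls: np.empty(n_draws) for cls in FFL_CLASSES}
    for d in range(n_draws):
        sampled: list[Edge] = []
        for pair, k in identified_sizes.items():
            pool = pools[pair]
            idx = rng.choice(len(pool), size=k, replace=False)
            sampled.extend(pool[i] for i in idx)
        c = count_by_class(enumerate_ffls(sampled, tf_roster))
        for cls in FFL_CLASSES:
            counts[cls][d] = c[cls]
    report = NullFFLReport(
        observed_counts={cls: int(observed.get(cls, 0)) for cls in FFL_CLASSES},
        null_mean={}, null_sd={}, t_pvalue={}, n_draws=n_draws,
    )
    for cls in FFL_CLASSES:
        draws = counts[cls]
        mean, sd = float(draws.mean()), float(draws.std(ddof=1))
        report.null_mean[cls] = mean
        report.null_sd[cls] = sd
        obs = report.observed_counts[cls]
        if sd == 0:  # constant null draws: degenerate but decidable
            p = 0.0 if obs > mean else 1.0
        else:
            p = float(stats.t.sf((obs - mean) / sd, df=n_draws - 1))
        report.t_pvalue[cls] = p
    return report


def pcc_shift_test(
    pairs_before: Sequence[tuple[np.ndarray, np.ndarray]],
    pairs_after: Sequence[tuple[np.ndarray, np.ndarray]],
) -> tuple[list[float], list[float], float]:
    """|PCC| per regulator/target pair, before vs after selection.

    Returns both |PCC| samples and the one-sided Mann-Whitney U p-value for
    the 'after' sample being stochastically greater. Constant profiles give a
    PCC of 0 with a warning.
    """
    def abs_pcc(pairs):
        out = []
        for reg, tgt in pairs:
            reg = np.asarray(reg, dtype=float)
            tgt = np.asarray(tgt, dtype=float)
            if reg.size != tgt.size or reg.size < 3:
                raise ValueError("pair profiles must share length >= 3")
            if reg.std() == 0 or tgt.std() == 0:
                logger.warning("constant profile in pair; PCC set to 0")
                out.append(0.0)
            else:
                out.append(abs(float(stats.pearsonr(reg, tgt)[0])))
        return out

    if not pairs_before or not pairs_after:
        raise ValueError("both pair lists must be non-empty")
    before = abs_pcc(pairs_before)
    after = abs_pcc(pairs_after)
    u = stats.mannwhitneyu(after, before, alternative="greater")
    return before, after, float(u.pvalue)


def known_interaction_enrichment(
    selected: Iterable[Edge], known: Iterable[Edge], universe: Iterable[Edge]
) -> tuple[float, float, float]:
    """Hypergeometric enrichment of known interactions among selected edges.

    Returns (fraction known among selected, fraction known in universe,
    one-sided upper-tail hypergeometric p-value for the overlap).
    """
    universe_set = set(universe)
    selected_set = set(selected)
    if not selected_set:
        raise ValueError("selected edge set is empty")
    if not selected_set <= universe_set:
        raise ValueError("selected edges must be a subset of the universe")
    known_in_universe = set(known) & universe_set
    N, K, n = len(universe_set), len(known_in_universe), len(selected_set)
    k = len(selected_set & known_in_universe)
    # P(X >= k) for X ~ Hypergeom(N, K, n)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k / n, K / N, p


def chi_square_2x2(a_pos: int, a_tot: int, b_pos: int, b_tot: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df=1, no continuity correction.

    Compares proportions a_pos/a_tot vs b_pos/b_tot; returns (chi2, p).
    """
    if not (a_tot >= a_pos >= 0 and b_tot >= b_pos >= 0) or a_tot == 0 or b_tot == 0:
        raise ValueError("invalid 2x2 counts")
    table = np.array([[a_pos, a_tot - a_pos], [b_pos, b_tot - b_pos]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
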