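"""Filter feature selection: mutual information and mRMR candidate ranking.

For every target the predicted regulators are ranked greedily by the
minimum-redundancy-maximum-relevance criterion, I(candidate; target) minus the
mean mutual information with the already-selected set, and up to 20 top
candidates are retained for the downstream regression wrapper. Expression
profiles are discretized per feature before estimating mutual information
(3-state mean +/- k*sigma by default, equal-frequency bins as an alternative),
and all information quantities are in bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

DEFAULT_MAX_KEEP = 20


@dataclass(frozen=True)
class DiscretizationScheme:
    """How a continuous expression profile is mapped to discrete states."""

    method: str = "mean_sd_3state"
    n_bins: int = 3
    sd_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in ("mean_sd_3state", "equal_frequency"):
            raise ValueError(f"unknown discretization method {self.method!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.sd_factor <= 0:
            raise ValueError("sd_factor must be > 0")


@dataclass
class CandidateRanking:
    """mRMR ranking of a target's candidate regulators.

    ``ranked`` lists (regulator_id, relevance_MI, mrmr_score) in selection
    order; ``selected`` is the retained prefix of regulator ids.
    """

    target_id: str
    ranked: list[tuple[str, float, float]] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)


def discretize(values: np.ndarray, scheme: DiscretizationScheme) -> np.ndarray:
    """Map a real vector to integer states under ``scheme``.

    mean_sd_3state: below mean - k*sd -> 0, within -> 1, above mean + k*sd -> 2.
    equal_frequency: n_bins quantile bins assigned by stable rank order, so ties
    are split deterministically and bins are as equal as n allows.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to discretize")
    if scheme.method == "mean_sd_3state":
        mu = values.mean()
        sd = values.std()
        lo, hi = mu - scheme.sd_factor * sd, mu + scheme.sd_factor * sd
        states = np.ones(values.size, dtype=np.int64)
        states[values < lo] = 0
        states[values > hi] = 2
        return states
    # equal_frequency: rank via stable argsort, then split ranks into bins
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=np.int64)
    ranks[order] = np.arange(values.size)
    return (ranks * scheme.n_bins) // values.size


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information in bits between two discrete state vectors.

    I(X;Y) = sum_{x,y} p(x,y) log2[ p(x,y) / (p(x) p(y)) ] over observed joint
    frequencies, with 0*log(0) = 0; the result is clipped at 0 against rounding.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log2(pxy / (px * py))
    return max(0.0, float(np.nansum(terms)))


def entropy(x: np.ndarray) -> float:
    """Empirical Shannon entropy of a state vector, in bits."""
    _, counts = np.unique(np.asarray(x), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def rank_mrmr(
    target_profile: np.ndarray,
    candidate_profiles: Mapping[str, np.ndarray],
    scheme: DiscretizationScheme = DiscretizationScheme(),
    max_keep: int = DEFAULT_MAX_KEEP,
    target_id: str = "",
) -> CandidateRanking:
    """Greedy mRMR ranking of candidate regulators against a target profile.

    The first pick maximizes relevance I(candidate; target); each later pick
    maximizes relevance minus the mean MI with the already-selected set. Ties
    break lexicographically on regulator id. Selection stops at
    min(max_keep, #candidates).
    """
    if not candidate_profiles:
        raise ValueError("no candidate regulators supplied")
    t = discretize(target_profile, scheme)
    ids = sorted(candidate_profiles)
    disc = {cid: discretize(candidate_profiles[cid], scheme) for cid in ids}
    relevance = {cid: mutual_information(disc[cid], t) for cid in ids}

    selected: list[str] = []
    ranked: list[tuple[str, float, float]] = []
    remaining = list(ids)
    redundancy_sum = {cid: 0.0 for cid in ids}  # sum of MI with selected set
    n_keep = min(max_keep, len(ids))
    while len(selected) < n_keep:
        best_id, best_score = None, -np.inf
        for cid in remaining:  # remaining stays sorted -> lexicographic ties
            if selected:
                score = relevance[cid] - redundancy_sum[cid] / len(selected)
            else:
                score = relevance[cid]
            if score > best_score:
                best_id, best_score = cid, score
        assert best_id is not None
        ranked.append((best_id, relevance[best_id], best_score))
        selected.append(best_id)
        remaining.remove(best_id)
        for cid in remaining:
            redundancy_sum[cid] += mutual_information(disc[cid], disc[best_id])
    return CandidateRanking(target_id=target_id, ranked=ranked, selected=selected)
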