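"""Wrapper feature selection: backward elimination over multiple linear OLS.

Each target's expression is modeled as a linear combination of its candidate
regulators' expression plus Gaussian noise. Starting from the mRMR-filtered
candidate set, the regulator with the smallest absolute standardized
coefficient is removed one step at a time until a single-regulator model has
been evaluated; the accepted model is the evaluated subset with the smallest
overall F-test p-value, provided that p-value is below alpha (default 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .data_io import Edge, ParallelDataset, PriorCatalog
from .filter_mrmr import DiscretizationScheme, rank_mrmr, DEFAULT_MAX_KEEP

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01


@dataclass
class RegressionFit:
    """OLS fit of one target on a regulator set, on the standardized scale."""

    target_id: str
    regulator_ids: list[str]
    beta: np.ndarray
    intercept: float
    residual_variance: float
    f_pvalue: float
    n_samples: int
    df_model: int
    df_resid: int


@dataclass
class EliminationStep:
    regulator_set: tuple[str, ...]
    f_pvalue: float
    eliminated_regulator: str | None  # regulator removed after this step


@dataclass
class EliminationPath:
    """The full record of a backward-elimination run for one target."""

    steps: list[EliminationStep]
    optimal_step_index: int
    accepted: bool

    @property
    def optimal_step(self) -> EliminationStep:
        return self.steps[self.optimal_step_index]

    @property
    def selected(self) -> tuple[str, ...]:
        return self.optimal_step.regulator_set if self.accepted else ()


@dataclass
class TargetSelection:
    """Identified edges for one target, or the reason none were identified."""

    target_id: str
    edges: list[Edge] = field(default_factory=list)
    stats: dict[Edge, dict] = field(default_factory=dict)
    reason: str = "ok"
    n_unmeasured_candidates: int = 0
    path: EliminationPath | None = None


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v, dtype=float)
    return (v - v.mean()) / sd


def fit_linear(
    target: np.ndarray, regulators: Mapping[str, np.ndarray], target_id: str = ""
) -> RegressionFit:
    """OLS of a target on its regulators, both z-scored before fitting.

    The reported p-value is from the overall model F statistic against the
    intercept-only model with df = (p, n - p - 1). Exactly duplicated
    regulator columns are dropped (keeping the lexicographically first id)
    before fitting.
    """
    if not regulators:
        raise ValueError("at least one regulator required")
    y = _zscore(np.asarray(target, dtype=float))
    n = y.size
    ids = sorted(regulators)
    cols = {rid: _zscore(np.asarray(regulators[rid], dtype=float)) for rid in ids}
    if any(c.size != n for c in cols.values()):
        raise ValueError("regulator/target length mismatch")
    # drop exactly collinear duplicates
    kept: list[str] = []
    for rid in ids:
        if any(np.allclose(cols[rid], cols[k]) for k in kept):
            logger.warning("dropping duplicate regulator column %s", rid)
            continue
        kept.append(rid)
    p = len(kept)
    if p >= n - 1:
        raise ValueError(f"{p} regulators with {n} samples: caller must pre-truncate")
    X = np.column_stack([np.ones(n)] + [cols[rid] for rid in kept])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df_model, df_resid = p, n - p - 1
    if tss == 0:
        f_pvalue = 1.0
    else:
        ess = tss - rss
        if rss <= 1e-12 * tss:
            f_pvalue = 0.0
        else:
            f_stat = (ess / df_model) / (rss / df_resid)
            f_pvalue = float(stats.f.sf(f_stat, df_model, df_resid))
    return RegressionFit(
        target_id=target_id,
        regulator_ids=kept,
        beta=coef[1:],
        intercept=float(coef[0]),
        residual_variance=rss / df_resid if df_resid > 0 else float("nan"),
        f_pvalue=f_pvalue,
        n_samples=n,
        df_model=df_model,
        df_resid=df_resid,
    )


def backward_eliminate(
    target: np.ndarray,
    regulators: Mapping[str, np.ndarray],
    alpha: float = DEFAULT_ALPHA,
    target_id: str = "",
) -> EliminationPath:
    """Recursive backward elimination, keeping the best F-test model.

    At each step the current set is fit, then the regulator with the smallest
    |standardized beta| (ties: lexicographically first id) is removed; the path
    ends after the one-regulator model. The optimal step minimizes the F-test
    p-value (ties: the earlier, larger set); it is accepted iff p < alpha.
    """
    current = dict(regulators)
    if not current:
        raise ValueError("at least one regulator required")
    steps: list[EliminationStep] = []
    while current:
        fit = fit_linear(target, current, target_id=target_id)
        # collinear duplicates dropped inside fit_linear leave the path too
        current = {rid: current[rid] for rid in fit.regulator_ids}
        if len(fit.regulator_ids) > 1:
            order = sorted(
                zip(np.abs(fit.beta), fit.regulator_ids), key=lambda t: (t[0], t[1])
            )
            eliminated = order[0][1]
        else:
            eliminated = None
        steps.append(
            EliminationStep(
                regulator_set=tuple(fit.regulator_ids),
                f_pvalue=fit.f_pvalue,
                eliminated_regulator=eliminated,
            )
        )
        if eliminated is None:
            break
        current.pop(eliminated)
    pvals = [s.f_pvalue for s in steps]
    optimal = int(np.argmin(pvals))  # argmin takes the first = largest set on ties
    return EliminationPath(
        steps=steps, optimal_step_index=optimal, accepted=pvals[optimal] < alpha
    )


def select_regulators_for_target(
    target_id: str,
    dataset: ParallelDataset,
    priors: PriorCatalog,
    scheme: DiscretizationScheme = DiscretizationScheme(),
    alpha: float = DEFAULT_ALPHA,
    max_candidates: int = DEFAULT_MAX_KEEP,
    mrmr: bool = True,
    wrapper: bool = True,
) -> TargetSelection:
    """Filter (mRMR) then wrap (backward elimination) one target's candidates.

    Prior regulators without an expression profile are silently excluded and
    counted. ``mrmr=False`` skips the filter (all measured candidates go to the
    wrapper, truncated for OLS identifiability); ``wrapper=False`` returns the
    filter's selected set directly — used for method comparisons.
    """
    target_profile = dataset.profile(target_id)
    if target_profile is None:
        return TargetSelection(target_id=target_id, reason="target_not_measured")
    prior_edges = {e.regulator_id: e for e in priors.regulators_of(target_id)}
    if not prior_edges:
        return TargetSelection(target_id=target_id, reason="no_prior_regulators")
    profiles: dict[str, np.ndarray] = {}
    n_unmeasured = 0
    for rid in prior_edges:
        prof = dataset.profile(rid)
        if prof is None:
            n_unmeasured += 1
        else:
            profiles[rid] = prof
    if not profiles:
        return TargetSelection(
            target_id=target_id, reason="no_candidates",
            n_unmeasured_candidates=n_unmeasured,
        )
    if mrmr:
        ranking = rank_mrmr(
            target_profile, profiles, scheme=scheme, max_keep=max_candidates,
            target_id=target_id,
        )
        kept = list(ranking.selected)
    else:
        kept = sorted(profiles)
    # OLS identifiability: never offer the wrapper more than n - 3 regulators
    limit = dataset.n_samples - 3
    if len(kept) > limit:
        kept = kept[:limit]
    if not wrapper:
        edges = [prior_edges[rid] for rid in kept]
        return TargetSelection(
            target_id=target_id, edges=sorted(edges),
            stats={e: {} for e in edges},
            n_unmeasured_candidates=n_unmeasured,
        )
    path = backward_eliminate(
        target_profile, {rid: profiles[rid] for rid in kept}, alpha=alpha,
        target_id=target_id,
    )
    sel = TargetSelection(
        target_id=target_id, n_unmeasured_candidates=n_unmeasured, path=path
    )
    if not path.accepted:
        sel.reason = "not_significant"
        return sel
    fit = fit_linear(
        target_profile, {rid: profiles[rid] for rid in path.selected},
        target_id=target_id,
    )
    betas = dict(zip(fit.regulator_ids, fit.beta))
    for rid in path.selected:
        e = prior_edges[rid]
        sel.edges.append(e)
        sel.stats[e] = {
            "beta": float(betas[rid]),
            "beta_sign": int(np.sign(betas[rid])),
            "f_pvalue": fit.f_pvalue,
        }
    sel.edges.sort()
    return sel


def identify_edges(
    dataset: ParallelDataset,
    priors: PriorCatalog,
    scheme: DiscretizationScheme = DiscretizationScheme(),
    alpha: float = DEFAULT_ALPHA,
    max_candidates: int = DEFAULT_MAX_KEEP,
    mrmr: bool = True,
    wrapper: bool = True,
) -> dict[str, TargetSelection]:
    """Run per-target selection over every target in the prior catalog."""
    return {
        tid: select_regulators_for_target(
            tid, dataset, priors, scheme=scheme, alpha=alpha,
            max_candidates=max_candidates, mrmr=mrmr, wrapper=wrapper,
        )
        for tid in priors.targets()
    }


def identified_edge_set(selections: Mapping[str, TargetSelection]) -> frozenset[Edge]:
    """Union of identified edges across targets."""
    out: set[Edge] = set()
    for sel in selections.values():
        out.update(sel.edges)
    return frozenset(out)
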