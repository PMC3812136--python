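import math

import numpy as np
import pytest

from ffloops.data_io import Edge, PriorCatalog, TFRoster
from ffloops.ffl_builder import TF_FFL, count_by_class, enumerate_ffls
from ffloops.validation_stats import (
    chi_square_2x2,
    estimate_fdr,
    known_interaction_enrichment,
    null_ffl_test,
    pcc_shift_test,
    permute_expression,
)


class TestEstimateFdr:
    def test_constant_procedure_has_fdr_one(self, default_sim):
        dataset, _, _, _ = default_sim
        fixed = {Edge("TF", "TF001", "gene", "G001")}
        report = estimate_fdr(lambda ds: fixed, dataset, n_perm=3, n_repeat=2, seed=0)
        assert report.fdr_mean == 1.0

    def test_procedure_silent_on_permuted_data_has_fdr_zero(self, default_sim):
        dataset, _, _, _ = default_sim
        marker = dataset.mrna.profile("TF001").tolist()

        def identify(ds):
            # recognizes the real (unpermuted) dataset only
            if ds.mrna.profile("TF001").tolist() == marker:
                return {Edge("TF", "TF001", "gene", "G001")}
            return set()

        report = estimate_fdr(identify, dataset, n_perm=5, n_repeat=2, seed=0)
        assert report.fdr_mean == 0.0

    def test_zero_real_discoveries_raise(self, default_sim):
        dataset, _, _, _ = default_sim
        with pytest.raises(ValueError, match="undefined FDR"):
            estimate_fdr(lambda ds: set(), dataset, n_perm=2, n_repeat=1)

    def test_permutation_preserves_marginals(self, default_sim, rng):
        dataset, _, _, _ = default_sim
        permuted = permute_expression(dataset.mrna, rng)
        np.testing.assert_allclose(
            np.sort(permuted.values, axis=1), np.sort(dataset.mrna.values, axis=1)
        )


def triangle_priors(n_ffls=10, n_extra=60, seed=0):
    """Priors whose first edges tile disjoint TF-FFL triangles plus decoys."""
    rng = np.random.default_rng(seed)
    edges, triangles = [], []
    for i in range(n_ffls):
        t, m, g = f"T{i}", f"M{i}", f"G{i}"
        tri = [
            Edge("TF", t, "miRNA", m),
            Edge("TF", t, "gene", g),
            Edge("miRNA", m, "gene", g),
        ]
        edges += tri
        triangles += tri
    genes = [f"X{i}" for i in range(40)]
    seen = {(e.regulator_id, e.target_id) for e in edges}
    while n_extra > 0:
        t = f"T{rng.integers(n_ffls)}"
        m = f"M{rng.integers(n_ffls)}"
        g = genes[rng.integers(len(genes))]
        kind = rng.integers(3)
        e = [Edge("TF", t, "gene", g), Edge("miRNA", m, "gene", g),
             Edge("TF", t, "miRNA", f"MX{rng.integers(30)}")][kind]
        if (e.regulator_id, e.target_id) not in seen:
            seen.add((e.regulator_id, e.target_id))
            edges.append(e)
            n_extra -= 1
    roster = TFRoster(frozenset(f"T{i}" for i in range(n_ffls)))
    return PriorCatalog(frozenset(edges)), triangles, roster


class TestNullFflTest:
    def test_observed_at_null_mean_gives_half(self):
        priors, _, roster = triangle_priors()
        sizes = {("TF", "gene"): 8, ("TF", "miRNA"): 8, ("miRNA", "gene"): 8}
        report = null_ffl_test({}, priors, sizes, roster, n_draws=200, seed=1)
        centered = dict(report.observed_counts)
        centered[TF_FFL] = round(report.null_mean[TF_FFL])
        report2 = null_ffl_test(centered, priors, sizes, roster, n_draws=200, seed=1)
        assert 0.2 < report2.t_pvalue[TF_FFL] < 0.8

    def test_enriched_observation_rejects(self):
        priors, triangles, roster = triangle_priors()
        observed = count_by_class(enumerate_ffls(triangles, roster))
        sizes = {
            ("TF", "gene"): 10, ("TF", "miRNA"): 10, ("miRNA", "gene"): 10,
        }
        report = null_ffl_test(observed, priors, sizes, roster, n_draws=300, seed=2)
        assert report.t_pvalue[TF_FFL] < 0.01

    def test_single_draw_raises(self):
        priors, _, roster = triangle_priors()
        with pytest.raises(ValueError):
            null_ffl_test({}, priors, {("TF", "gene"): 1}, roster, n_draws=1)

    def test_oversized_request_raises(self):
        priors, _, roster = triangle_priors()
        with pytest.raises(ValueError):
            null_ffl_test({}, priors, {("TF", "gene"): 10 ** 6}, roster, n_draws=5)


class TestPccShiftTest:
    def test_identical_lists_no_shift(self, rng):
        pairs = [(rng.standard_normal(20), rng.standard_normal(20)) for _ in range(15)]
        _, _, p = pcc_shift_test(pairs, list(pairs))
        assert 0.3 < p < 0.7

    def test_separated_distributions(self, rng):
        before = [(rng.standard_normal(30), rng.standard_normal(30)) for _ in range(50)]
        after = []
        for _ in range(50):
            x = rng.standard_normal(30)
            after.append((x, x + 0.05 * rng.standard_normal(30)))
        _, _, p = pcc_shift_test(before, after)
        assert p < 1e-6

    def test_constant_profile_scores_zero(self, rng):
        pairs = [(np.ones(10), rng.standard_normal(10))]
        before, after, _ = pcc_shift_test(pairs, [(rng.standard_normal(10),) * 2])
        assert before == [0.0]

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            pcc_shift_test([], [(np.arange(5.0), np.arange(5.0))])


class TestKnownInteractionEnrichment:
    @staticmethod
    def edges(prefix, n):
        return [Edge("miRNA", f"m{prefix}{i}", "gene", f"g{prefix}{i}") for i in range(n)]

    def test_matches_hypergeometric_tail_sum(self):
        universe = self.edges("u", 100)
        known = universe[:10]
        selected = universe[5:25]  # overlap 5
        _, _, p = known_interaction_enrichment(selected, known, universe)
        oracle = sum(
            math.comb(10, k) * math.comb(90, 20 - k) / math.comb(100, 20)
            for k in range(5, 11)
        )
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_known_equals_universe_gives_one(self):
        universe = self.edges("u", 30)
        frac_sel, frac_uni, p = known_interaction_enrichment(universe[:10], universe, universe)
        assert frac_sel == 1.0 and frac_uni == 1.0 and p == pytest.approx(1.0)

    def test_zero_overlap_with_expectation_near_one(self):
        universe = self.edges("u", 100)
        known = universe[:50]
        selected = universe[60:80]
        _, _, p = known_interaction_enrichment(selected, known, universe)
        assert p > 0.999

    def test_empty_selected_raises(self):
        universe = self.edges("u", 10)
        with pytest.raises(ValueError):
            known_interaction_enrichment([], universe[:2], universe)


class TestChiSquare2x2:
    def test_identical_proportions(self):
        chi2, p = chi_square_2x2(10, 100, 10, 100)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 10, 0, 10)

    def test_matches_monte_carlo_permutation_oracle(self):
        # permute the pooled positives across the two groups (margins fixed):
        # the group-A positive count is then hypergeometric; the table is
        # large enough for the asymptotic chi-square tail to hold
        a_pos, a_tot, b_pos, b_tot = 60, 160, 36, 180
        chi_obs, p = chi_square_2x2(a_pos, a_tot, b_pos, b_tot)
        rng = np.random.default_rng(3)
        n_mc = 50_000
        pos, neg = a_pos + b_pos, (a_tot - a_pos) + (b_tot - b_pos)
        a = rng.hypergeometric(pos, neg, a_tot, size=n_mc).astype(float)

        def chi2_stat(a11):
            table = np.stack(
                [a11, a_tot - a11, pos - a11, b_tot - (pos - a11)], axis=-1
            )
            n = a_tot + b_tot
            exp = np.stack(
                [
                    a_tot * pos / n, a_tot * neg / n,
                    b_tot * pos / n, b_tot * neg / n,
                ],
                axis=-1,
            )
            return ((table - exp) ** 2 / exp).sum(axis=-1)

        p_mc = float((chi2_stat(a) >= chi_obs - 1e-12).mean())
        se = math.sqrt(p_mc * (1 - p_mc) / n_mc)
        assert abs(p - p_mc) <= 3 * se + 1e-9
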