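"""Running-sum enrichment score, permutation p-values, ORA, and BH correction."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from evcargo.config import EnrichmentConfig
from evcargo.enrichment import (
    EnrichmentError,
    bh_adjust,
    enrichment_score,
    gsea,
    ora,
    rank_genes,
)


def oracle_running_sum_es(ranked: pd.Series, members: set, p: float) -> float:
    """Step-by-step literal evaluation of the running-sum definition."""
    n = len(ranked)
    hits = [g in members for g in ranked.index]
    n_hit = sum(hits)
    nr = sum(abs(ranked.iloc[i]) ** p for i in range(n) if hits[i])
    total, best = 0.0, 0.0
    for i in range(n):
        if hits[i]:
            total += (abs(ranked.iloc[i]) ** p) / nr if nr > 0 else 1.0 / n_hit
        else:
            total -= 1.0 / (n - n_hit)
        # earliest-position tie-break, tolerant of float rounding of
        # mathematically equal deviations
        if abs(total) > abs(best) + 1e-12:
            best = total
    return best


def ranked_series(values, genes=None) -> pd.Series:
    genes = genes or [f"g{i}" for i in range(len(values))]
    return pd.Series(values, index=genes, dtype=float)


class TestRankGenes:
    def test_equal_means_give_zero_and_doubling_gives_one(self):
        values = pd.DataFrame(
            {"a1": [10.0, 40.0], "a2": [10.0, 40.0], "b1": [10.0, 20.0]},
            index=pd.Index(["gEq", "gUp"], name="gene"),
        )
        ranked = rank_genes(values, ["a1", "a2"], ["b1"], pseudocount=0.0)
        assert ranked["gEq"] == 0.0
        assert ranked["gUp"] == 1.0
        assert list(ranked.index) == ["gUp", "gEq"]  # descending order

    def test_hand_computed_ordering_with_tie_break(self):
        values = pd.DataFrame(
            {"a": [8.0, 2.0, 4.0, 4.0, 1.0], "b": [2.0, 8.0, 1.0, 1.0, 1.0]},
            index=pd.Index(["g3", "g4", "g2", "g1", "g0"], name="gene"),
        )
        ranked = rank_genes(values, ["a"], ["b"], pseudocount=0.0)
        # metrics: g3=2, g4=-2, g2=2, g1=2, g0=0; ties broken by gene id
        assert list(ranked.index) == ["g1", "g2", "g3", "g0", "g4"]

    def test_empty_group_rejected(self):
        values = pd.DataFrame({"a": [1.0]}, index=pd.Index(["g"], name="gene"))
        with pytest.raises(EnrichmentError):
            rank_genes(values, [], ["a"])


class TestEnrichmentScore:
    def test_full_list_set_scores_one(self):
        ranked = ranked_series([3.0, 2.0, 1.0, -1.0])
        assert enrichment_score(ranked, set(ranked.index)).es == pytest.approx(1.0)

    def test_single_top_gene_unweighted_scores_one(self):
        ranked = ranked_series([3.0, 2.0, 1.0, -1.0])
        assert enrichment_score(ranked, {"g0"}, p=0.0).es == pytest.approx(1.0)

    def test_disjoint_set_rejected(self):
        with pytest.raises(EnrichmentError):
            enrichment_score(ranked_series([1.0, 0.5]), {"absent"})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ranked = ranked_series(np.sort(rng.normal(0, 2, 10))[::-1])
        members = set(rng.choice(ranked.index, 3, replace=False))
        for p in (0.0, 1.0, 2.0):
            got = enrichment_score(ranked, members, p=p).es
            assert got == pytest.approx(oracle_running_sum_es(ranked, members, p))

    def test_magnitude_bounded_by_one(self):
        rng = np.random.default_rng(97)
        for _ in range(50):
            n = rng.integers(4, 30)
            ranked = ranked_series(np.sort(rng.normal(0, 3, n))[::-1])
            k = int(rng.integers(1, n))
            members = set(rng.choice(ranked.index, k, replace=False))
            assert abs(enrichment_score(ranked, members).es) <= 1.0 + 1e-12

    def test_leading_edge_contains_hits_up_to_peak(self):
        ranked = ranked_series([5.0, 4.0, 1.0, 0.5, -0.1, -4.0])
        res = enrichment_score(ranked, {"g0", "g1", "g5"})
        assert res.leading_edge == ["g0", "g1"]


class TestGseaPermutation:
    def test_exhaustive_p_equals_enumeration_oracle(self):
        """8-gene list, 3-gene set: all C(8,3)=56 placements enumerated."""
        rng = np.random.default_rng(7)
        ranked = ranked_series(np.sort(rng.normal(0, 2, 8))[::-1])
        members = {"g0", "g2", "g5"}
        obs = enrichment_score(ranked, members).es
        es_all = [
            oracle_running_sum_es(ranked, set(combo), 1.0)
            for combo in combinations(ranked.index, 3)
        ]
        assert len(es_all) == comb(8, 3)
        sign = 1 if obs >= 0 else -1
        same = [e for e in es_all if e * sign > 0]
        expected_p = sum(abs(e) >= abs(obs) - 1e-12 for e in same) / len(same)
        result = gsea(ranked, {"S": members}, EnrichmentConfig(seed=0), exhaustive=True)
        assert result.loc["S", "p_nominal"] == pytest.approx(expected_p)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(19)
        ranked = ranked_series(np.sort(rng.normal(0, 1, 40))[::-1])
        sets = {"A": set(ranked.index[:5]), "B": set(ranked.index[20:28])}
        cfg = EnrichmentConfig(n_permutations=200, seed=5)
        r1 = gsea(ranked, sets, cfg)
        r2 = gsea(ranked, sets, cfg)
        pd.testing.assert_frame_equal(r1, r2)

    def test_top_k_set_of_strong_metric_is_significant(self):
        metric = np.concatenate([np.linspace(5, 4, 5), np.linspace(1, -1, 45)])
        ranked = ranked_series(metric)
        result = gsea(
            ranked, {"top": set(ranked.index[:5])}, EnrichmentConfig(n_permutations=500, seed=2)
        )
        assert result.loc["top", "p_nominal"] < 0.05
        assert bool(result.loc["top", "significant"])

    def test_null_metric_calibration(self):
        """Under a null ranking the nominal p is uniform: the rejection rate at
        alpha=0.05 stays within 3 Monte-Carlo standard errors."""
        rng = np.random.default_rng(29)
        n_genes, n_sets, h = 300, 120, 15
        metric = rng.normal(0, 1, n_genes)
        ranked = ranked_series(np.sort(metric)[::-1])
        pvals = []
        for i in range(n_sets):
            members = set(rng.choice(ranked.index, h, replace=False))
            res = gsea(ranked, {"S": members},
                       EnrichmentConfig(n_permutations=400, seed=1000 + i))
            pvals.append(res.loc["S", "p_nominal"])
        alpha = 0.05
        frac = np.mean(np.array(pvals) < alpha)
        se = np.sqrt(alpha * (1 - alpha) / n_sets)
        assert abs(frac - alpha) <= 3 * se + 1e-9

    def test_phenotype_mode_requires_ranker(self):
        ranked = ranked_series([2.0, 1.0, -1.0])
        with pytest.raises(EnrichmentError, match="phenotype"):
            gsea(ranked, {"S": {"g0"}},
                 EnrichmentConfig(permutation_mode="phenotype", seed=0))


class TestOra:
    def test_fully_overlapping_half_universe(self):
        """universe 10, set 5, selected 5, overlap 5 -> p = 1/C(10,5)."""
        universe = {f"u{i}" for i in range(10)}
        members = {f"u{i}" for i in range(5)}
        result = ora(members, universe, {"S": members})
        assert result.loc["S", "p_value"] == pytest.approx(1 / comb(10, 5))

    def test_matches_enumeration_oracle_on_tiny_case(self):
        universe = [f"u{i}" for i in range(8)]
        members = set(universe[:4])
        selected = {universe[0], universe[1], universe[5]}
        k_obs = len(members & selected)
        total = hits = 0
        for draw in combinations(universe, len(selected)):
            total += 1
            hits += len(set(draw) & members) >= k_obs
        result = ora(selected, universe, {"S": members})
        assert result.loc["S", "p_value"] == pytest.approx(hits / total)

    def test_set_equal_to_universe_gives_p_one(self):
        universe = {f"u{i}" for i in range(6)}
        result = ora({"u0", "u1"}, universe, {"S": universe})
        assert result.loc["S", "p_value"] == pytest.approx(1.0)

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(EnrichmentError, match="universe"):
            ora({"x"}, {"a", "b"}, {"S": {"a"}})

    def test_overlap_bounded(self):
        rng = np.random.default_rng(3)
        universe = [f"u{i}" for i in range(40)]
        selected = set(rng.choice(universe, 12, replace=False))
        sets = {f"S{j}": set(rng.choice(universe, 8, replace=False)) for j in range(6)}
        result = ora(selected, universe, sets)
        assert (result["overlap"] <= np.minimum(result["set_size"], result["selected_size"])).all()
        assert result["fdr_q"].between(0, 1).all()


class TestBhAdjust:
    def test_single_p_is_unchanged(self):
        assert bh_adjust([0.04]).tolist() == [0.04]

    def test_step_up_arithmetic_oracle(self):
        # q_(i) = min_{j >= i} p_(j) * m / j: all three collapse to 0.03
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_stay_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_invalid_p_rejected(self):
        with pytest.raises(EnrichmentError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(51)
        for _ in range(10):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_adjust(p), q_ref)

    def test_monotone_in_order_statistics(self):
        rng = np.random.default_rng(53)
        p = rng.uniform(0, 1, 25)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()
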