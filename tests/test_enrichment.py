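import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirstrat.enrichment import (
    gene_statistics,
    ks_enrichment_score,
    ora_hypergeometric,
    permutation_test,
    run_target_enrichment,
)
from mirstrat.io import GeneSetCollection


def _scores(values, genes=None):
    genes = genes or [f"g{i:03d}" for i in range(len(values))]
    return pd.Series(np.asarray(values, dtype=float), index=genes)


class TestKSEnrichmentScore:
    def test_all_targets_first_gives_one(self):
        s = _scores([10, 9, 8, 3, 2, 1])
        assert ks_enrichment_score(s, {"g000", "g001", "g002"}) == pytest.approx(1.0)

    def test_perfectly_interleaved_four_and_four(self):
        # T N T N T N T N: running sum peaks at 1/|T| right after the first hit
        s = _scores([8, 7, 6, 5, 4, 3, 2, 1])
        targets = {"g000", "g002", "g004", "g006"}
        assert ks_enrichment_score(s, targets) == pytest.approx(1.0 / 4.0)

    def test_matches_cdf_difference_oracle(self, rng):
        # ES == sup_t (F_T(rank <= t) - F_N(rank <= t)) over all cut points
        for _ in range(50):
            n = int(rng.integers(8, 60))
            vals = rng.normal(size=n)
            genes = [f"g{i:03d}" for i in range(n)]
            s = _scores(vals, genes)
            n_t = int(rng.integers(1, n))
            targets = set(rng.choice(genes, size=n_t, replace=False))
            order = np.lexsort((np.array(genes), -vals))
            is_t = np.isin(np.array(genes)[order], list(targets))
            d_plus = max(
                is_t[: i + 1].sum() / n_t - (~is_t[: i + 1]).sum() / (n - n_t)
                for i in range(n)
            )
            assert ks_enrichment_score(s, targets) == pytest.approx(d_plus, abs=1e-12)

    def test_invariant_under_monotone_score_transform(self, rng):
        vals = rng.uniform(1.0, 5.0, size=40)
        s = _scores(vals)
        targets = set(s.index[rng.choice(40, size=10, replace=False)])
        assert ks_enrichment_score(s, targets) == pytest.approx(
            ks_enrichment_score(np.exp(s), targets), abs=1e-12
        )

    def test_rejects_empty_and_full_overlap(self):
        s = _scores([3, 2, 1])
        with pytest.raises(ValueError):
            ks_enrichment_score(s, {"absent"})
        with pytest.raises(ValueError):
            ks_enrichment_score(s, {"g000", "g001", "g002"})


class TestPermutationTest:
    def test_p_floor_reached_iff_obs_exceeds_all(self, rng):
        # targets occupy the top ranks: every permutation scores lower,
        # so p equals the floor exactly
        s = _scores(np.arange(200.0, 0.0, -1.0))
        targets = set(s.index[:20])
        res = permutation_test(s, targets, B=999, seed=5)
        assert res.es_observed == pytest.approx(1.0)
        assert res.p_empirical == pytest.approx(1.0 / 1000.0)

    def test_single_permutation_support(self, rng):
        # B=1: p is (0+1)/2 or (1+1)/2, nothing else
        s = _scores(rng.normal(size=30))
        targets = set(s.index[:6])
        seen = set()
        for seed in range(20):
            res = permutation_test(s, targets, B=1, seed=seed)
            seen.add(res.p_empirical)
            assert math.isnan(res.nes)
        assert seen <= {0.5, 1.0}

    def test_plus_one_smoothing_definition(self, rng):
        s = _scores(rng.normal(size=50))
        targets = set(s.index[rng.choice(50, size=10, replace=False)])
        res = permutation_test(s, targets, B=200, seed=3)
        exceed = int(np.count_nonzero(res.es_null >= res.es_observed))
        assert res.p_empirical == pytest.approx((exceed + 1) / 201)

    def test_null_p_values_uniform_and_nes_centred(self):
        # scores and targets independent: p ~ U on its grid, mean NES ~ 0
        ps, nes = [], []
        for seed in range(500):
            r = np.random.default_rng(seed)
            s = _scores(r.normal(size=60))
            targets = set(s.index[r.choice(60, size=12, replace=False)])
            res = permutation_test(s, targets, B=99, seed=seed + 10_000)
            ps.append(res.p_empirical)
            nes.append(res.nes)
        ps = np.asarray(ps)
        assert abs(ps.mean() - 0.5) < 0.05
        assert abs((ps < 0.25).mean() - 0.25) < 0.06
        assert abs(float(np.mean(nes))) < 0.1

    def test_nes_is_zscore_of_null(self, rng):
        s = _scores(rng.normal(size=80))
        targets = set(s.index[:15])
        res = permutation_test(s, targets, B=2000, seed=11)
        mu, sd = res.es_null.mean(), res.es_null.std(ddof=1)
        assert res.nes == pytest.approx((res.es_observed - mu) / sd)

    def test_determinism_and_chunking_equivalence(self, rng):
        # two calls with the same seed agree even across chunk boundaries
        s = _scores(rng.normal(size=5000))
        targets = set(s.index[rng.choice(5000, size=100, replace=False)])
        a = permutation_test(s, targets, B=1500, seed=7)
        b = permutation_test(s, targets, B=1500, seed=7)
        np.testing.assert_array_equal(a.es_null, b.es_null)
        assert a.p_empirical == b.p_empirical

    def test_rejects_nonpositive_b(self, rng):
        s = _scores(rng.normal(size=10))
        with pytest.raises(ValueError):
            permutation_test(s, {"g000"}, B=0)


class TestGeneStatistics:
    def test_association_and_magnitude_values(self):
        degs = pd.DataFrame(
            {"p": [0.01, 1.0, 1e-320], "logFC": [2.0, -3.0, 0.0]},
            index=["a", "b", "c"],
        )
        out = gene_statistics(degs)
        assert out.loc["a", "association"] == pytest.approx(2.0)
        assert out.loc["b", "association"] == pytest.approx(0.0)
        # association is floored so scores stay finite
        assert np.isfinite(out.loc["c", "association"])
        assert out.loc["a", "magnitude"] == pytest.approx(np.log10(4.0))
        assert out.loc["b", "magnitude"] == pytest.approx(np.log10(8.0))
        assert out.loc["c", "magnitude"] >= 0.0

    def test_magnitude_is_direction_blind(self):
        degs = pd.DataFrame({"p": [0.5, 0.5], "logFC": [1.7, -1.7]}, index=["u", "d"])
        out = gene_statistics(degs)
        assert out.loc["u", "magnitude"] == pytest.approx(out.loc["d", "magnitude"])


class TestRunTargetEnrichment:
    def test_duplicates_and_out_of_universe_targets_handled(self, deg_table):
        genes = list(deg_table.index[:30])
        a1, m1 = run_target_enrichment(deg_table, genes, B=50, seed=1)
        a2, m2 = run_target_enrichment(
            deg_table, genes + genes[:5] + ["NOT_A_GENE"], B=50, seed=1
        )
        assert a1.es_observed == a2.es_observed
        assert a1.p_empirical == a2.p_empirical
        assert a1.target_set_size == a2.target_set_size == 30
        assert m1.p_empirical == m2.p_empirical

    def test_target_order_does_not_matter(self, deg_table, rng):
        genes = list(deg_table.index[100:140])
        a1, _ = run_target_enrichment(deg_table, genes, B=50, seed=2)
        a2, _ = run_target_enrichment(deg_table, list(reversed(genes)), B=50, seed=2)
        assert a1.es_observed == a2.es_observed
        assert a1.p_empirical == a2.p_empirical

    def test_planted_targets_detected(self, cohort, deg_table):
        assoc, mag = run_target_enrichment(
            deg_table, cohort.target_genes, B=200, seed=0
        )
        assert assoc.p_empirical == pytest.approx(1.0 / 201.0)
        assert mag.p_empirical == pytest.approx(1.0 / 201.0)
        assert assoc.nes > 3

    def test_rejects_disjoint_targets(self, deg_table):
        with pytest.raises(ValueError):
            run_target_enrichment(deg_table, ["nope1", "nope2"], B=10)


class TestORAHypergeometric:
    def test_closed_form_top_five_of_twenty(self):
        # P(all 5 draws land in a 5-member set out of 20) = 1 / C(20,5) = 1/15504
        universe = {f"g{i}" for i in range(20)}
        hits = {f"g{i}" for i in range(5)}
        sets = GeneSetCollection(sets={"S": set(hits)}, descriptions={"S": ""})
        out = ora_hypergeometric(hits, sets, universe)
        assert out.loc["S", "p"] == pytest.approx(1.0 / 15504.0)
        assert out.loc["S", "overlap"] == 5
        assert bool(out.loc["S", "significant"])

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        sets = GeneSetCollection(sets={"S": {"g8", "g9"}}, descriptions={"S": ""})
        out = ora_hypergeometric({"g0", "g1"}, sets, universe)
        # any draw has overlap >= 0, so P(X >= 0) = 1
        assert out.loc["S", "p"] == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self, rng):
        # exhaustively enumerate draws in a universe of size <= 12
        universe = [f"g{i}" for i in range(10)]
        members = {"g1", "g3", "g4", "g7"}
        n_hits = 4
        hits = set(rng.choice(universe, size=n_hits, replace=False))
        obs = len(hits & members)
        count = sum(
            1
            for combo in itertools.combinations(universe, n_hits)
            if len(set(combo) & members) >= obs
        )
        expected = count / math.comb(10, n_hits)
        sets = GeneSetCollection(sets={"S": members}, descriptions={"S": ""})
        out = ora_hypergeometric(hits, sets, set(universe))
        assert out.loc["S", "p"] == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_fisher_exact(self, rng):
        universe = {f"g{i}" for i in range(200)}
        members = set(rng.choice(sorted(universe), size=40, replace=False))
        hits = set(rng.choice(sorted(universe), size=30, replace=False))
        overlap = len(hits & members)
        table = [
            [overlap, len(hits) - overlap],
            [len(members) - overlap, 200 - len(hits) - len(members) + overlap],
        ]
        _, p_fisher = stats.fisher_exact(table, alternative="greater")
        sets = GeneSetCollection(sets={"S": members}, descriptions={"S": ""})
        out = ora_hypergeometric(hits, sets, universe)
        assert out.loc["S", "p"] == pytest.approx(p_fisher, rel=1e-9)

    def test_sorted_by_p(self, rng):
        universe = {f"g{i}" for i in range(100)}
        hits = {f"g{i}" for i in range(10)}
        sets = GeneSetCollection(
            sets={
                "strong": {f"g{i}" for i in range(10)},
                "weak": {f"g{i}" for i in range(50, 60)},
                "mid": {f"g{i}" for i in range(5, 15)},
            },
            descriptions={},
        )
        out = ora_hypergeometric(hits, sets, universe)
        assert (out["p"].diff().dropna() >= 0).all()
        assert out.index[0] == "strong"
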