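"""Enrichment statistics against brute-force combinatorial oracles."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from methylcode.enrichment import (
    cpg_gene_correlation,
    enrichment_score,
    fisher_set_enrichment,
    interval_colocalization,
    link_probes_to_genes,
    ranked_set_enrichment,
    tissue_rank_context,
)
from methylcode.io import BetaMatrix, GenomicIntervalSet, ProbeManifest
from methylcode.simulate import manifest_for_probes, simulate_annotations


def hypergeom_tail_oracle(a, n_query, n_ann, n_universe):
    """P(X >= a) by exact integer summation of the hypergeometric pmf."""
    total = math.comb(n_universe, n_query)
    acc = 0
    for x in range(a, min(n_query, n_ann) + 1):
        acc += math.comb(n_ann, x) * math.comb(n_universe - n_ann, n_query - x)
    return acc / total


class TestFisher:
    def test_worked_2x2_example(self):
        universe = [f"p{i}" for i in range(100)]
        ann = set(universe[:20])
        query = set(universe[:8]) | set(universe[20:22])  # overlap 8 of 10
        res = fisher_set_enrichment(query, {"ann": ann}, universe)
        row = res.iloc[0]
        assert (row["a"], row["b"], row["c"], row["d"]) == (8, 2, 12, 78)
        assert row["odds_ratio"] == pytest.approx(26.0)
        assert row["log2_or"] == pytest.approx(np.log2(26), abs=1e-3)
        assert row["p_value"] == pytest.approx(
            hypergeom_tail_oracle(8, 10, 20, 100), abs=1e-12
        )

    def test_matches_summation_oracle_over_small_universes(self):
        rng = np.random.default_rng(0)
        for n_universe in (5, 10, 25, 60, 120, 200):
            universe = [f"p{i}" for i in range(n_universe)]
            for _ in range(8):
                nq = int(rng.integers(1, n_universe))
                na = int(rng.integers(1, n_universe))
                query = set(rng.choice(universe, nq, replace=False))
                ann = set(rng.choice(universe, na, replace=False))
                res = fisher_set_enrichment(query, {"ann": ann}, universe)
                a = int(res.iloc[0]["a"])
                expected = hypergeom_tail_oracle(a, nq, na, n_universe)
                assert res.iloc[0]["p_value"] == pytest.approx(expected, abs=1e-12)

    def test_annotation_equals_universe_degenerate(self):
        universe = [f"p{i}" for i in range(30)]
        res = fisher_set_enrichment(universe[:5], {"all": universe}, universe)
        assert res.iloc[0]["p_value"] == pytest.approx(1.0)
        assert res.iloc[0]["odds_ratio"] == 1.0  # degenerate margin convention

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_set_enrichment(["x"], {"a": ["p1"]}, ["p1", "p2"])

    def test_planted_odds_ratio_recovered(self):
        manifest = manifest_for_probes([f"cg{i:05d}" for i in range(4000)])
        theta = 4.0
        ors = []
        for seed in range(5):
            query, sets, _, gt = simulate_annotations(manifest, 3, theta, seed=seed)
            res = fisher_set_enrichment(query, sets, list(manifest.probe_ids))
            res = res.set_index("annotation")
            assert res.loc["set00", "a"] >= 20
            ors.append(res.loc["set00", "odds_ratio"])
            # null sets sit near OR = 1
            assert 0.6 < res.loc["set01", "odds_ratio"] < 1.6
        assert theta / 1.5 <= np.median(ors) <= theta * 1.5

    def test_null_enrichment_factor_gives_or_one(self):
        manifest = manifest_for_probes([f"cg{i:05d}" for i in range(3000)])
        ors = []
        for seed in range(8):
            query, sets, _, _ = simulate_annotations(manifest, 1, 1.0, seed=100 + seed)
            res = fisher_set_enrichment(query, sets, list(manifest.probe_ids))
            ors.append(res.iloc[0]["odds_ratio"])
        assert np.mean(ors) == pytest.approx(1.0, abs=0.15)


class TestIntervals:
    def test_expansion_arithmetic_and_clamp(self):
        ivs = GenomicIntervalSet(
            pd.DataFrame({"chrom": ["chr1"], "start": [6000], "end": [6001], "name": ["snp"]})
        )
        exp = ivs.expand(5000)
        assert (exp.table["start"].iloc[0], exp.table["end"].iloc[0]) == (1000, 11001)
        clamped = GenomicIntervalSet(
            pd.DataFrame({"chrom": ["chr1"], "start": [999], "end": [1000], "name": ["cpg"]})
        ).expand(5000)
        assert clamped.table["start"].iloc[0] == 0

    def test_expanded_cpg_and_snp_overlap(self):
        cpg = GenomicIntervalSet(
            pd.DataFrame({"chrom": ["chr1"], "start": [999], "end": [1000], "name": ["c1"]})
        )
        snp = GenomicIntervalSet(
            pd.DataFrame({"chrom": ["chr1"], "start": [6000], "end": [6001], "name": ["s1"]})
        )
        res = interval_colocalization(cpg, {"snp": snp}, cpg, expand_bp=5000)
        assert res.iloc[0]["a"] == 1
        res0 = interval_colocalization(cpg, {"snp": snp}, cpg, expand_bp=0)
        assert res0.iloc[0]["a"] == 0

    def test_chromosome_mismatch_is_loud(self):
        cpg = GenomicIntervalSet(
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2], "name": ["c1"]})
        )
        feat = GenomicIntervalSet(
            pd.DataFrame({"chrom": ["1"], "start": [0], "end": [2], "name": ["f"]})
        )
        with pytest.raises(ValueError, match="chr1"):
            interval_colocalization(cpg, {"f": feat}, cpg, expand_bp=0)

    def test_order_invariance_and_idempotent_sort(self):
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 10_000, 50)
        t = pd.DataFrame(
            {"chrom": "chr2", "start": starts, "end": starts + 100,
             "name": [f"iv{i}" for i in range(50)]}
        )
        ivs = GenomicIntervalSet(t)
        shuffled = GenomicIntervalSet(t.sample(frac=1, random_state=3))
        pd.testing.assert_frame_equal(
            ivs.sorted().table.reset_index(drop=True),
            shuffled.sorted().table.reset_index(drop=True),
        )
        pd.testing.assert_frame_equal(ivs.sorted().table, ivs.sorted().sorted().table)


class TestRankedSetEnrichment:
    def test_extreme_concentration_gives_es_one(self):
        ranked = [f"p{i}" for i in range(50)]
        res = ranked_set_enrichment(ranked, ranked[:5], n_permutations=50, seed=0)
        assert res.es == pytest.approx(1.0)
        assert res.p_value >= 1 / 51

    def test_uniform_spread_gives_small_es(self):
        n, q = 1000, 100
        ranked = [f"p{i}" for i in range(n)]
        query = ranked[::10][:q]
        es = enrichment_score(np.isin(np.arange(n), np.arange(0, n, 10)[:q]))
        assert abs(es) < 0.05

    def test_permutation_p_matches_exhaustive_enumeration(self):
        # N=10, |Q|=2: the exact null of |ES| over all 45 placements
        ranked = [f"p{i}" for i in range(10)]
        query = [ranked[0], ranked[4]]
        obs = None
        null = []
        for c in combinations(range(10), 2):
            is_hit = np.zeros(10, dtype=bool)
            is_hit[list(c)] = True
            null.append(abs(enrichment_score(is_hit)))
        is_obs = np.zeros(10, dtype=bool)
        is_obs[[0, 4]] = True
        obs = abs(enrichment_score(is_obs))
        exact_p = np.mean([v >= obs - 1e-12 for v in null])
        res = ranked_set_enrichment(ranked, query, n_permutations=4000, seed=3)
        se = np.sqrt(exact_p * (1 - exact_p) / 4000)
        assert res.p_value == pytest.approx(exact_p, abs=4 * se + 1e-3)

    def test_null_p_values_super_uniform(self):
        # small-scale version of the type-I calibration (the acceptance suite
        # runs the full 1000-repetition check)
        rng = np.random.default_rng(7)
        ranked = [f"p{i}" for i in range(200)]
        n_rep, hits = 200, 0
        for i in range(n_rep):
            query = list(rng.choice(ranked, 10, replace=False))
            res = ranked_set_enrichment(ranked, query, n_permutations=99, seed=int(rng.integers(2**31)))
            hits += res.p_value <= 0.05
        # binomial 99.9% upper bound around 0.05
        assert hits / n_rep <= 0.05 + 3.29 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_degenerate_query_sizes_rejected(self):
        ranked = ["a", "b", "c"]
        with pytest.raises(ValueError):
            ranked_set_enrichment(ranked, [], seed=0)
        with pytest.raises(ValueError):
            ranked_set_enrichment(ranked, ranked, seed=0)


def kruskal_oracle(groups):
    """Textbook H = 12/(n(n+1)) * sum n_i (rbar_i - rbar)^2 with tie correction."""
    from scipy.stats import rankdata

    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        m = len(g)
        rbar = ranks[start : start + m].mean()
        h += m * (rbar - (n + 1) / 2) ** 2
        start += m
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


class TestTissueRankContext:
    def test_ranks_and_midranks(self):
        bm = BetaMatrix(
            pd.DataFrame([[0.1, 0.5, 0.9, 0.5]], index=["cg1"],
                         columns=["s0", "s1", "s2", "s3"])
        )
        groups = pd.Series({"s0": "a", "s1": "b", "s2": "c", "s3": "b"})
        res = tissue_rank_context(bm, ["cg1"], groups)
        mr = res["mean_ranks"]
        assert mr.loc["cg1", "a"] == 1.0
        assert mr.loc["cg1", "b"] == 2.5  # midranks for the tie at 0.5
        assert mr.loc["cg1", "c"] == 4.0

    def test_h_statistic_matches_closed_form_oracle(self):
        # 3 tissues x 2 samples with planted ordering over many CpGs:
        # compare the pooled-distribution H to the hand-computed formula
        rng = np.random.default_rng(11)
        samples = [f"s{i}" for i in range(6)]
        groups = pd.Series(dict(zip(samples, ["a", "a", "b", "b", "c", "c"])))
        vals = np.column_stack([
            rng.uniform(0.0, 0.3, 40), rng.uniform(0.0, 0.3, 40),
            rng.uniform(0.3, 0.6, 40), rng.uniform(0.3, 0.6, 40),
            rng.uniform(0.6, 0.9, 40), rng.uniform(0.6, 0.9, 40),
        ])
        bm = BetaMatrix(pd.DataFrame(vals, index=[f"cg{i}" for i in range(40)],
                                     columns=samples))
        res = tissue_rank_context(bm, [f"cg{i}" for i in range(40)], groups)
        dists = [res["mean_ranks"][t].to_numpy() for t in ["a", "b", "c"]]
        assert res["kruskal_h"] == pytest.approx(kruskal_oracle(dists), rel=1e-6)
        assert res["kruskal_p"] < 1e-6
        dunn = res["dunn"].set_index(["group1", "group2"])
        assert dunn.loc[("a", "c"), "p_value"] < dunn.loc[("a", "b"), "p_value"]


class TestGeneLinking:
    def _genes(self):
        return GenomicIntervalSet(
            pd.DataFrame(
                {"chrom": ["chr1", "chr1"], "start": [10_000, 50_000],
                 "end": [20_000, 60_000], "name": ["GENE1", "GENE2"]}
            )
        )

    def test_window_linking_rules(self):
        manifest = ProbeManifest(
            pd.DataFrame({"probe_id": ["cg_in", "cg_near", "cg_far"],
                          "chrom": "chr1",
                          "start": [15_000, 5000, 80_000],
                          "end": [15_002, 5002, 80_002]})
        )
        linked0 = link_probes_to_genes(manifest, self._genes(), window_bp=0)
        assert set(zip(linked0["probe_id"], linked0["gene"])) == {("cg_in", "GENE1")}
        linked10k = link_probes_to_genes(manifest, self._genes(), window_bp=10_000)
        pairs = set(zip(linked10k["probe_id"], linked10k["gene"]))
        assert ("cg_near", "GENE1") in pairs
        assert ("cg_far", "GENE2") not in pairs  # 80k start vs 60k end + 10k window

    def test_correlation_affine_independent_and_degenerate(self):
        tissues = [f"t{i}" for i in range(8)]
        rng = np.random.default_rng(13)
        beta = pd.DataFrame(rng.random((3, 8)), index=["cgA", "cgB", "cgC"], columns=tissues)
        expr = pd.DataFrame(
            {t: [100 * beta.loc["cgA", t], rng.random(), 5.0] for t in tissues},
            index=["gAFFINE", "gNOISE", "gCONST"],
        )
        pairs = pd.DataFrame({"probe_id": ["cgA", "cgB", "cgC"],
                              "gene": ["gAFFINE", "gNOISE", "gCONST"]})
        res = cpg_gene_correlation(beta, expr, pairs).set_index("probe_id")
        assert res.loc["cgA", "r"] == pytest.approx(1.0, abs=1e-12)
        assert np.isnan(res.loc["cgC", "r"])  # zero-variance expression
        # many independent pairs center at r = 0
        big_beta = pd.DataFrame(rng.random((200, 8)), columns=tissues,
                                index=[f"cg{i}" for i in range(200)])
        big_expr = pd.DataFrame(rng.random((200, 8)), columns=tissues,
                                index=[f"g{i}" for i in range(200)])
        big_pairs = pd.DataFrame({"probe_id": big_beta.index, "gene": big_expr.index})
        rs = cpg_gene_correlation(big_beta, big_expr, big_pairs)["r"]
        assert abs(rs.mean()) < 0.05
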