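"""One-vs-rest marker discovery against exact enumeration oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methylcode.io import BetaMatrix
from methylcode.markers import (
    MarkerThresholds,
    constitutive_screen,
    hierarchical_contrasts,
    intermediate_screen,
    one_vs_rest_markers,
    tissue_specific_features,
    variability_rank,
)
from methylcode.simulate import SimulationConfig, simulate_group_samples, simulate_references


def exact_wilcoxon_oracle(target, rest):
    """Exact two-sided rank-sum p and pair-count AUC by full enumeration.

    Enumerates every assignment of the pooled ranks to the target group; the
    two-sided p doubles the smaller tail of the U distribution (capped at 1).
    """
    pooled = np.concatenate([target, rest])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(target), len(rest)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [sum(ranks[list(c)]) - n1 * (n1 + 1) / 2 for c in combinations(range(n1 + n2), n1)]
    )
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    p = min(1.0, 2 * min(lo, hi))
    # probability-of-superiority AUC by exhaustive pair counting
    wins = sum((t > r) + 0.5 * (t == r) for t in target for r in rest)
    return p, wins / (n1 * n2), u_obs


def _groups(labels):
    return pd.Series(labels, index=[f"s{i}" for i in range(len(labels))])


def _bm_from_rows(rows, samples):
    return BetaMatrix(
        pd.DataFrame(np.atleast_2d(rows), index=[f"cg{i}" for i in range(len(rows))],
                     columns=samples),
        validate=False,
    )


class TestWilcoxonAuc:
    def test_complete_separation_example(self):
        target = [0.9, 0.8, 0.85]
        rest = [0.1, 0.2, 0.15, 0.05]
        bm = _bm_from_rows([target + rest], [f"s{i}" for i in range(7)])
        res = one_vs_rest_markers(
            bm, _groups(["T"] * 3 + ["R"] * 4), "T", MarkerThresholds(min_auc=0.5, min_delta=0)
        )
        row = res.iloc[0]
        assert row["auc"] == 1.0
        assert row["delta_beta"] == pytest.approx(0.725)
        assert row["direction"] == "hyper"
        assert row["p_value"] == pytest.approx(2 / 35, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (3, 4), (4, 5), (5, 5), (6, 6)])
    def test_exact_p_and_auc_match_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(5):
            target = rng.random(n1)
            rest = rng.random(n2)
            p_oracle, auc_oracle, _ = exact_wilcoxon_oracle(target, rest)
            bm = _bm_from_rows(
                [np.concatenate([target, rest])], [f"s{i}" for i in range(n1 + n2)]
            )
            res = one_vs_rest_markers(
                bm, _groups(["T"] * n1 + ["R"] * n2), "T",
                MarkerThresholds(min_auc=0.5, min_delta=0),
            )
            assert res.iloc[0]["p_value"] == pytest.approx(p_oracle, abs=1e-12)
            assert res.iloc[0]["auc"] == pytest.approx(auc_oracle, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 20), min_size=2, max_size=6),
           st.lists(st.integers(0, 20), min_size=2, max_size=6))
    def test_auc_equals_pair_counting_with_ties(self, tvals, rvals):
        target = np.array(tvals) / 20.0
        rest = np.array(rvals) / 20.0
        _, auc_oracle, _ = exact_wilcoxon_oracle(target, rest)
        if np.all(target == target[0]) and np.all(rest == rest[0]) and target[0] == rest[0]:
            return  # constant CpG: no contrast to test
        bm = _bm_from_rows(
            [np.concatenate([target, rest])], [f"s{i}" for i in range(len(tvals) + len(rvals))]
        )
        res = one_vs_rest_markers(
            bm, _groups(["T"] * len(tvals) + ["R"] * len(rvals)), "T",
            MarkerThresholds(min_auc=0.5, min_delta=0),
        )
        assert res.iloc[0]["auc"] == pytest.approx(auc_oracle, abs=1e-12)


class TestNaRulesAndSelection:
    def test_na_caps_drop_probes(self):
        samples = [f"s{i}" for i in range(14)]
        labels = _groups(["T"] * 4 + ["R"] * 10)
        ok_row = np.concatenate([[0.9] * 4, [0.1] * 10])
        target_na = ok_row.copy(); target_na[0] = np.nan          # 25% NA in target
        rest_na = ok_row.copy(); rest_na[4:10] = np.nan           # 60% NA in rest
        bm = _bm_from_rows([ok_row, target_na, rest_na], samples)
        res = one_vs_rest_markers(bm, labels, "T", MarkerThresholds(min_auc=0.5, min_delta=0))
        assert list(res["probe_id"]) == ["cg0"]

    def test_cap_balances_hyper_and_hypo(self):
        refs, gt = simulate_references(
            SimulationConfig(n_probes=500, n_celltypes=3, n_markers_per_type=40,
                             marker_delta=0.4, noise_sd=0.0, seed=11)
        )
        bm, labels = simulate_group_samples(refs, n_per_type=4, noise_sd=0.05, seed=12)
        res = one_vs_rest_markers(
            bm, labels, "CT0", MarkerThresholds(min_auc=1.0, min_delta=0.3), cap=20
        )
        assert len(res) == 20
        counts = res["direction"].value_counts()
        assert abs(counts.get("hyper", 0) - counts.get("hypo", 0)) <= 1

    def test_too_few_samples_skips_contrast_with_warning(self):
        bm = _bm_from_rows([[0.1, 0.9, 0.5]], ["s0", "s1", "s2"])
        with pytest.warns(UserWarning, match="skipped"):
            res = one_vs_rest_markers(bm, _groups(["T", "R", "R"]), "T")
        assert res.empty

    def test_null_labels_give_uniform_p_and_no_markers(self):
        rng = np.random.default_rng(21)
        n_probes, n_samples = 1200, 30
        vals = rng.beta(0.5, 0.5, size=(n_probes, n_samples))
        samples = [f"s{i}" for i in range(n_samples)]
        bm = BetaMatrix(pd.DataFrame(vals, index=[f"cg{i}" for i in range(n_probes)],
                                     columns=samples), validate=False)
        labels = _groups(["T"] * 15 + ["R"] * 15)
        res = one_vs_rest_markers(
            bm, labels, "T", MarkerThresholds(min_auc=0.5, min_delta=0), return_all=True
        )
        passing = ((res["auc"] >= 0.8) | (res["auc"] <= 0.2)) & (res["delta_beta"].abs() >= 0.2)
        assert passing.mean() < 0.005
        # calibration at several alpha levels within the binomial 99% CI
        # (a strict continuous KS test would flag only the deliberate
        # conservatism of the continuity correction in the far tail)
        p = res["p_value"].to_numpy()
        n = len(p)
        for alpha in (0.01, 0.05, 0.1, 0.2, 0.5):
            half_width = 2.576 * np.sqrt(alpha * (1 - alpha) / n) + 1 / n
            assert abs((p <= alpha).mean() - alpha) <= half_width


class TestPlantedRecovery:
    def test_precision_and_recall_on_planted_markers(self):
        refs, gt = simulate_references(
            SimulationConfig(n_probes=1500, n_celltypes=5, n_markers_per_type=20,
                             marker_delta=0.4, noise_sd=0.5, seed=31)
        )
        bm, labels = simulate_group_samples(refs, n_per_type=10, noise_sd=0.5, seed=32)
        truth, found = set(), set()
        for ct in refs.sample_ids:
            truth |= {(ct, p) for p in gt.marker_ids[ct]["probe_id"]}
            res = one_vs_rest_markers(bm, labels, ct)
            found |= {(ct, p) for p in res["probe_id"]}
        tp = len(found & truth)
        assert tp / len(found) >= 0.95
        assert tp / len(truth) >= 0.95


class TestHierarchical:
    def test_flat_tree_equals_one_vs_rest(self):
        rng = np.random.default_rng(41)
        samples = [f"s{i}" for i in range(12)]
        bm = BetaMatrix(pd.DataFrame(rng.random((50, 12)),
                                     index=[f"cg{i}" for i in range(50)], columns=samples),
                        validate=False)
        labels = _groups(["A"] * 6 + ["B"] * 6)
        tree = pd.DataFrame({"major": labels.to_numpy()}, index=samples)
        th = MarkerThresholds(min_auc=0.5, min_delta=0)
        res = hierarchical_contrasts(bm, tree, th)
        flat = one_vs_rest_markers(bm, labels, "A", th)
        pd.testing.assert_frame_equal(res[(0, (), "A")], flat)

    def test_subtype_markers_found_only_at_level_two(self):
        # subtype marker: differs between A1 and A2 but identical in mean
        # across majors A and B
        samples = [f"s{i}" for i in range(16)]
        major = ["A"] * 8 + ["B"] * 8
        sub = ["A1"] * 4 + ["A2"] * 4 + ["B1"] * 8
        rng = np.random.default_rng(5)
        base = rng.uniform(0.4, 0.6, size=(30, 16))
        # probe 0: subtype marker inside A
        base[0, :4] = 0.9
        base[0, 4:8] = 0.1
        base[0, 8:] = 0.5
        bm = BetaMatrix(pd.DataFrame(base, index=[f"cg{i}" for i in range(30)],
                                     columns=samples), validate=False)
        tree = pd.DataFrame({"major": major, "sub": sub}, index=samples)
        res = hierarchical_contrasts(bm, tree, MarkerThresholds(min_auc=0.9, min_delta=0.3))
        level1_hits = set(res[(0, (), "A")]["probe_id"])
        level2_hits = set(res[(1, ("A",), "A1")]["probe_id"])
        assert "cg0" not in level1_hits
        assert "cg0" in level2_hits
        # B has a single subtype: sibling set is degenerate, node skipped
        assert (1, ("B",), "B1") not in res


class TestScreens:
    def test_constitutive_rules(self):
        bm = _bm_from_rows(
            [[0.1, 0.15, 0.05], [0.85, 0.9, np.nan], [0.1, 0.85, 0.5],
             [np.nan, np.nan, np.nan]],
            ["s0", "s1", "s2"],
        )
        unmod, mod = constitutive_screen(bm)
        assert unmod == ["cg0"]
        assert mod == ["cg1"]

    def test_intermediate_default_and_design_variant(self):
        bm = _bm_from_rows([[0.5, 0.5, 0.5], [0.5, 0.75, 0.5]], ["s0", "s1", "s2"])
        assert intermediate_screen(bm) == ["cg0"]
        # design variant boundary: inside the band for 139 of 180 -> excluded,
        # 140 -> included
        row139 = np.concatenate([np.full(139, 0.5), np.full(41, 0.9)])
        row140 = np.concatenate([np.full(140, 0.5), np.full(40, 0.9)])
        big = _bm_from_rows([row139, row140], [f"s{i}" for i in range(180)])
        kept = intermediate_screen(big, min_n_samples=140)
        assert kept == ["cg1"]

    def test_variability_rank_closed_form_and_filter(self):
        bm = _bm_from_rows([[0.0, 1.0], [0.5, 0.5], [0.2, 0.4]], ["s0", "s1"])
        ranked = variability_rank(bm)
        assert ranked.loc[0, "probe_id"] == "cg0"
        assert ranked.loc[0, "sd"] == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert ranked.iloc[-1]["probe_id"] == "cg1"  # constant row last
        chroms = pd.Series({"cg0": "chrX", "cg1": "chr1", "cg2": "chr2"})
        auto = variability_rank(bm, chrom_by_probe=chroms, autosomes_only=True)
        assert "cg0" not in set(auto["probe_id"])


class TestExpressionFeatures:
    def test_tissue_biased_gene_found_and_constant_excluded(self):
        expr = pd.DataFrame(
            {
                "liver": [100.0, 5.0],
                "lung": [1.0, 5.0],
                "heart": [0.5, 5.0],
                "kidney": [2.0, 5.0],
                "brain": [1.5, 5.0],
            },
            index=["gLIV", "gCONST"],
        )
        out = tissue_specific_features(expr)
        assert list(out["liver"]["probe_id"]) == ["gLIV"]
        for tissue, res in out.items():
            assert "gCONST" not in set(res["probe_id"])

    def test_single_column_auc_matches_rank_oracle(self):
        expr = pd.DataFrame(
            {"a": [10.0], "b": [1.0], "c": [3.0], "d": [5.0]}, index=["g"]
        )
        out = tissue_specific_features(
            expr, MarkerThresholds(min_auc=0.5, min_delta=0.0, max_na_target=1, max_na_rest=1)
        )
        # target a=10 beats all three others -> AUC 1; d=5 beats 2 of 3
        assert out["a"].iloc[0]["auc"] == 1.0
        assert out["d"].iloc[0]["auc"] == pytest.approx(2 / 3, abs=1e-12)
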