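"""Downstream statistics: Wilcoxon, Fisher, overlaps, GSEA, classes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from omegak.correction import multiple_correction
from omegak.stats import (
    classify_orthogroups,
    enrichment_table,
    fisher_enrichment,
    go_term_k_tests,
    gsea,
    overlap_stats,
    rank_transform_k,
    sign_balance_test,
    top_gene_sets,
    transform_k,
    wilcoxon_signed_rank,
)


def exact_wilcoxon_p(diffs, alternative="two-sided"):
    """Full 2^n sign-pattern enumeration, independent of scipy."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    vs = []
    for signs in itertools.product([0, 1], repeat=n):
        vs.append(sum(r for s, r in zip(signs, ranks) if s))
    vs = np.array(vs)
    if alternative == "greater":
        return np.mean(vs >= v_obs)
    if alternative == "less":
        return np.mean(vs <= v_obs)
    return min(1.0, 2 * min(np.mean(vs >= v_obs), np.mean(vs <= v_obs)))


class TestWilcoxon:
    def test_worked_example(self):
        res = wilcoxon_signed_rank([1.1, 1.2, 1.3, 1.4, 1.5], mu=1.0)
        assert res.statistic == 15.0
        assert res.p == pytest.approx(0.0625)

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        vals = rng.normal(0.2, 1.0, n)
        res = wilcoxon_signed_rank(vals, mu=0.0)
        if "exact" in res.method:
            assert res.p == pytest.approx(exact_wilcoxon_p(vals), abs=1e-12)

    def test_symmetric_values_not_significant(self):
        vals = 1.0 + np.array([-0.4, -0.3, -0.2, -0.1, 0.1, 0.2, 0.3, 0.4])
        res = wilcoxon_signed_rank(vals, mu=1.0)
        n = res.n_effective
        assert res.statistic == n * (n + 1) / 4
        assert res.p > 0.5

    def test_all_zero_differences(self):
        res = wilcoxon_signed_rank([1.0, 1.0, 1.0], mu=1.0)
        assert res.p == 1.0 and res.n_effective == 0

    def test_large_sample_uses_approximation(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0.5, 1.0, 80)
        res = wilcoxon_signed_rank(vals)
        assert "approx" in res.method and 0 <= res.p <= 1

    def test_sign_balance(self):
        res = sign_balance_test([0.2, 0.3, 0.4, 1.8])
        want = sps.binomtest(3, 4, 0.5).pvalue
        assert res.p == pytest.approx(want)
        assert sign_balance_test([1.0, 1.0]).n_effective == 0


class TestFisher:
    def test_hand_computed_tail(self):
        universe = {f"a{i}" for i in range(122)} | {f"b{i}" for i in range(2580)}
        go = {"a0": {"T"}, "a1": {"T"}}
        p = fisher_enrichment("T", {f"a{i}" for i in range(122)}, universe, go)
        assert p == pytest.approx(122 * 121 / (2702 * 2701), rel=1e-12)

    def test_balanced_table(self):
        # [[5,5],[5,5]]: P(X >= 5), X ~ Hypergeom(N=20, K=10, n=10)
        universe = {i for i in range(20)}
        selected = set(range(10))
        go = {i: {"T"} for i in list(range(5)) + list(range(10, 15))}
        p = fisher_enrichment("T", selected, universe, go)
        want = sps.hypergeom.sf(4, 20, 10, 10)
        assert p == pytest.approx(want)
        assert p == pytest.approx(0.6718591, abs=1e-6)

    def test_absent_term_p_one(self):
        assert fisher_enrichment("GO:X", {1}, {1, 2}, {}) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_tail_sum_consistency(self, seed):
        rng = np.random.default_rng(seed)
        n_uni = int(rng.integers(10, 40))
        universe = set(range(n_uni))
        selected = set(rng.choice(n_uni, size=int(rng.integers(2, n_uni // 2)), replace=False).tolist())
        with_term = set(rng.choice(n_uni, size=int(rng.integers(1, n_uni // 2)), replace=False).tolist())
        go = {i: {"T"} for i in with_term}
        over = fisher_enrichment("T", selected, universe, go, tail="over")
        under = fisher_enrichment("T", selected, universe, go, tail="under")
        k = len(selected & with_term)
        point = sps.hypergeom.pmf(k, n_uni, len(with_term), len(selected))
        assert over + under - point == pytest.approx(1.0, abs=1e-10)

    def test_enrichment_table_flags(self):
        universe = set(range(40))
        go = {i: {"GO:A"} for i in range(10)}
        for i in range(40):
            go.setdefault(i, set()).add("GO:B")
        selected = set(range(8))  # heavily enriched for GO:A
        tab = enrichment_table(selected, universe, go, fdr=0.10, alpha=0.05)
        row = tab.set_index("term").loc["GO:A"]
        assert row["significant"] and row["trend"]
        assert not tab.set_index("term").loc["GO:B"]["significant"]


class TestOverlap:
    def test_worked_example(self):
        exp, _, _ = overlap_stats(set(range(122)), set(range(92)), 2702)
        assert exp == pytest.approx(122 * 92 / 2702)

    def test_empty_set(self):
        exp, obs, p = overlap_stats(set(), {1, 2}, 100)
        assert exp == 0 and obs == 0 and p == 1.0

    def test_monte_carlo_expectation(self):
        rng = np.random.default_rng(0)
        n, a_size, b_size = 300, 40, 30
        draws = 10_000
        overlaps = np.empty(draws)
        for i in range(draws):
            a = rng.choice(n, a_size, replace=False)
            b = rng.choice(n, b_size, replace=False)
            overlaps[i] = len(set(a.tolist()) & set(b.tolist()))
        expected, _, _ = overlap_stats(set(range(a_size)), set(range(b_size)), n)
        se = overlaps.std() / np.sqrt(draws)
        assert abs(overlaps.mean() - expected) < 3 * se + 1e-9

    def test_zero_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_stats({1}, {2}, 0)


class TestTransform:
    def test_fixed_points(self):
        assert transform_k(1.0) == 0.0
        assert transform_k(0.0) == -1.0
        assert transform_k(50.0) == pytest.approx(49 / 51)

    def test_monotone_and_sign(self):
        ks = np.linspace(0, 50, 200)
        s = transform_k(ks)
        assert (np.diff(s) > 0).all()
        assert ((s > 0) == (ks > 1)).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_k(-0.1)

    def test_rank_variant_bounds(self):
        s = rank_transform_k([0.1, 0.5, 1.0, 2.0, 9.0])
        assert (np.diff(s) > 0).all() and (np.abs(s) <= 1).all()


class TestCorrection:
    def test_bh_worked_example(self):
        got = multiple_correction([0.01, 0.02, 0.03, 0.04], "bh")
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bonferroni(self):
        assert multiple_correction([0.01, 0.5], "bonferroni") == pytest.approx([0.02, 1.0])

    def test_single_p_unchanged(self):
        assert multiple_correction([0.037], "bh") == pytest.approx([0.037])

    def test_empty(self):
        assert multiple_correction([], "bh").size == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_bh_monotone_and_inflationary(self, seed):
        """BH preserves the p-value ordering; re-adjusting adjusted
        values can only move them up (min over j>=i of (m/j) q_(j) >=
        q_(i)), with equality at the top rank."""
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 25)
        q = multiple_correction(p, "bh")
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        q2 = multiple_correction(q, "bh")
        assert (q2 >= q - 1e-12).all()
        assert q2[order[-1]] == pytest.approx(q[order[-1]])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            multiple_correction([0.5, 1.5], "bh")


class TestGSEA:
    def _scores(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return {f"og{i:03d}": s for i, s in enumerate(rng.uniform(-1, 1, n))}

    def test_all_genes_set_es_zero(self):
        scores = self._scores()
        res = gsea(scores, {"ALL": set(scores)}, n_perm=50, seed=0)
        assert res[0].es == 0.0

    def test_p_lower_bound(self):
        scores = self._scores()
        sets = {"S": set(list(scores)[:10])}
        res = gsea(scores, sets, n_perm=200, seed=1)
        assert res[0].p >= 1 / 201

    def test_planted_top_set_recovered(self):
        scores = self._scores(n=200, seed=2)
        ranked = sorted(scores, key=lambda g: -scores[g])
        planted = set(ranked[:10])  # the top 5% of scores
        sets = {"PLANTED": planted, "RANDOM": set(ranked[50:80])}
        res = {r.gene_set: r for r in gsea(scores, sets, n_perm=1000, seed=3)}
        assert res["PLANTED"].nes > 0
        assert res["PLANTED"].p <= 0.01
        assert res["PLANTED"].q <= res["RANDOM"].q

    def test_small_set_skipped(self):
        scores = self._scores()
        res = gsea(scores, {"TINY": set(list(scores)[:2])}, n_perm=20, seed=0)
        assert res == []

    def test_top_sets_split_by_sign(self):
        scores = self._scores(n=100, seed=4)
        ranked = sorted(scores, key=lambda g: -scores[g])
        sets = {"HI": set(ranked[:8]), "LO": set(ranked[-8:])}
        res = gsea(scores, sets, n_perm=200, seed=5)
        pos, neg = top_gene_sets(res, n=3)
        assert {r.gene_set for r in pos} == {"HI"}
        assert {r.gene_set for r in neg} == {"LO"}


class TestGMT:
    def test_round_trip(self, tmp_path):
        from omegak.stats import read_gmt

        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\t-\tg9\n")
        sets = read_gmt(path)
        assert sets == {"setA": {"g1", "g2", "g3"}, "setB": {"g9"}}

    def test_malformed_line_rejected(self, tmp_path):
        from omegak.stats import read_gmt

        path = tmp_path / "bad.gmt"
        path.write_text("onlyname\n")
        with pytest.raises(ValueError, match="line 1"):
            read_gmt(path)


class TestClassify:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["orthogroup_id", "k_hat", "q_BH", "bs_q"],
        )

    def test_rules(self):
        tab = self._table(
            [
                ("a", 0.3, 0.05, 0.5),
                ("b", 1.0, 0.05, 0.5),
                ("c", 4.0, 0.5, 0.01),
                ("d", 2.0, 0.01, 0.01),
            ]
        )
        out = classify_orthogroups(tab, fdr=0.10).set_index("orthogroup_id")
        assert out.loc["a", "relaxed"] and not out.loc["a", "intensified"]
        assert not out.loc["b", "relaxed"] and not out.loc["b", "intensified"]
        assert not out.loc["c", "relaxed"] and out.loc["c", "diversifying"]
        assert out.loc["d", "intensified"] and out.loc["d", "diversifying"]

    def test_missing_fit_unclassified(self):
        tab = self._table([("a", np.nan, np.nan, np.nan)])
        out = classify_orthogroups(tab, fdr=0.10)
        assert not out[["relaxed", "intensified", "diversifying"]].any().any()

    def test_counts_monotone_in_fdr(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"og{i}", rng.uniform(0, 3), rng.uniform(0, 1), rng.uniform(0, 1))
            for i in range(100)
        ]
        tab = self._table(rows)
        counts = []
        for fdr in (0.20, 0.10, 0.05, 0.01):
            out = classify_orthogroups(tab, fdr=fdr)
            counts.append(out[["relaxed", "intensified", "diversifying"]].sum().sum())
        assert (np.diff(counts) <= 0).all()


class TestGoKTests:
    def test_min_n_exclusion_and_direction(self):
        k_table = pd.DataFrame(
            {
                "orthogroup_id": [f"og{i}" for i in range(12)],
                "k_hat": [0.2] * 6 + [3.0] * 6,
            }
        )
        go_map = {f"og{i}": {"GO:LOW"} for i in range(6)}
        for i in range(6, 12):
            go_map[f"og{i}"] = {"GO:HIGH"}
        go_map["og0"].add("GO:RARE")
        out = go_term_k_tests(go_map, k_table, min_n=5)
        assert set(out["term"]) == {"GO:LOW", "GO:HIGH"}
        by = out.set_index("term")
        assert by.loc["GO:LOW", "direction"] == "relaxed"
        assert by.loc["GO:HIGH", "direction"] == "intensified"
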