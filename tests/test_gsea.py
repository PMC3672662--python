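"""Gene-set enrichment: exact scores, permutation null, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parityomics.gsea import (
    GeneSetCollection,
    GeneSetEnrichment,
    _null_es_for_size,
    enrichment_score,
    permute_and_score,
    rank_by_difference,
    read_gmt,
    write_gmt,
)


def ranked_series(scores, genes=None):
    genes = genes or [f"g{i:03d}" for i in range(len(scores))]
    return pd.Series(list(scores), index=genes)


def brute_force_es(ranked, members, p):
    """Position-by-position running sum, the obvious O(N) oracle."""
    hits = np.array([g in members for g in ranked.index])
    w = np.abs(ranked.to_numpy()) ** p
    hit_w = np.where(hits, w, 0.0)
    total = hit_w.sum() if hit_w.sum() > 0 else hits.sum()
    run, best = 0.0, 0.0
    for i in range(len(ranked)):
        run += hit_w[i] / total if hits[i] else -1.0 / (len(ranked) - hits.sum())
        if abs(run) > abs(best):
            best = run
    return best


class TestEnrichmentScore:
    def test_top_contiguous_set_scores_one_unweighted(self):
        ranked = ranked_series(np.linspace(5, -5, 20))
        es, _ = enrichment_score(ranked, set(ranked.index[:4]), weight_exponent=0)
        assert es == pytest.approx(1.0)

    def test_bottom_contiguous_set_scores_minus_one(self):
        ranked = ranked_series(np.linspace(5, -5, 20))
        es, _ = enrichment_score(ranked, set(ranked.index[-4:]), weight_exponent=0)
        assert es == pytest.approx(-1.0)

    def test_worked_ten_gene_instance(self):
        # N=10, hits at ranked positions 1 and 6, p=0: max deviation 0.5
        ranked = ranked_series(np.linspace(3, -3, 10))
        members = {ranked.index[0], ranked.index[5]}
        es, running = enrichment_score(ranked, members, weight_exponent=0)
        assert es == pytest.approx(0.5)
        assert es == pytest.approx(brute_force_es(ranked, members, 0))

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(12)
        ranked = ranked_series(np.sort(rng.normal(size=80))[::-1])
        for _ in range(25):
            members = set(rng.choice(ranked.index, size=rng.integers(2, 20), replace=False))
            for p in (0.0, 1.0, 2.0):
                es, _ = enrichment_score(ranked, members, weight_exponent=p)
                assert es == pytest.approx(brute_force_es(ranked, members, p), abs=1e-12)

    def test_running_sum_returns_to_zero(self):
        rng = np.random.default_rng(13)
        ranked = ranked_series(np.sort(rng.normal(size=60))[::-1])
        members = set(rng.choice(ranked.index, size=10, replace=False))
        es, running = enrichment_score(ranked, members)
        assert abs(running[-1]) < 1e-12
        assert -1.0 <= es <= 1.0

    def test_reversing_list_negates_score(self):
        rng = np.random.default_rng(14)
        scores = np.sort(rng.normal(size=50))[::-1]
        ranked = ranked_series(scores)
        rev = pd.Series(-scores[::-1], index=ranked.index[::-1])
        members = set(rng.choice(ranked.index, size=8, replace=False))
        es_f, _ = enrichment_score(ranked, members)
        es_r, _ = enrichment_score(rev, members)
        assert es_r == pytest.approx(-es_f)

    def test_disjoint_set_rejected(self):
        ranked = ranked_series([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="does not intersect"):
            enrichment_score(ranked, {"absent"})

    def test_null_sampler_matches_direct_scores(self):
        # the vectorised permutation scorer must agree with the plain
        # per-set enrichment_score on the same index draws
        rng = np.random.default_rng(15)
        ranked = ranked_series(np.sort(rng.normal(size=70))[::-1])
        w = np.abs(ranked.to_numpy())
        null = _null_es_for_size(w, 9, 50, np.random.default_rng(99))
        check_rng = np.random.default_rng(99)
        for es_null in null:
            idx = np.sort(check_rng.choice(70, size=9, replace=False))
            direct, _ = enrichment_score(ranked, set(ranked.index[idx]))
            assert es_null == pytest.approx(direct, abs=1e-12)


class TestRanking:
    def test_identical_matrices_rank_lexicographically(self):
        df = pd.DataFrame(np.ones((4, 3)), index=["d", "b", "a", "c"])
        ranked = rank_by_difference(df, df)
        assert list(ranked.index) == ["a", "b", "c", "d"]
        assert (ranked == 0).all()

    def test_shifted_gene_ranks_first(self):
        rng = np.random.default_rng(16)
        virgin = pd.DataFrame(rng.normal(size=(30, 3)), index=[f"g{i}" for i in range(30)])
        parous = virgin + rng.normal(scale=0.01, size=virgin.shape)
        parous.loc["g7"] += 2.0
        assert rank_by_difference(parous, virgin).index[0] == "g7"

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(17)
        idx = [f"g{i}" for i in range(40)]
        virgin = pd.DataFrame(rng.normal(size=(40, 3)), index=idx)
        parous = pd.DataFrame(rng.normal(size=(40, 3)), index=idx)
        ranked = rank_by_difference(parous, virgin)
        perm = rng.permutation(idx)
        ranked2 = rank_by_difference(parous.loc[perm], virgin.loc[perm])
        pd.testing.assert_series_equal(ranked, ranked2)


class TestPermutation:
    def make_ranked(self, seed=18, n=600):
        rng = np.random.default_rng(seed)
        return ranked_series(np.sort(rng.normal(size=n))[::-1])

    def test_seeded_determinism(self):
        ranked = self.make_ranked()
        sets = {"s1": frozenset(ranked.index[5:25]), "s2": frozenset(ranked.index[::7])}
        r1 = permute_and_score(ranked, sets, n_perm=100, seed=5)
        r2 = permute_and_score(ranked, sets, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_nes_sign_matches_es(self):
        ranked = self.make_ranked(19)
        sets = {
            "top": frozenset(ranked.index[:20]),
            "bottom": frozenset(ranked.index[-20:]),
        }
        res = permute_and_score(ranked, sets, n_perm=200, seed=6)
        assert (np.sign(res["nes"]) == np.sign(res["es"])).all()
        assert res.loc["top", "es"] > 0 > res.loc["bottom", "es"]

    def test_nominal_p_uniform_under_null(self):
        # random sets carry no signal: nominal p is uniform
        rng = np.random.default_rng(20)
        ranked = self.make_ranked(21, n=400)
        sets = {
            f"null_{i}": frozenset(rng.choice(ranked.index, size=15, replace=False))
            for i in range(120)
        }
        res = permute_and_score(ranked, sets, n_perm=250, seed=7)
        frac = (res["p_nominal"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 120) + 1e-9
        ks = stats.kstest(res["p_nominal"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_downregulated_set_detected(self):
        # 50-gene set shifted down by 1 against noise sd 0.5 in a
        # 5000-gene universe: strongly negative NES at small FDR
        rng = np.random.default_rng(22)
        n = 5000
        scores = rng.normal(0, 0.5, size=n)
        idx = [f"g{i:04d}" for i in range(n)]
        planted = rng.choice(n, size=50, replace=False)
        scores[planted] -= 1.0
        order = np.argsort(-scores)
        ranked = pd.Series(scores[order], index=np.array(idx)[order])
        sets = {
            "planted": frozenset(np.array(idx)[planted]),
            "random": frozenset(rng.choice(idx, size=50, replace=False)),
        }
        res = permute_and_score(ranked, sets, n_perm=500, seed=8)
        assert res.loc["planted", "nes"] < 0
        assert res.loc["planted", "fdr_q"] < 0.05

    def test_size_flags_and_warnings(self):
        ranked = self.make_ranked(23, n=100)
        sets = {"tiny": frozenset(ranked.index[:2]), "ok": frozenset(ranked.index[:10])}
        res = permute_and_score(ranked, sets, n_perm=50, seed=9)
        assert res.loc["tiny", "size_flag"] == "below_min_size"
        assert res.loc["ok", "size_flag"] == "ok"
        big = {"big": frozenset(ranked.index[:60])}
        with pytest.warns(RuntimeWarning, match="half the universe"):
            permute_and_score(ranked, big, n_perm=50, seed=9)

    def test_too_few_permutations_rejected(self):
        ranked = self.make_ranked(24, n=50)
        with pytest.raises(ValueError, match="at least 10"):
            permute_and_score(ranked, {"s": frozenset(ranked.index[:5])}, n_perm=5)


class TestGmtRoundTrip:
    def test_write_then_read(self, tmp_path):
        coll = GeneSetCollection(
            sets={"SET_A": frozenset({"g1", "g2"}), "SET_B": frozenset({"g3"})},
            descriptions={"SET_A": "first", "SET_B": "second"},
        )
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets
        assert back.descriptions == coll.descriptions

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\n")
        with pytest.raises(ValueError, match="malformed"):
            read_gmt(path)
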