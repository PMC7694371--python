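import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp, mannwhitneyu

from concordia import (
    GeneSetCollection,
    combined_significance_threshold,
    dual_level_combine,
    enrichment_score,
    fdr_q,
    normalize_and_test,
    permutation_null,
    preranked_gsea,
    read_gmt,
    write_gmt,
)


def brute_force_es(scores, hit_mask, weight):
    """Independent plain-loop running-sum oracle (same tie rule: positive wins)."""
    n = len(scores)
    m = sum(hit_mask)
    hit_w = [abs(s) ** weight for s, h in zip(scores, hit_mask) if h]
    total = sum(hit_w)
    rs, path = 0.0, []
    it = iter(hit_w)
    for s, h in zip(scores, hit_mask):
        rs += next(it) / total if h else -1.0 / (n - m)
        path.append(rs)
    hi, lo = max(path), min(path)
    return (hi if abs(hi) >= abs(lo) else lo), path


def toy_universe(n, rng=None, positive=False):
    rng = rng or np.random.default_rng(7)
    scores = np.sort(rng.standard_normal(n))[::-1]
    if positive:
        scores = np.sort(rng.random(n) + 0.5)[::-1]
    genes = [f"g{i}" for i in range(n)]
    return genes, scores


class TestEnrichmentScore:
    def test_single_top_hit_reaches_one(self):
        es, rs = enrichment_score(list("abcd"), [4.0, 3.0, 2.0, 1.0], {"a"}, weight=1.0)
        assert es == pytest.approx(1.0)
        assert rs[0] == pytest.approx(1.0)

    def test_single_bottom_hit_is_maximally_negative(self):
        # uniform positive scores, weight 0: all misses precede the one hit, so
        # the running sum bottoms out at -1 just before it
        n = 8
        es, rs = enrichment_score(
            [f"g{i}" for i in range(n)], [1.0] * n, {f"g{n - 1}"}, weight=0.0
        )
        assert es < 0
        assert es == pytest.approx(-1.0)
        assert rs[n - 2] == pytest.approx(-1.0)

    def test_weight_zero_equals_ks_statistic(self, rng):
        for n in range(4, 13):
            genes, scores = toy_universe(n, rng)
            for m in range(1, n):
                hits = rng.choice(n, size=m, replace=False)
                members = {genes[i] for i in hits}
                es, _ = enrichment_score(genes, scores, members, weight=0.0)
                misses = np.setdiff1d(np.arange(n), hits)
                ks = ks_2samp(hits, misses, method="exact").statistic
                assert abs(es) == pytest.approx(ks, abs=1e-12)

    def test_bounds_closure_and_brute_force_agreement(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 40))
            genes, scores = toy_universe(n, rng)
            m = int(rng.integers(1, n))
            members = set(rng.choice(genes, size=m, replace=False))
            weight = float(rng.choice([0.0, 1.0, 2.0]))
            es, rs = enrichment_score(genes, scores, members, weight=weight)
            assert abs(es) <= 1.0 + 1e-12
            assert abs(rs[-1]) < 1e-9  # increments balance exactly
            oracle_es, oracle_path = brute_force_es(
                scores, [g in members for g in genes], weight
            )
            assert es == pytest.approx(oracle_es, abs=1e-12)
            np.testing.assert_allclose(rs, oracle_path, atol=1e-12)

    def test_set_outside_universe_rejected(self):
        genes, scores = toy_universe(5)
        with pytest.raises(ValueError, match="no member"):
            enrichment_score(genes, scores, {"zz"})

    def test_whole_universe_rejected(self):
        genes, scores = toy_universe(5)
        with pytest.raises(ValueError, match="whole universe"):
            enrichment_score(genes, scores, set(genes))

    def test_unsorted_scores_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            enrichment_score(list("abc"), [1.0, 2.0, 0.0], {"a"})


class TestPermutationNull:
    def test_seeded_runs_bit_reproducible(self):
        _, scores = toy_universe(50)
        a = permutation_null(scores, 5, 20, seed=123)
        b = permutation_null(scores, 5, 20, seed=123)
        np.testing.assert_array_equal(a, b)
        assert permutation_null(scores, 5, 1, seed=9).shape == (1,)

    def test_different_seeds_same_distribution(self):
        _, scores = toy_universe(200)
        a = permutation_null(scores, 20, 400, seed=1)
        b = permutation_null(scores, 20, 400, seed=2)
        assert mannwhitneyu(a, b).pvalue > 0.01
        sem = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        assert abs(a.mean() - b.mean()) < 3 * sem

    @pytest.mark.parametrize("bad_size", [0, 50])
    def test_set_size_out_of_range(self, bad_size):
        _, scores = toy_universe(50)
        with pytest.raises(ValueError, match="out of range"):
            permutation_null(scores, bad_size, 10, seed=0)

    def test_pool_draws_match_fresh_draws_in_distribution(self):
        # first-m-of-a-permutation sampling must agree with direct subset draws
        _, scores = toy_universe(100, positive=True)
        from concordia.enrichment import make_permutation_pool

        pool = make_permutation_pool(100, 500, np.random.default_rng(5))
        via_pool = permutation_null(scores, 10, 500, pool=pool)
        fresh = permutation_null(scores, 10, 500, seed=11)
        assert mannwhitneyu(via_pool, fresh).pvalue > 0.01


class TestNormalizeAndTest:
    @pytest.mark.parametrize(
        "es_obs, null, exp_nes, exp_p",
        [
            (0.5, [0.5, 0.5, 0.5], 1.0, 1.0),
            (0.9, [0.3, 0.3, 0.3], 3.0, 0.25),
            (-0.6, [-0.3, -0.3, 0.3], -2.0, 1.0 / 3.0),
            (0.0, [0.3, -0.3], 0.0, 1.0),
        ],
    )
    def test_forced_arithmetic(self, es_obs, null, exp_nes, exp_p):
        nes, p = normalize_and_test(es_obs, null)
        assert nes == pytest.approx(exp_nes)
        assert p == pytest.approx(exp_p)

    def test_no_same_sign_null_flags_undefined(self):
        nes, p = normalize_and_test(0.5, [-0.2, -0.4])
        assert np.isnan(nes)
        assert p == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError, match="empty null"):
            normalize_and_test(0.5, [])

    def test_p_floor_is_add_one(self):
        null = np.full(99, 0.1)
        _, p = normalize_and_test(0.99, null)
        assert p == pytest.approx(1.0 / 100.0)


class TestExhaustiveSmallUniverse:
    """6-gene universe, sets of size 2: all 15 subsets enumerable by hand."""

    # irregular spacing so no subset produces an exact |max| == |min| tie,
    # which the two independent implementations may break differently
    genes = [f"g{i}" for i in range(6)]
    scores = np.array([3.11, 2.47, 1.96, 1.58, 0.93, 0.41])

    def exhaustive_null(self):
        out = []
        for pair in itertools.combinations(range(6), 2):
            mask = [i in pair for i in range(6)]
            es, _ = brute_force_es(self.scores, mask, 1.0)
            out.append(es)
        return np.array(out)

    def test_add_one_p_matches_enumeration(self):
        null = self.exhaustive_null()
        es_obs, _ = enrichment_score(self.genes, self.scores, {"g0", "g1"}, weight=1.0)
        nes, p = normalize_and_test(es_obs, null)
        same = null[null > 0]
        hand_p = (1 + int((np.abs(same) >= abs(es_obs)).sum())) / (1 + same.size)
        assert p == pytest.approx(hand_p)
        assert nes == pytest.approx(es_obs / np.abs(same).mean())

    def test_monte_carlo_null_converges_to_enumeration(self):
        null = self.exhaustive_null()
        mc = permutation_null(self.scores, 2, 4000, weight=1.0, seed=3)
        sem = mc.std(ddof=1) / np.sqrt(mc.size)
        assert abs(mc.mean() - null.mean()) < 3 * sem + 1e-12


class TestFdrQ:
    def test_observed_above_all_nulls_gives_zero(self):
        q = fdr_q([2.0], np.full((1, 10), 1.0))
        assert q[0] == 0.0

    def test_observed_equal_to_nulls_gives_one(self):
        q = fdr_q([1.0], np.full((1, 10), 1.0))
        assert q[0] == 1.0

    def test_hand_tail_count_oracle(self):
        obs = np.array([1.5, 0.8, -1.2])
        null = np.array(
            [
                [1.6, 1.0, 0.5, -0.5, 0.9, 1.2, -1.0, 0.4, 0.7, 1.1],
                [0.9, 0.8, 1.4, -0.9, 0.6, -1.5, 1.0, 0.3, 0.2, 1.3],
                [-1.1, -0.7, 1.2, -1.3, 0.8, -0.2, -0.9, 1.0, -1.4, 0.5],
            ]
        )
        q = fdr_q(obs, null)
        pooled = null.ravel()
        pos, neg = pooled[pooled > 0], pooled[pooled < 0]
        obs_pos = obs[obs > 0]
        raw = {}
        for v in obs_pos:
            raw[v] = min(
                1.0,
                ((pos >= v).mean()) / ((obs_pos >= v).sum() / obs_pos.size),
            )
        # monotonisation can only raise q of the less extreme observation
        assert q[0] == pytest.approx(raw[1.5])
        assert q[1] == pytest.approx(max(raw[0.8], raw[1.5]))
        exp_neg = min(1.0, (neg <= -1.2).mean() / 1.0)
        assert q[2] == pytest.approx(exp_neg)

    def test_monotone_in_abs_nes_within_sign(self, rng):
        for _ in range(20):
            obs = rng.standard_normal(12) * 1.5
            null = rng.standard_normal((12, 40))
            q = fdr_q(obs, null)
            for sign in (1, -1):
                side = [(abs(o), qq) for o, qq in zip(obs, q) if o * sign > 0]
                side.sort()
                qs = [qq for _, qq in side]
                assert all(qs[i] >= qs[i + 1] for i in range(len(qs) - 1))


@pytest.fixture(scope="module")
def scores():
    rng = np.random.default_rng(42)
    return pd.Series(rng.standard_normal(300), index=[f"g{i}" for i in range(300)])


class TestPrerankedGsea:

    def test_small_sets_skipped_and_rows_complete(self, scores):
        sets = GeneSetCollection(
            {"tiny": ("g0", "g1"), "ok": tuple(f"g{i}" for i in range(10, 30))}
        )
        res = preranked_gsea(scores, sets, n_perm=100, seed=0)
        assert list(res["set_name"]) == ["ok"]
        row = res.iloc[0]
        assert row["size_in_universe"] == 20
        assert abs(row["es"]) <= 1.0
        assert row["p_perm"] >= 1.0 / 101.0
        assert np.sign(row["nes"]) == np.sign(row["es"])

    def test_empty_collection_exits_cleanly(self, scores):
        res = preranked_gsea(scores, GeneSetCollection({}), n_perm=10, seed=0)
        assert len(res) == 0
        assert list(res.columns) == [
            "set_name", "size_in_universe", "es", "nes", "p_perm", "q_fdr",
        ]

    def test_seeded_run_reproducible(self, scores):
        sets = GeneSetCollection({"s": tuple(f"g{i}" for i in range(0, 40, 2))})
        a = preranked_gsea(scores, sets, n_perm=200, seed=5)
        b = preranked_gsea(scores, sets, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_exclude_blocklist_filters_sets(self, scores):
        sets = GeneSetCollection(
            {
                "keep": tuple(f"g{i}" for i in range(20)),
                "DISEASE_X": tuple(f"g{i}" for i in range(20, 40)),
            }
        )
        res = preranked_gsea(scores, sets, n_perm=50, seed=0, exclude=["DISEASE_X"])
        assert list(res["set_name"]) == ["keep"]


def test_es_and_nes_match_independent_reference(tmp_path):
    """Dual-route check against fgsea (R): the deterministic ES must agree to
    float precision; NES, which depends on the null sample, agrees loosely."""
    import subprocess

    rng = np.random.default_rng(3)
    n = 500
    scores = pd.Series(rng.standard_normal(n), index=[f"g{i}" for i in range(n)])
    members = sorted(rng.choice(scores.index, 40, replace=False))
    scores[members] += 1.0
    res = preranked_gsea(
        scores, GeneSetCollection({"S": tuple(members)}), n_perm=2000, weight=1.0,
        seed=0,
    ).iloc[0]
    scores.rename("score").rename_axis("gene").to_csv(tmp_path / "scores.tsv", sep="\t")
    (tmp_path / "set.gmt").write_text("S\tna\t" + "\t".join(members) + "\n")
    r = subprocess.run(
        ["Rscript", "-e", f'''
suppressMessages(library(fgsea))
s <- read.delim("{tmp_path}/scores.tsv"); v <- setNames(s$score, s$gene)
set.seed(1)
res <- fgsea(gmtPathways("{tmp_path}/set.gmt"), v, gseaParam=1, nperm=2000,
             scoreType="std")
cat(res$ES, res$NES, res$pval, "\\n")
'''],
        capture_output=True, text=True, check=True,
    )
    ref_es, ref_nes, ref_p = map(float, r.stdout.split())
    assert res["es"] == pytest.approx(ref_es, abs=1e-6)
    assert res["nes"] == pytest.approx(ref_nes, rel=0.1)
    assert res["p_perm"] == pytest.approx(ref_p, abs=0.005)


class TestDualLevelCombine:
    @staticmethod
    def row(name, nes, q):
        return {"set_name": name, "size_in_universe": 20, "es": np.sign(nes) * 0.5,
                "nes": nes, "p_perm": 0.01, "q_fdr": q}

    def test_pass_and_fail_rules(self):
        t = pd.DataFrame([self.row("up", 2.0, 0.10), self.row("leaky", 1.5, 0.10),
                          self.row("mixed", 1.2, 0.05)])
        p = pd.DataFrame([self.row("up", 1.8, 0.15), self.row("leaky", 1.4, 0.30),
                          self.row("mixed", -1.3, 0.05)])
        dual = dual_level_combine(t, p, fdr_threshold=0.2).set_index("set_name")
        assert bool(dual.loc["up", "passes_dual_fdr"])
        assert dual.loc["up", "direction"] == "concordant_up"
        assert not bool(dual.loc["leaky", "passes_dual_fdr"])  # q_p = 0.3
        assert dual.loc["mixed", "direction"] == "mixed"
        assert not bool(dual.loc["mixed", "passes_dual_fdr"])

    def test_one_sided_set_flagged_not_fatal(self):
        t = pd.DataFrame([self.row("only_t", 2.0, 0.05)])
        p = pd.DataFrame([self.row("only_p", -2.0, 0.05)])
        dual = dual_level_combine(t, p).set_index("set_name")
        assert not dual["in_both"].any()
        assert not dual["passes_dual_fdr"].any()

    def test_implied_combined_threshold(self):
        assert combined_significance_threshold(0.2) == pytest.approx(0.04)
        dual = dual_level_combine(
            pd.DataFrame([self.row("s", 1.0, 0.1)]),
            pd.DataFrame([self.row("s", 1.0, 0.1)]),
            fdr_threshold=0.2,
        )
        assert dual.attrs["combined_p_threshold"] == pytest.approx(0.04)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            combined_significance_threshold(1.2)


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            {"alpha": ("g1", "g2", "g3"), "beta": ("g9", "g2")},
            descriptions={"alpha": "first", "beta": "second"},
        )
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets
        assert back.descriptions == coll.descriptions

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("name_only\tdesc\n")
        with pytest.raises(ValueError, match="malformed"):
            read_gmt(path)

    def test_duplicate_set_name_rejected(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("s\td\tg1\ns\td\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(path)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSetCollection({"s": ()})
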