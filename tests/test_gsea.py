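import itertools

import numpy as np
import pytest
from scipy import stats

import mirimmune as mi
from mirimmune.gsea import DegenerateSetError


def brute_force_es(gene_ids, scores, members, w):
    """Independent step-by-step running-sum walk (the oracle).

    Hits rise by |score|^w normalised over hits; misses fall by
    1/(N - N_hits); the ES is the signed maximal absolute deviation
    (positive preferred on exact magnitude ties).
    """
    n = len(gene_ids)
    hits = [g in members for g in gene_ids]
    n_hit = sum(hits)
    denom = sum(abs(scores[i]) ** w for i in range(n) if hits[i])
    cur, hi, lo = 0.0, 0.0, 0.0
    for i in range(n):
        if hits[i]:
            cur += (abs(scores[i]) ** w) / denom if denom > 0 else 1.0 / n_hit
        else:
            cur -= 1.0 / (n - n_hit)
        hi = max(hi, cur)
        lo = min(lo, cur)
    return hi if hi + 1e-12 >= -lo else lo


def _random_instance(rng, n_max=50, k_max=10):
    n = int(rng.integers(5, n_max + 1))
    k = int(rng.integers(1, min(k_max, n - 1) + 1))
    ids = [f"g{i:03d}" for i in range(n)]
    scores = np.sort(rng.uniform(-1, 1, size=n))[::-1]
    members = frozenset(rng.choice(ids, size=k, replace=False).tolist())
    ranked = mi.RankedGeneList("m", ids, scores)
    return ranked, mi.GeneSet("S", "", members)


class TestEnrichmentScore:
    def test_single_member_at_rank_one_is_plus_one(self, toy_ranked):
        es, running, le = mi.enrichment_score(toy_ranked, mi.GeneSet("s", "", {"g1"}), 1.0)
        assert es == pytest.approx(1.0)
        assert le == ["g1"]

    def test_single_member_at_rank_n_is_minus_one(self, toy_ranked):
        es, _, le = mi.enrichment_score(toy_ranked, mi.GeneSet("s", "", {"g10"}), 1.0)
        assert es == pytest.approx(-1.0)
        assert le == ["g10"]

    def test_ten_gene_example_matches_walk_oracle(self, toy_ranked):
        members = {"g1", "g2", "g5"}
        es, running, _ = mi.enrichment_score(toy_ranked, mi.GeneSet("s", "", members), 1.0)
        expected = brute_force_es(toy_ranked.gene_ids, toy_ranked.scores, members, 1.0)
        assert es == pytest.approx(expected, abs=1e-12)
        # hand walk: hits at ranks 1,2 contribute (1.0+0.9)/2.5 = 0.76 before
        # any miss; later points are lower, so ES = 0.76
        assert es == pytest.approx(1.9 / 2.5, abs=1e-12)

    @pytest.mark.parametrize("w", [0.0, 1.0])
    def test_random_instances_match_oracle(self, w):
        rng = np.random.default_rng(42)
        for _ in range(200):
            ranked, gene_set = _random_instance(rng)
            es, running, _ = mi.enrichment_score(ranked, gene_set, w)
            expected = brute_force_es(ranked.gene_ids, ranked.scores, gene_set.members, w)
            assert es == pytest.approx(expected, abs=1e-9)
            assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12

    def test_running_sum_starts_stepwise_and_ends_at_zero(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            ranked, gene_set = _random_instance(rng)
            _, running, _ = mi.enrichment_score(ranked, gene_set, 1.0)
            assert abs(running[-1]) < 1e-9

    def test_w_zero_equals_ecdf_difference(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            ranked, gene_set = _random_instance(rng)
            es, _, _ = mi.enrichment_score(ranked, gene_set, 0.0)
            hits = np.array([g in gene_set.members for g in ranked.gene_ids])
            f_in = np.cumsum(hits) / hits.sum()
            f_out = np.cumsum(~hits) / (~hits).sum()
            diff = f_in - f_out
            i = int(np.argmax(np.abs(diff)))
            assert abs(es) == pytest.approx(abs(diff[i]), abs=1e-12)

    def test_degenerate_full_coverage_rejected(self, toy_ranked):
        full = mi.GeneSet("all", "", set(toy_ranked.gene_ids))
        with pytest.raises(DegenerateSetError):
            mi.enrichment_score(toy_ranked, full, 1.0)

    def test_empty_intersection_rejected(self, toy_ranked):
        with pytest.raises(ValueError, match="no genes"):
            mi.enrichment_score(toy_ranked, mi.GeneSet("x", "", {"absent"}), 1.0)


class TestPermutationNull:
    def test_same_seed_identical_sample(self, toy_ranked):
        params = mi.GseaParams(n_permutations=100, seed=5)
        a = mi.permutation_null(toy_ranked, 3, params)
        b = mi.permutation_null(toy_ranked, 3, params)
        assert np.array_equal(a, b)

    def test_symmetric_under_equal_scores_w0(self):
        ids = [f"g{i:02d}" for i in range(40)]
        ranked = mi.RankedGeneList("m", ids, np.full(40, 0.5))
        params = mi.GseaParams(weight_exponent=0.0, n_permutations=2000, seed=6)
        null = mi.permutation_null(ranked, 5, params)
        assert abs(null.mean()) < 2 * null.std() / np.sqrt(len(null))

    def test_null_matches_exhaustive_enumeration(self):
        """Permutation null vs the exact ES distribution over all subsets."""
        n, k = 12, 3
        ids = [f"g{i:02d}" for i in range(n)]
        scores = np.sort(np.random.default_rng(7).uniform(-1, 1, n))[::-1]
        ranked = mi.RankedGeneList("m", ids, scores)
        exact = [
            brute_force_es(ids, scores, frozenset(c), 1.0)
            for c in itertools.combinations(ids, k)
        ]
        null = mi.permutation_null(
            ranked, k, mi.GseaParams(n_permutations=4000, seed=8)
        )
        d = stats.ks_2samp(null, exact).statistic
        assert d < 0.05

    def test_subset_sampler_marginally_uniform_for_small_k(self):
        """The sparse-set sampler (k << N path) hits every position with
        equal frequency."""
        from mirimmune.gsea import _random_positions

        rng = np.random.default_rng(13)
        pos = _random_positions(rng, 20_000, 4, 200)
        counts = np.bincount(pos.ravel(), minlength=200)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_size_out_of_bounds_rejected(self, toy_ranked):
        with pytest.raises(ValueError):
            mi.permutation_null(toy_ranked, 10, mi.GseaParams())


class TestRunCollection:
    def test_small_set_excluded_and_reported(self, toy_ranked):
        sets = mi.GeneSetCollection(
            [
                mi.GeneSet("ok", "", {"g1", "g2", "g5"}),
                mi.GeneSet("tiny", "", {"g3", "g4"}),
            ]
        )
        out = mi.run_collection(toy_ranked, sets, mi.GseaParams(n_permutations=50, seed=1))
        assert [r.set_id for r in out.results] == ["ok"]
        assert out.excluded and out.excluded[0][0] == "tiny"
        assert "min_set_size" in out.excluded[0][1]

    def test_top_block_set_has_minimum_fdr(self):
        rng = np.random.default_rng(9)
        n = 200
        ids = [f"g{i:03d}" for i in range(n)]
        scores = np.sort(rng.uniform(-1, 1, n))[::-1]
        ranked = mi.RankedGeneList("m", ids, scores)
        sets = [mi.GeneSet("top5pct", "", set(ids[:10]))]
        for j in range(20):
            members = rng.choice(ids, size=10, replace=False)
            sets.append(mi.GeneSet(f"rand{j}", "", frozenset(members.tolist())))
        out = mi.run_collection(
            ranked, mi.GeneSetCollection(sets), mi.GseaParams(n_permutations=200, seed=3)
        )
        fdrs = {r.set_id: r.fdr for r in out.results}
        assert fdrs["top5pct"] == min(fdrs.values())
        # sorted by fdr ascending, so the structured set leads
        assert out.results[0].set_id == "top5pct"

    def test_p_floor_and_sorting_invariants(self, toy_ranked):
        sets = mi.GeneSetCollection(
            [mi.GeneSet(f"s{j}", "", {f"g{j + 1}", f"g{j + 2}", f"g{j + 3}"}) for j in range(6)]
        )
        params = mi.GseaParams(n_permutations=100, seed=2)
        out = mi.run_collection(toy_ranked, sets, params)
        for r in out.results:
            assert r.p_nominal >= 1.0 / (params.n_permutations + 1)
            assert 0.0 <= r.fdr <= 1.0
            assert r.set_size_used >= params.min_set_size
        fdrs = [r.fdr for r in out.results]
        assert fdrs == sorted(fdrs)

    def test_same_seed_identical_results(self, toy_ranked):
        sets = mi.GeneSetCollection([mi.GeneSet("s", "", {"g2", "g4", "g7"})])
        params = mi.GseaParams(n_permutations=100, seed=11)
        a = mi.run_collection(toy_ranked, sets, params)
        b = mi.run_collection(toy_ranked, sets, params)
        assert a.results[0] == b.results[0]
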