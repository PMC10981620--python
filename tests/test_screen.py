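import numpy as np
import pandas as pd
import pytest

import mirimmune as mi
from mirimmune.screen import OTHER_IMMUNE, KeywordConfig


def _term(term_id, name, description=""):
    return pd.Series({"term_id": term_id, "name": name, "description": description})


def _table(names):
    return mi.GoTermTable(
        pd.DataFrame(
            {
                "term_id": [f"GO:{i:07d}" for i in range(1, len(names) + 1)],
                "name": names,
                "description": ["" for _ in names],
            }
        )
    )


class TestFilter:
    def test_substring_hit_retained(self):
        table = _table(["T cell activation"])
        subset, matched = mi.filter_immune_terms(table, KeywordConfig())
        assert len(subset) == 1
        assert "t cell" in matched["GO:0000001"]

    def test_no_hit_excluded(self):
        table = _table(["mitochondrion organization"])
        subset, _ = mi.filter_immune_terms(table, KeywordConfig())
        assert len(subset) == 0

    def test_filter_is_monotone_in_vocabulary(self):
        names = [
            "T cell activation", "mitochondrion organization",
            "interferon signaling", "axon guidance", "response to wounding",
        ]
        table = _table(names)
        small = KeywordConfig(keywords=["t cell"])
        bigger = KeywordConfig(keywords=["t cell", "interferon", "wounding"])
        kept_small, _ = mi.filter_immune_terms(table, small)
        kept_big, _ = mi.filter_immune_terms(table, bigger)
        assert set(kept_small.term_ids) <= set(kept_big.term_ids)

    def test_description_field_matching_optional(self):
        table = mi.GoTermTable(
            pd.DataFrame(
                {
                    "term_id": ["GO:1"],
                    "name": ["some process"],
                    "description": ["involves cytokine storms"],
                }
            )
        )
        name_only, _ = mi.filter_immune_terms(table, KeywordConfig(match_fields=("name",)))
        both, _ = mi.filter_immune_terms(
            table, KeywordConfig(match_fields=("name", "description"))
        )
        assert len(name_only) == 0 and len(both) == 1


class TestCategories:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("regulation of immune response", "immune response regulation"),
            ("inflammatory response to wounding", "inflammatory response"),
            (
                "antigen processing and presentation of peptide antigen",
                "antigen processing & presentation",
            ),
        ],
    )
    def test_named_category_assignments(self, name, expected):
        cats = mi.assign_categories(_term("GO:1", name), KeywordConfig())
        assert expected in cats

    def test_multi_category_membership_allowed(self):
        cats = mi.assign_categories(
            _term("GO:1", "cytokine production in inflammatory response"),
            KeywordConfig(),
        )
        assert "inflammatory response" in cats
        assert "cytokine production & signalling" in cats

    def test_uncategorised_immune_term_goes_to_residual_bin(self):
        cats = mi.assign_categories(_term("GO:1", "complement activation"), KeywordConfig())
        assert cats == [OTHER_IMMUNE]

    def test_default_category_count_is_seven(self):
        assert len(KeywordConfig().categories) == 7

    def test_yaml_round_trip(self, tmp_path):
        cfg = KeywordConfig()
        p = tmp_path / "kw.yaml"
        cfg.to_yaml(p)
        back = KeywordConfig.from_yaml(p)
        assert back.keywords == cfg.keywords
        assert back.category_map == cfg.category_map


def _results(pairs):
    return [
        mi.EnrichmentResult(tid, 0.5, 1.0, p, p, 5, []) for tid, p in pairs
    ]


class TestCounting:
    def _immune_table(self):
        return mi.GoTermTable(
            pd.DataFrame(
                {
                    "term_id": ["GO:1", "GO:2", "GO:3"],
                    "name": [
                        "inflammatory response",
                        "acute inflammatory reaction",
                        "chronic inflammatory state",
                    ],
                    "description": ["", "", ""],
                }
            )
        )

    def test_all_null_counts_zero(self):
        score = mi.count_significant(
            _results([("GO:1", 0.5), ("GO:2", 0.5), ("GO:3", 0.5)]),
            self._immune_table(),
            KeywordConfig(),
        )
        assert score.n_significant_total == 0
        assert score.n_terms_tested == 3

    def test_three_significant_terms_in_one_category(self):
        score = mi.count_significant(
            _results([("GO:1", 0.01), ("GO:2", 0.01), ("GO:3", 0.01)]),
            self._immune_table(),
            KeywordConfig(),
        )
        assert score.n_significant_total == 3
        assert score.n_significant_by_category["inflammatory response"] == 3
        assert all(
            v == 0
            for c, v in score.n_significant_by_category.items()
            if c != "inflammatory response"
        )
        assert score.min_log2p_by_category["inflammatory response"] == pytest.approx(
            -np.log2(0.01)
        )

    def test_fdr_criterion_switch(self):
        results = [mi.EnrichmentResult("GO:1", 0.5, 1.0, 0.01, 0.2, 5, [])]
        by_p = mi.count_significant(results, self._immune_table(), KeywordConfig())
        by_fdr = mi.count_significant(
            results, self._immune_table(), KeywordConfig(), criterion="fdr"
        )
        assert by_p.n_significant_total == 1
        assert by_fdr.n_significant_total == 0

    def test_non_immune_results_ignored(self):
        score = mi.count_significant(
            _results([("GO:1", 0.01), ("GO:999", 0.001)]),
            self._immune_table(),
            KeywordConfig(),
        )
        assert score.n_terms_tested == 1


class TestRanking:
    def _score(self, mid, total, colour):
        return mi.MiRNAImmuneScore(
            mirna_id=mid,
            n_significant_total=total,
            n_significant_by_category={"catA": total},
            min_log2p_by_category={"catA": colour},
            n_terms_tested=10,
        )

    def test_descending_by_count(self):
        df = mi.rank_mirnas([self._score("a", 1, 1.0), self._score("b", 5, 1.0)])
        assert list(df["mirna_id"]) == ["b", "a"]
        assert list(df["rank"]) == [1, 2]

    def test_count_tie_broken_by_colour_then_id(self):
        df = mi.rank_mirnas(
            [self._score("b", 3, 2.0), self._score("a", 3, 5.0), self._score("c", 3, 2.0)]
        )
        assert list(df["mirna_id"]) == ["a", "b", "c"]

    def test_bubble_table_rows_match_nonzero_cells(self):
        scores = [
            mi.MiRNAImmuneScore(
                "m1", 3,
                {"catA": 2, "catB": 1, "catC": 0},
                {"catA": 5.0, "catB": 3.0, "catC": 0.0},
                10,
            ),
            mi.MiRNAImmuneScore(
                "m2", 0, {"catA": 0, "catB": 0, "catC": 0},
                {"catA": 0.0, "catB": 0.0, "catC": 0.0}, 10,
            ),
        ]
        bt = mi.bubble_table(scores)
        expected_rows = sum(
            1 for s in scores for c, v in s.n_significant_by_category.items() if v > 0
        )
        assert len(bt) == expected_rows == 2
        assert set(bt.columns) == {"mirna_id", "category", "count", "neg_log2_p"}


class TestNullCalibration:
    def test_expected_counts_match_alpha_when_genes_are_iid(self):
        """With no latent structure at all (regulator and gene loadings
        zero) genes are i.i.d., the gene-permutation null is exact, and
        the expected significant-immune-term count per miRNA is
        alpha * n_immune_terms within binomial tolerance."""
        cfg = mi.CohortConfig(
            n_samples=100, n_genes=800, n_mirnas=10, n_immune_sets=10,
            genes_per_set=10, regulator_loading=0.0, gene_loading=0.0, seed=55,
        )
        genes, mirnas, truth = mi.generate_cohort(cfg)
        table, sets, _ = mi.generate_go_universe(
            60, 1.0 / 3.0, mi.screen.DEFAULT_KEYWORDS, seed=56, truth=truth
        )
        params = mi.GseaParams(n_permutations=200, seed=57)
        _, scores, _ = mi.screen_cohort(mirnas, genes, table, sets, params=params)
        n_tests = sum(s.n_terms_tested for s in scores)
        n_hits = sum(s.n_significant_total for s in scores)
        expected = 0.05 * n_tests
        tol = 3 * np.sqrt(n_tests * 0.05 * 0.95)
        assert abs(n_hits - expected) <= tol


class TestScreenRecovery:
    def test_planted_regulator_ranks_first(self, small_cohort, small_universe):
        _, genes, mirnas, truth = small_cohort
        table, sets, _ = small_universe
        params = mi.GseaParams(n_permutations=200, seed=77)
        ranking, scores, _ = mi.screen_cohort(mirnas, genes, table, sets, params=params)
        assert ranking.iloc[0]["mirna_id"] == truth.planted_regulators[0]
        planted_total = ranking.iloc[0]["n_significant_total"]
        background = ranking.iloc[1:]["n_significant_total"]
        assert planted_total > np.percentile(background, 95)
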