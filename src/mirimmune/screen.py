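"""The immune-prioritisation screen: keyword-filter GO terms, assign the
7 immunological categories, count significant immune terms per miRNA,
and rank miRNAs.

A GO term is immunological when any configured keyword occurs
case-insensitively as a substring of its name (and/or description).
Retained terms are assigned to every category whose keyword list
matches — GO terms are not partitioned by theme, so a term may belong to
several categories — with a residual "other immune" bin for retained
terms matching no category. Each miRNA's score is the number of immune
terms whose GSEA significance passes the threshold (default nominal
p < 0.05; FDR selectable), and miRNAs are ranked by that count.

The default vocabulary and 7-category map are editable stand-ins for a
curated list: everything downstream is parameterised by the
:class:`KeywordConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .containers import GoTermTable
from .correlation import rank_all_mirnas
from .gsea import GseaParams, run_collection

OTHER_IMMUNE = "other immune"

DEFAULT_KEYWORDS = [
    "immune", "immun", "inflamm", "leukocyte", "lymphocyte", "t cell",
    "b cell", "cytokine", "chemokine", "interferon", "interleukin",
    "antigen", "mhc", "natural killer", "macrophage", "dendritic",
    "phagocyt", "complement", "toll-like", "myeloid",
]

DEFAULT_CATEGORIES = {
    "immune response regulation": ["immune response", "immune system", "immunity"],
    "inflammatory response": ["inflamm"],
    "lymphocyte activation & differentiation": [
        "lymphocyte", "t cell", "b cell", "natural killer",
    ],
    "myeloid & dendritic cell activation": [
        "myeloid", "dendritic", "macrophage", "phagocyt",
    ],
    "antigen processing & presentation": ["antigen", "mhc"],
    "cytokine production & signalling": [
        "cytokine", "chemokine", "interferon", "interleukin",
    ],
    "leukocyte migration": ["leukocyte"],
}


@dataclass
class KeywordConfig:
    """Vocabulary for immune-term filtering and the category map."""

    keywords: list = field(default_factory=lambda: list(DEFAULT_KEYWORDS))
    category_map: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CATEGORIES.items()}
    )
    match_fields: tuple = ("name",)

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("keyword list is empty")
        self.keywords = [k.lower() for k in self.keywords]
        self.category_map = {
            c: [k.lower() for k in kws] for c, kws in self.category_map.items()
        }
        bad = set(self.match_fields) - {"name", "description"}
        if bad:
            raise ValueError(f"unknown match fields: {bad}")

    @property
    def categories(self) -> list:
        return list(self.category_map)

    @classmethod
    def from_yaml(cls, path) -> "KeywordConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            keywords=raw.get("keywords", list(DEFAULT_KEYWORDS)),
            category_map=raw.get("categories", dict(DEFAULT_CATEGORIES)),
            match_fields=tuple(raw.get("match_fields", ("name",))),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "keywords": list(self.keywords),
                    "categories": {k: list(v) for k, v in self.category_map.items()},
                    "match_fields": list(self.match_fields),
                },
                fh,
                sort_keys=False,
            )


@dataclass
class MiRNAImmuneScore:
    """Per-miRNA summary of the screen: the ranking statistic."""

    mirna_id: str
    n_significant_total: int
    n_significant_by_category: dict
    min_log2p_by_category: dict  # -log2 of the best p per category (colour score)
    n_terms_tested: int


def _matches(text: str, keywords) -> list:
    low = text.lower()
    return [k for k in keywords if k in low]


def filter_immune_terms(table: GoTermTable, cfg: KeywordConfig):
    """Retain GO terms with any keyword substring in a configured field.

    Returns ``(subset GoTermTable, matched)`` where ``matched`` maps each
    retained term_id to the list of keywords that hit. The filter is
    monotone in the vocabulary: adding a keyword can only add terms.
    """
    matched = {}
    keep_rows = []
    for _, row in table.records.iterrows():
        hits = []
        for fieldname in cfg.match_fields:
            hits += [k for k in _matches(str(row[fieldname]), cfg.keywords) if k not in hits]
        if hits:
            matched[row["term_id"]] = hits
            keep_rows.append(row)
    subset = GoTermTable(
        pd.DataFrame(keep_rows, columns=table.records.columns).reset_index(drop=True)
    )
    return subset, matched


def assign_categories(term_record, cfg: KeywordConfig) -> list:
    """Categories whose keyword lists match this (retained) term.

    A retained term matching no category goes to the residual
    ``"other immune"`` bin so it is counted, not silently dropped.
    """
    texts = [str(term_record[f]) for f in cfg.match_fields]
    cats = []
    for cat, kws in cfg.category_map.items():
        if any(_matches(t, kws) for t in texts):
            cats.append(cat)
    return cats or [OTHER_IMMUNE]


def count_significant(
    results,
    immune_terms: GoTermTable,
    cfg: KeywordConfig,
    alpha: float = 0.05,
    criterion: str = "p_nominal",
) -> MiRNAImmuneScore:
    """Count significant immune terms for one miRNA's enrichment results.

    ``results`` is an iterable of EnrichmentResult (or a
    CollectionResult) whose set_ids are GO term ids; only terms present
    in ``immune_terms`` are considered. The per-category colour score is
    -log2 of the best p among all tested terms of the category (when the
    category has a significant term, the best p is attained by one).
    """
    if criterion not in ("p_nominal", "fdr"):
        raise ValueError(f"criterion must be 'p_nominal' or 'fdr', got {criterion!r}")
    recs = immune_terms.records.set_index("term_id")
    mirna_id = getattr(results, "mirna_id", "")
    cats = list(cfg.category_map) + [OTHER_IMMUNE]
    counts = {c: 0 for c in cats}
    best_p = {c: np.inf for c in cats}
    total = 0
    tested = 0
    for r in results:
        if r.set_id not in recs.index:
            continue
        tested += 1
        value = r.p_nominal if criterion == "p_nominal" else r.fdr
        term_cats = assign_categories(recs.loc[r.set_id], cfg)
        significant = value < alpha
        if significant:
            total += 1
        for c in term_cats:
            if significant:
                counts[c] += 1
            best_p[c] = min(best_p[c], value)
    if tested == 0:
        raise ValueError(f"no immune terms among results for {mirna_id!r}")
    min_log2p = {
        c: (-np.log2(max(p, 1e-300)) if np.isfinite(p) else 0.0)
        for c, p in best_p.items()
    }
    return MiRNAImmuneScore(
        mirna_id=mirna_id,
        n_significant_total=total,
        n_significant_by_category=counts,
        min_log2p_by_category=min_log2p,
        n_terms_tested=tested,
    )


def rank_mirnas(scores) -> pd.DataFrame:
    """Rank miRNAs by significant immune-term count (the screen output).

    Descending by count; ties by the summed per-category colour score
    descending, then miRNA id. Rank 1 is the screen hit.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("no scores to rank")
    rows = [
        {
            "mirna_id": s.mirna_id,
            "n_significant_total": s.n_significant_total,
            "colour_score": float(sum(s.min_log2p_by_category.values())),
            "n_terms_tested": s.n_terms_tested,
        }
        for s in scores
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["n_significant_total", "colour_score", "mirna_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def bubble_table(scores) -> pd.DataFrame:
    """Long-format (miRNA, category, count, -log2 p) table for bubble plots.

    One row per (miRNA, category) with a nonzero significant count:
    bubble size is the count, colour the -log2 best p.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("no scores to tabulate")
    rows = []
    for s in scores:
        for cat, count in s.n_significant_by_category.items():
            if count > 0:
                rows.append(
                    {
                        "mirna_id": s.mirna_id,
                        "category": cat,
                        "count": count,
                        "neg_log2_p": s.min_log2p_by_category[cat],
                    }
                )
    return pd.DataFrame(rows, columns=["mirna_id", "category", "count", "neg_log2_p"])


def screen_cohort(
    mirnas,
    genes,
    go_table: GoTermTable,
    go_sets,
    cfg: KeywordConfig | None = None,
    params: GseaParams | None = None,
    alpha: float = 0.05,
    criterion: str = "p_nominal",
):
    """Run the full screen over every miRNA in the cohort.

    For each miRNA: transcriptome-wide ranked gene list, pre-ranked GSEA
    over the complete GO collection, then significant-immune-term
    counting restricted to the keyword-filtered terms. Returns
    ``(ranking DataFrame, scores list, per-miRNA CollectionResult dict)``.
    """
    cfg = cfg or KeywordConfig()
    params = params or GseaParams()
    immune_terms, _ = filter_immune_terms(go_table, cfg)
    ranked_lists = rank_all_mirnas(mirnas, genes)
    scores = []
    collections = {}
    for mirna_id, ranked in ranked_lists.items():
        coll = run_collection(ranked, go_sets, params)
        collections[mirna_id] = coll
        scores.append(count_significant(coll, immune_terms, cfg, alpha, criterion))
    return rank_mirnas(scores), scores, collections
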