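"""Synthetic tumour cohorts with planted immune-regulator miRNAs.

The generator emulates the statistical structure the screen must detect:
a per-sample latent immune-activity factor ``A_s ~ N(0, 1)`` couples a
small number of *planted* miRNAs to the members of immune gene sets,

    planted miRNA:    x_{m,s} = gamma * A_s + eps,   eps ~ N(0, sigma^2)
    immune-set gene:  y_{g,s} = beta  * A_s + eps,

while every other miRNA and gene is independent noise whose variance is
matched to the planted features, ``N(0, sigma^2 + max(gamma, beta)^2)``,
so nothing can be detected from marginal variance alone. The expected
Pearson correlation between a planted miRNA and an immune gene is

    rho = gamma * beta / sqrt((gamma^2 + sigma^2) * (beta^2 + sigma^2)),

which equals 0.5 at the default gamma = beta = sigma = 1.

A matching GO universe (immune terms identifiable by keyword, each with a
gene set drawn from the immune or background pool) and an immune
signature collection (default 68 signatures) complete the inputs the
screen needs, with the ground truth recorded for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    GoTermTable,
)


class ConfigError(ValueError):
    """A generator configuration violates an invariant."""


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults are the screen's reference conditions: 200 patients,
    4000 genes of which 40 immune sets x 10 genes load on the latent
    factor (immune genes a ~10% minority, as in a real transcriptome),
    20 miRNAs with one planted regulator, and unit loadings and noise
    (planted-pair correlation 0.5).
    """

    n_samples: int = 200
    n_genes: int = 4000
    n_mirnas: int = 20
    n_immune_sets: int = 40
    genes_per_set: int = 10
    planted_regulators: tuple = (0,)
    regulator_loading: float = 1.0  # gamma
    gene_loading: float = 1.0  # beta
    noise_sd: float = 1.0  # sigma
    noise_dist: str = "gaussian"  # or "student_t" (heavier tails, sd-matched)
    student_t_df: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ConfigError("n_samples must be >= 3")
        if min(self.n_genes, self.n_mirnas, self.n_immune_sets, self.genes_per_set) < 1:
            raise ConfigError("counts must be positive")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.n_immune_sets * self.genes_per_set > self.n_genes:
            raise ConfigError(
                f"immune genes ({self.n_immune_sets} sets x {self.genes_per_set}) "
                f"exceed n_genes={self.n_genes}"
            )
        bad = [m for m in self.planted_regulators if not 0 <= m < self.n_mirnas]
        if bad:
            raise ConfigError(f"planted regulator indices out of range: {bad}")
        if self.noise_dist not in ("gaussian", "student_t"):
            raise ConfigError(f"unknown noise_dist {self.noise_dist!r}")

    @property
    def expected_pairwise_correlation(self) -> float:
        g, b, s = self.regulator_loading, self.gene_loading, self.noise_sd
        return g * b / np.sqrt((g * g + s * s) * (b * b + s * s))


@dataclass
class SyntheticTruth:
    """Ground-truth record of a generated cohort, for recovery testing."""

    planted_regulators: list  # miRNA IDs
    immune_set_ids: list
    expected_pairwise_correlation: float
    seed: int
    immune_sets: dict = field(default_factory=dict)  # set_id -> member gene IDs
    immune_gene_ids: list = field(default_factory=list)
    background_gene_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)
    mirna_ids: list = field(default_factory=list)
    latent_factor: list = field(default_factory=list)  # A_s per sample

    def to_jsonable(self) -> dict:
        return {
            "planted_regulators": list(self.planted_regulators),
            "immune_set_ids": list(self.immune_set_ids),
            "expected_pairwise_correlation": float(self.expected_pairwise_correlation),
            "seed": int(self.seed),
            "immune_sets": {k: list(v) for k, v in self.immune_sets.items()},
            "immune_gene_ids": list(self.immune_gene_ids),
            "background_gene_ids": list(self.background_gene_ids),
            "gene_ids": list(self.gene_ids),
            "mirna_ids": list(self.mirna_ids),
            "latent_factor": [float(a) for a in self.latent_factor],
        }


def _noise(rng: np.random.Generator, sd: float, shape, config: CohortConfig) -> np.ndarray:
    if config.noise_dist == "gaussian":
        return rng.normal(0.0, sd, size=shape)
    # Student-t rescaled to the requested standard deviation
    df = config.student_t_df
    scale = sd / np.sqrt(df / (df - 2.0))
    return rng.standard_t(df, size=shape) * scale


def generate_cohort(config: CohortConfig):
    """Generate (gene matrix, miRNA matrix, truth) under the latent-factor model.

    Deterministic under ``config.seed``: the same config yields
    bit-identical matrices.
    """
    rng = np.random.default_rng(config.seed)
    n_immune_genes = config.n_immune_sets * config.genes_per_set

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    mirna_ids = [f"MIR-{i:04d}" for i in range(config.n_mirnas)]
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]

    immune_idx = np.sort(
        rng.choice(config.n_genes, size=n_immune_genes, replace=False)
    )
    immune_gene_ids = [gene_ids[i] for i in immune_idx]
    background_gene_ids = [g for g in gene_ids if g not in set(immune_gene_ids)]

    immune_sets = {}
    for s in range(config.n_immune_sets):
        sid = f"IMMSET{s:03d}"
        block = immune_gene_ids[s * config.genes_per_set: (s + 1) * config.genes_per_set]
        immune_sets[sid] = list(block)

    A = rng.normal(0.0, 1.0, size=config.n_samples)  # latent immune activity
    gamma, beta, sigma = config.regulator_loading, config.gene_loading, config.noise_sd
    bg_sd = float(np.sqrt(sigma**2 + max(gamma, beta) ** 2))

    genes = _noise(rng, bg_sd, (config.n_genes, config.n_samples), config)
    genes[immune_idx, :] = beta * A + _noise(
        rng, sigma, (n_immune_genes, config.n_samples), config
    )

    mirnas = _noise(rng, bg_sd, (config.n_mirnas, config.n_samples), config)
    planted = np.asarray(sorted(config.planted_regulators), dtype=int)
    mirnas[planted, :] = gamma * A + _noise(
        rng, sigma, (len(planted), config.n_samples), config
    )

    gene_matrix = ExpressionMatrix(
        pd.DataFrame(genes, index=gene_ids, columns=sample_ids),
        feature_kind="gene",
        unit="synthetic-log2-like",
    )
    mirna_matrix = ExpressionMatrix(
        pd.DataFrame(mirnas, index=mirna_ids, columns=sample_ids),
        feature_kind="mirna",
        unit="synthetic-log2-like",
    )
    truth = SyntheticTruth(
        planted_regulators=[mirna_ids[i] for i in planted],
        immune_set_ids=list(immune_sets),
        expected_pairwise_correlation=config.expected_pairwise_correlation,
        seed=config.seed,
        immune_sets=immune_sets,
        immune_gene_ids=immune_gene_ids,
        background_gene_ids=background_gene_ids,
        gene_ids=gene_ids,
        mirna_ids=mirna_ids,
        latent_factor=A.tolist(),
    )
    return gene_matrix, mirna_matrix, truth


# name templates for immune terms; {kw} is replaced by a vocabulary word
_IMMUNE_TEMPLATES = (
    "regulation of {kw}",
    "positive regulation of {kw}",
    "negative regulation of {kw}",
    "{kw} response",
    "{kw} activation",
    "{kw} mediated signaling pathway",
)

# building blocks for non-immune term names; every candidate is checked
# against the vocabulary so background terms are guaranteed keyword-free
_SAFE_NOUNS = (
    "mitochondrion", "ribosome biogenesis", "chromatin remodeling",
    "cytoskeleton", "golgi vesicle transport", "dna repair",
    "rna splicing", "lipid metabolic process", "glycolytic process",
    "axon guidance", "protein folding", "oxidative phosphorylation",
    "telomere maintenance", "nucleotide biosynthesis", "autophagosome",
    "spindle assembly", "membrane fusion", "histone modification",
    "peroxisome organization", "mrna export",
)
_SAFE_TEMPLATES = (
    "{n}", "regulation of {n}", "{n} organization", "{n} assembly",
)


def generate_go_universe(
    n_terms: int,
    immune_fraction: float,
    keyword_vocab,
    seed: int,
    *,
    truth: SyntheticTruth,
    set_size_range: tuple = (5, 20),
):
    """Generate a GO universe whose immune terms are identifiable by keyword.

    Returns ``(GoTermTable, GeneSetCollection, immune_term_ids)``. Immune
    terms embed at least one vocabulary word in their name and draw their
    gene sets from the cohort's immune gene pool; background terms are
    verified free of every vocabulary word and draw from background
    genes. Set sizes are uniform over ``set_size_range``.
    """
    if not keyword_vocab:
        raise ConfigError("keyword vocabulary is empty")
    if not 0.0 < immune_fraction < 1.0:
        raise ConfigError("immune_fraction must be in (0, 1)")
    n_immune = int(round(n_terms * immune_fraction))
    if n_immune < 1:
        raise ConfigError(
            f"immune_fraction={immune_fraction} x n_terms={n_terms} yields no immune terms"
        )
    vocab = [k.lower() for k in keyword_vocab]
    rng = np.random.default_rng(seed)

    safe_names = []
    for tmpl in _SAFE_TEMPLATES:
        for noun in _SAFE_NOUNS:
            name = tmpl.format(n=noun)
            if not any(k in name.lower() for k in vocab):
                safe_names.append(name)
    if len(safe_names) < n_terms - n_immune:
        raise ConfigError(
            f"cannot build {n_terms - n_immune} keyword-free background names "
            f"under this vocabulary (only {len(safe_names)} available)"
        )

    # interleave immune/background terms so immune IDs are not a prefix
    is_immune = np.zeros(n_terms, dtype=bool)
    is_immune[rng.choice(n_terms, size=n_immune, replace=False)] = True

    lo, hi = set_size_range
    records = []
    sets = []
    immune_term_ids = []
    bg_order = rng.permutation(len(safe_names))
    n_bg_used = 0
    n_imm_used = 0
    for t in range(n_terms):
        term_id = f"GO:{t + 1:07d}"
        size = int(rng.integers(lo, hi + 1))
        if is_immune[t]:
            kw = vocab[n_imm_used % len(vocab)]
            tmpl = _IMMUNE_TEMPLATES[int(rng.integers(len(_IMMUNE_TEMPLATES)))]
            name = tmpl.format(kw=kw)
            members = rng.choice(truth.immune_gene_ids, size=size, replace=False)
            immune_term_ids.append(term_id)
            n_imm_used += 1
        else:
            name = safe_names[bg_order[n_bg_used % len(safe_names)]]
            members = rng.choice(truth.background_gene_ids, size=size, replace=False)
            n_bg_used += 1
        desc = f"synthetic GO term modelling {name}"
        records.append({"term_id": term_id, "name": name, "description": desc})
        sets.append(GeneSet(term_id, name, frozenset(members.tolist())))

    table = GoTermTable(pd.DataFrame(records, columns=["term_id", "name", "description"]))
    return table, GeneSetCollection(sets), immune_term_ids


def generate_signature_collection(
    n_signatures: int = 68,
    *,
    truth: SyntheticTruth,
    seed: int = 0,
    contamination: float = 0.2,
    signature_size: int = 30,
) -> GeneSetCollection:
    """Generate immune signature gene sets (default 68, mirroring the
    published anti-cancer immune signature panel the screen correlates
    against).

    Each signature draws ``(1 - contamination)`` of its members from the
    immune gene pool and the rest from background genes; at
    ``contamination=1.0`` signatures are pure background and the
    downstream miRNA/signature correlation is a null.
    """
    if n_signatures < 1:
        raise ConfigError("n_signatures must be >= 1")
    if not 0.0 <= contamination <= 1.0:
        raise ConfigError("contamination must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_signatures):
        n_imm = int(round((1.0 - contamination) * signature_size))
        n_bg = signature_size - n_imm
        members = []
        if n_imm:
            members += rng.choice(truth.immune_gene_ids, size=n_imm, replace=False).tolist()
        if n_bg:
            members += rng.choice(truth.background_gene_ids, size=n_bg, replace=False).tolist()
        sets.append(
            GeneSet(f"SIG{i + 1:03d}", f"synthetic immune signature {i + 1}", frozenset(members))
        )
    return GeneSetCollection(sets)
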