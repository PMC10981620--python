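"""End-to-end orchestration of the screen with seeded determinism.

Stages: simulate (or load) -> per-miRNA ranked lists -> pre-ranked GSEA
-> immune filtering/counting/ranking -> ssGSEA -> miRNA/signature
Spearman correlation. A single master seed deterministically derives one
seed per stage (seed-sequence on (master, stage index)), so re-running
with the same config reproduces every output byte for byte. The run
manifest records the package version, per-stage seeds, input file
hashes, and row counts of every table written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from .containers import ExpressionMatrix, GeneSetCollection, GoTermTable
from .gsea import GseaParams
from .screen import KeywordConfig, screen_cohort
from .simulate import (
    CohortConfig,
    generate_cohort,
    generate_go_universe,
    generate_signature_collection,
)
from .ssgsea import score_matrix
from .signatures import correlate_mirnas_with_signatures, directionality_summary

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of a full screen run.

    With ``simulate=True`` (default) the cohort, GO universe and
    signature collection are generated; otherwise the five input paths
    must point to existing files.
    """

    outdir: str = "screen_output"
    seed: int = 0
    simulate: bool = True
    # synthetic-cohort study conditions (used when simulate=True)
    cohort: CohortConfig | None = None
    n_go_terms: int = 120
    immune_fraction: float = 1.0 / 3.0
    n_signatures: int = 68
    signature_contamination: float = 0.2
    # input paths (used when simulate=False)
    gene_matrix: str | None = None
    mirna_matrix: str | None = None
    go_table: str | None = None
    go_gmt: str | None = None
    signatures_gmt: str | None = None
    # analysis parameters
    keywords_yaml: str | None = None
    gsea: GseaParams = field(default_factory=GseaParams)
    alpha: float = 0.05
    criterion: str = "p_nominal"
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort")) if "cohort" in raw else None
        gsea = GseaParams(**raw.pop("gsea")) if "gsea" in raw else GseaParams()
        return cls(cohort=cohort, gsea=gsea, **raw)


def stage_seed(master: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence((int(master), int(stage_index)))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_full_screen(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest.

    Any stage error aborts with the stage name after removing that
    stage's partial outputs. All referenced input paths are checked
    before any computation starts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if not config.simulate:
        paths = {
            "gene_matrix": config.gene_matrix,
            "mirna_matrix": config.mirna_matrix,
            "go_table": config.go_table,
            "go_gmt": config.go_gmt,
            "signatures_gmt": config.signatures_gmt,
        }
        missing = [k for k, v in paths.items() if v is None or not Path(v).exists()]
        if missing:
            raise PipelineError(f"startup: missing input path(s): {', '.join(missing)}")
    if config.keywords_yaml is not None and not Path(config.keywords_yaml).exists():
        raise PipelineError(f"startup: keywords file not found: {config.keywords_yaml}")

    cfg_kw = (
        KeywordConfig.from_yaml(config.keywords_yaml)
        if config.keywords_yaml
        else KeywordConfig()
    )
    manifest = {
        "version": _version(),
        "master_seed": int(config.seed),
        "stages": {},
    }
    written: list = []  # outputs of the stage currently running

    def _stage(name):
        logger.info("stage: %s", name)
        written.clear()
        manifest["stages"][name] = {"seed": None, "outputs": {}}
        return manifest["stages"][name]

    def _write(stage_rec, name, writer, *args, n_rows=None):
        path = outdir / name
        writer(*args, path) if args else writer(path)
        written.append(path)
        stage_rec["outputs"][name] = {"sha256": _sha256(path)}
        if n_rows is not None:
            stage_rec["outputs"][name]["rows"] = int(n_rows)

    try:
        # ---- stage 0: inputs -------------------------------------------------
        rec = _stage("inputs")
        if config.simulate:
            seed0 = stage_seed(config.seed, 0)
            rec["seed"] = seed0
            cohort_cfg = config.cohort if config.cohort is not None else CohortConfig(seed=seed0)
            genes, mirnas, truth = generate_cohort(cohort_cfg)
            go_table, go_sets, immune_term_ids = generate_go_universe(
                config.n_go_terms,
                config.immune_fraction,
                cfg_kw.keywords,
                stage_seed(config.seed, 1),
                truth=truth,
            )
            signatures = generate_signature_collection(
                config.n_signatures,
                truth=truth,
                seed=stage_seed(config.seed, 2),
                contamination=config.signature_contamination,
            )
            _write(rec, "genes.tsv", lambda p: mio.write_expression_tsv(genes, p, seed=seed0),
                   n_rows=genes.shape[0])
            _write(rec, "mirnas.tsv", lambda p: mio.write_expression_tsv(mirnas, p, seed=seed0),
                   n_rows=mirnas.shape[0])
            _write(rec, "go_terms.tsv", lambda p: mio.write_go_table(go_table, p),
                   n_rows=len(go_table))
            _write(rec, "go_sets.gmt", lambda p: mio.write_gmt(go_sets, p),
                   n_rows=len(go_sets))
            _write(rec, "signatures.gmt", lambda p: mio.write_gmt(signatures, p),
                   n_rows=len(signatures))

            def _write_truth(p):
                payload = truth.to_jsonable()
                payload["immune_term_ids"] = immune_term_ids
                Path(p).write_text(json.dumps(payload, indent=1, sort_keys=True))

            _write(rec, "truth.json", _write_truth)
        else:
            genes = mio.read_expression_tsv(config.gene_matrix, "gene")
            mirnas = mio.read_expression_tsv(config.mirna_matrix, "mirna")
            go_table = mio.read_go_table(config.go_table)
            go_sets = mio.read_gmt(config.go_gmt)
            signatures = mio.read_gmt(config.signatures_gmt)
            for key, p in paths.items():
                rec["outputs"][key] = {"sha256": _sha256(Path(p))}

        # ---- stage 1: screen (correlate + GSEA + count + rank) ---------------
        rec = _stage("screen")
        gsea_params = GseaParams(
            weight_exponent=config.gsea.weight_exponent,
            n_permutations=config.gsea.n_permutations,
            min_set_size=config.gsea.min_set_size,
            max_set_size=config.gsea.max_set_size,
            seed=stage_seed(config.seed, 3),
        )
        rec["seed"] = gsea_params.seed
        ranking, scores, collections = screen_cohort(
            mirnas, genes, go_table, go_sets, cfg_kw, gsea_params,
            alpha=config.alpha, criterion=config.criterion,
        )
        enrich_dir = outdir / "enrichment"
        enrich_dir.mkdir(exist_ok=True)
        for mirna_id, coll in collections.items():
            path = enrich_dir / f"{mirna_id}.tsv"
            mio.write_results_table(coll.results, path, seed=gsea_params.seed)
            written.append(path)
        rec["outputs"]["enrichment/"] = {"tables": len(collections)}

        def _write_ranking(p):
            with open(p, "w") as fh:
                fh.write(mio._comment_header(config.seed))
                ranking.to_csv(fh, sep="\t", index=False, float_format="%.6g")

        _write(rec, "ranked_mirnas.tsv", _write_ranking, n_rows=len(ranking))

        from .screen import bubble_table

        bubbles = bubble_table(scores)

        def _write_bubbles(p):
            with open(p, "w") as fh:
                fh.write(mio._comment_header(config.seed))
                bubbles.to_csv(fh, sep="\t", index=False, float_format="%.6g")

        _write(rec, "bubble_table.tsv", _write_bubbles, n_rows=len(bubbles))

        # ---- stage 2: ssGSEA --------------------------------------------------
        rec = _stage("ssgsea")
        sig_scores = score_matrix(
            genes, signatures, alpha=config.ssgsea_alpha,
            normalize=config.ssgsea_normalize,
        )

        def _write_scores(p):
            with open(p, "w") as fh:
                fh.write(mio._comment_header(config.seed))
                sig_scores.scores.to_csv(fh, sep="\t", float_format="%.6g",
                                         index_label="signature_id")

        _write(rec, "signature_scores.tsv", _write_scores,
               n_rows=len(sig_scores.signature_ids))

        # ---- stage 3: signature correlation ----------------------------------
        rec = _stage("signature_correlation")
        corr = correlate_mirnas_with_signatures(mirnas, sig_scores)
        summaries = [directionality_summary(corr, m) for m in corr.mirna_ids]

        def _write_df(df, index_label):
            def w(p):
                with open(p, "w") as fh:
                    fh.write(mio._comment_header(config.seed))
                    df.to_csv(fh, sep="\t", float_format="%.6g", index_label=index_label)
            return w

        _write(rec, "signature_rho.tsv", _write_df(corr.rho, "mirna_id"),
               n_rows=len(corr.mirna_ids))
        _write(rec, "signature_p.tsv", _write_df(corr.p, "mirna_id"),
               n_rows=len(corr.mirna_ids))
        _write(rec, "directionality_summary.tsv",
               lambda p: mio.write_results_table(summaries, p, seed=config.seed),
               n_rows=len(summaries))
    except PipelineError:
        raise
    except Exception as exc:
        stage = list(manifest["stages"])[-1] if manifest["stages"] else "startup"
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _version() -> str:
    from . import __version__

    return __version__
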