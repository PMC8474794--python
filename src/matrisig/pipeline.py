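"""End-to-end driver: DE -> gene-set filter -> centroid -> stratify ->
survival -> per-gene screen -> refine -> re-stratify.

The configuration is a flat mapping (typically loaded from YAML).
Either file paths or simulation blocks supply the two data worlds:

* ``expression``/``conditions`` (+ optional ``annotation``) or a
  ``simulate_fibroblast`` block;
* ``cohort``/``clinical`` or a ``simulate_cohort`` block (the simulated
  cohort is built around the centroid derived upstream).

All randomness flows from the single top-level ``seed``. Every stage
output is written as TSV under ``out_dir`` together with a JSON manifest
recording parameters and headline statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genesets, rankprod, refinement, signature, simulate, survival
from .expression import ExpressionMatrix, read_expression

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_perm: int = 1000
    alpha_de: float = 0.05
    alpha_refine: float = 0.05
    cutoff_months: float = 120.0
    endpoint: str = "DMFS"
    stratification: str = "centroid"  # or "median-split"
    covariates: tuple[str, ...] = ("er", "ln", "grade", "age", "size")
    expression: str | None = None
    conditions: str | None = None
    annotation: str | None = None
    gene_set: str | None = None  # default: bundled matrisome list
    orthologs: str | None = None
    cohort: str | None = None
    clinical: str | None = None
    subgroups: str | None = None
    simulate_fibroblast: dict | None = None
    simulate_cohort: dict | None = None
    out_dir: str = "matrisig_out"

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_refine"):
            a = getattr(self, name)
            if not 0 <= a <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cutoff_months <= 0:
            raise ValueError("cutoff_months must be > 0")
        if self.stratification not in ("centroid", "median-split"):
            raise ValueError("stratification must be 'centroid' or 'median-split'")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "covariates" in raw:
        raw["covariates"] = tuple(raw["covariates"])
    return PipelineConfig(**raw)


def _get_fibroblast(cfg: PipelineConfig) -> ExpressionMatrix:
    if cfg.expression is not None:
        return read_expression(
            cfg.expression,
            conditions_path=cfg.conditions,
            annotation_path=cfg.annotation,
        )
    if cfg.simulate_fibroblast is None:
        raise ValueError("config needs 'expression' or a 'simulate_fibroblast' block")
    block = dict(cfg.simulate_fibroblast)
    block.setdefault("seed", cfg.seed)
    block["planted"] = [tuple(p) for p in block.get("planted", [])]
    return simulate.simulate_fibroblast(simulate.FibroblastSimSpec(**block))


def _get_cohort(cfg: PipelineConfig, centroid: signature.Centroid):
    if cfg.cohort is not None:
        if cfg.clinical is None:
            raise ValueError("config with 'cohort' also needs 'clinical'")
        expr = read_expression(cfg.cohort)
        clinical = survival.read_clinical(cfg.clinical)
        return expr, clinical, None
    if cfg.simulate_cohort is None:
        raise ValueError("config needs 'cohort' or a 'simulate_cohort' block")
    block = dict(cfg.simulate_cohort)
    block.setdefault("seed", cfg.seed + 1)
    block.setdefault("endpoint", cfg.endpoint)
    block["suppressor_genes"] = tuple(block.get("suppressor_genes", ()))
    spec = simulate.CohortSimSpec(centroid=centroid, **block)
    return simulate.simulate_cohort(spec)


def _stratify(cohort, centroid, method: str) -> pd.DataFrame:
    if method == "centroid":
        return signature.classify_by_centroid(cohort, centroid)
    return signature.composite_score(cohort, centroid)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, writing outputs under ``cfg.out_dir``.

    Returns a report bundle with the in-memory artefacts and headline
    statistics. If the refinement step selects no genes the pipeline
    reports that and stops before re-stratification.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in asdict(cfg).items()}, "stages": {}}

    def _stage(name):
        logger.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    # differential expression
    st = _stage("de")
    fibro = _get_fibroblast(cfg)
    de = rankprod.rankprod_test(fibro, n_perm=cfg.n_perm, seed=cfg.seed)
    rankprod.write_de(rankprod.sort_de(de), out / "de.tsv")
    st["n_probes"] = int(len(de))

    # significance + gene-set filter
    st = _stage("filter")
    sig_de = de[de["p_value"] < cfg.alpha_de]
    gs = (
        genesets.read_gene_set(cfg.gene_set)
        if cfg.gene_set
        else genesets.bundled_matrisome()
    )
    filtered = genesets.filter_by_gene_set(sig_de, gs)
    if filtered.empty:
        raise RuntimeError("stage 'filter': no significant gene-set probes retained")
    rankprod.write_de(rankprod.sort_de(filtered), out / "de_filtered.tsv")
    st.update(
        n_significant=int(len(sig_de)),
        n_in_gene_set=int(len(filtered)),
        n_genes=int(filtered["gene_symbol"].str.upper().nunique()),
    )

    # centroid with ortholog mapping to the cohort symbol space
    st = _stage("centroid")
    centroid = signature.build_centroid(filtered, provenance="pipeline DE run")
    om = (
        genesets.read_ortholog_map(cfg.orthologs)
        if cfg.orthologs
        else genesets.OrthologMap()
    )
    mapped, _ = genesets.map_orthologs(centroid.genes, om)
    weights = pd.Series(centroid.weights.to_numpy(), index=mapped)
    weights = weights.groupby(level=0, sort=False).mean()
    centroid = signature.Centroid(weights, provenance=centroid.provenance)
    signature.write_centroid(centroid, out / "centroid.tsv")
    st["n_genes"] = len(centroid)

    # cohort stratification and survival
    st = _stage("stratify")
    cohort, clinical, latent = _get_cohort(cfg, centroid)
    clinical = survival.apply_followup_cutoff(clinical, cfg.cutoff_months)
    strat = _stratify(cohort, centroid, cfg.stratification)
    signature.write_stratification(strat, out / "stratification.tsv")
    if latent is not None:
        survival.write_clinical(clinical, out / "clinical.tsv")
    st["group_sizes"] = strat["group"].value_counts().to_dict()

    st = _stage("survive")
    summary = survival.cox_fit(clinical, strat, covariates=cfg.covariates)
    summary.cox_entries.to_csv(out / "cox_full.tsv", sep="\t")
    st.update(
        logrank_statistic=summary.logrank_statistic, logrank_p=summary.logrank_p
    )

    # per-gene screening and refinement
    st = _stage("screen")
    subgroups = None
    if cfg.subgroups:
        with open(cfg.subgroups) as fh:
            subgroups = yaml.safe_load(fh)
    screen = refinement.per_gene_screen(
        cohort, clinical, centroid.genes, subgroups=subgroups
    )
    refinement.write_screen(screen, out / "screen.tsv")
    st["n_cells"] = int(screen["raw_p"].notna().sum())

    st = _stage("refine")
    selected = refinement.select_signature(screen, alpha=cfg.alpha_refine)
    selected.to_csv(out / "selected_genes.tsv", sep="\t", index=False)
    st["n_selected"] = int(len(selected))
    bundle = {
        "de": de,
        "filtered": filtered,
        "centroid": centroid,
        "stratification": strat,
        "survival_full": summary,
        "screen": screen,
        "selected": selected,
        "latent": latent,
        "manifest": manifest,
    }
    if selected.empty:
        st["stopped"] = "no genes passed refinement; re-stratification skipped"
        logger.warning(st["stopped"])
        _write_manifest(manifest, out)
        return bundle

    de_directions = {
        g: ("up" if w > 0 else "down") for g, w in centroid.weights.items()
    }
    calls = refinement.classify_directions(
        screen, de_directions, selected, alpha=cfg.alpha_refine
    )
    refined = refinement.build_refined_centroid(centroid, calls)
    signature.write_centroid(refined, out / "centroid_refined.tsv")
    st["n_refined"] = len(refined)
    st["reversed"] = [c.gene for c in calls if c.concordance == refinement.SUPPRESSOR]

    st = _stage("restratify")
    strat2 = _stratify(cohort, refined, cfg.stratification)
    signature.write_stratification(strat2, out / "stratification_refined.tsv")
    summary2 = survival.cox_fit(clinical, strat2, covariates=cfg.covariates)
    summary2.cox_entries.to_csv(out / "cox_refined.tsv", sep="\t")
    st.update(
        logrank_statistic=summary2.logrank_statistic, logrank_p=summary2.logrank_p
    )

    bundle.update(
        calls=calls,
        refined_centroid=refined,
        stratification_refined=strat2,
        survival_refined=summary2,
    )
    _write_manifest(manifest, out)
    return bundle


def _write_manifest(manifest: dict, out: Path) -> None:
    from . import __version__

    manifest["version"] = __version__

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.ndarray, tuple, set)):
            return list(obj)
        return str(obj)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_default)
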