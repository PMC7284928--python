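"""End-to-end orchestration: ingest → effects → pooling → network
classification → covariate MLR → enrichment, as one configured, logged run.

Every stage writes a TSV with fixed 6-significant-digit formatting so a
rerun with the same config and inputs is byte-identical. Outputs are
written with a ``.partial`` suffix while the run is in flight and renamed
on success, so an aborted run leaves its completed stages inspectable. A
JSON run manifest records inputs (with content hashes), parameter values,
library versions and per-stage gene counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .covariates import InfluenceResult, mlr_influence, write_influence
from .effect_size import GeneEffect, collect_effects, write_effects
from .enrichment import EnrichmentResult, enrich, read_gmt, write_enrichment
from .expression_io import (
    ExpressionStudy,
    GroupRule,
    SelectionCriteria,
    StudyCovariates,
    drop_sparse_genes,
    ensure_log2,
    map_probes,
    read_matrix_tsv,
    read_series_matrix,
    validate_selection,
)
from .meta import MetaResult, mega_analyze, write_meta
from .relations import (
    NetworkGene,
    candidate_sets,
    classify_network,
    load_relations,
    write_network,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class StudyInput:
    """One study file plus how to ingest it."""

    path: str
    format: str = "series_matrix"  # or "tsv"
    groups: Mapping[str, str] | str | None = None  # regex rule or groups file
    platform_map: str | None = None
    study_id: str | None = None
    covariates: StudyCovariates | None = None


@dataclass(frozen=True)
class PipelineConfig:
    studies: Sequence[StudyInput]
    relations: str
    gmt: str
    out_dir: str
    driver: str = "PPARG"
    disease: str = "MI"
    alpha: float = 0.05
    enrich_alpha_p: float = 0.005
    enrich_alpha_q: float = 0.005
    min_k: int = 2
    aggregation: str = "max_mean"
    min_total_samples: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("alpha", self.alpha),
                        ("enrich_alpha_p", self.enrich_alpha_p),
                        ("enrich_alpha_q", self.enrich_alpha_q)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for s in self.studies:
            if not Path(s.path).exists():
                raise FileNotFoundError(f"study file not found: {s.path}")
        for label, p in (("relations", self.relations), ("gmt", self.gmt)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (paths relative to the file)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    base = path.parent

    def resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    studies = []
    for s in raw["studies"]:
        groups = s.get("groups")
        if isinstance(groups, str):
            groups = resolve(groups)
        studies.append(
            StudyInput(
                path=resolve(s["path"]),
                format=s.get("format", "series_matrix"),
                groups=groups,
                platform_map=resolve(s["platform_map"]) if s.get("platform_map") else None,
                study_id=s.get("study_id"),
            )
        )
    kwargs = {
        k: raw[k]
        for k in ("driver", "disease", "alpha", "enrich_alpha_p", "enrich_alpha_q",
                  "min_k", "aggregation", "min_total_samples", "seed")
        if k in raw
    }
    return PipelineConfig(
        studies=tuple(studies),
        relations=resolve(raw["relations"]),
        gmt=resolve(raw["gmt"]),
        out_dir=resolve(raw["out_dir"]),
        **kwargs,
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _ingest_study(spec: StudyInput, criteria: SelectionCriteria,
                  aggregation: str) -> ExpressionStudy | None:
    if spec.format == "series_matrix":
        rule = spec.groups or {"case": "case", "control": "control"}
        study = read_series_matrix(spec.path, GroupRule(**dict(rule)),
                                   study_id=spec.study_id, covariates=spec.covariates)
    elif spec.format == "tsv":
        if not isinstance(spec.groups, str):
            raise ValueError(f"{spec.path}: tsv format needs a groups file path")
        study = read_matrix_tsv(spec.path, spec.groups, study_id=spec.study_id)
    else:
        raise ValueError(f"unknown study format {spec.format!r}")
    ok, reasons = validate_selection(study, criteria)
    if not ok:
        logger.warning("study %s excluded: %s", study.study_id, "; ".join(reasons))
        return None
    if spec.platform_map:
        import pandas as pd

        pmap = pd.read_csv(spec.platform_map, sep="\t")
        study = map_probes(study, pmap, aggregation=aggregation)
    study = ensure_log2(study)
    study = drop_sparse_genes(study)
    return study


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run every stage; returns the run manifest (also written to disk).

    On a stage failure a :class:`PipelineError` naming the stage is raised;
    outputs of completed stages remain in ``out_dir`` with a ``.partial``
    suffix.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    partials: list[tuple[Path, Path]] = []
    counts: dict[str, int] = {}

    def stage_out(name: str) -> Path:
        final = out_dir / name
        partial = out_dir / (name + ".partial")
        partials.append((partial, final))
        return partial

    criteria = SelectionCriteria(min_total_samples=config.min_total_samples)

    # --- ingest ---------------------------------------------------------
    try:
        studies = []
        for spec in config.studies:
            study = _ingest_study(spec, criteria, config.aggregation)
            if study is not None:
                studies.append(study)
        if not studies:
            raise ValueError("no study passed the selection criteria")
    except Exception as exc:
        raise PipelineError("ingest", exc) from exc
    counts["studies_ingested"] = len(studies)

    # --- effects --------------------------------------------------------
    try:
        effects_by_gene = collect_effects(studies)
        all_effects: list[GeneEffect] = [
            e for effs in effects_by_gene.values() for e in effs
        ]
        write_effects(sorted(all_effects, key=lambda e: (e.gene, e.study_id)),
                      stage_out("effects.tsv"))
    except Exception as exc:
        raise PipelineError("effects", exc) from exc
    counts["genes_with_effects"] = len(effects_by_gene)

    # --- mega-analysis --------------------------------------------------
    try:
        meta: dict[str, MetaResult] = mega_analyze(effects_by_gene, min_k=config.min_k)
        write_meta(meta, stage_out("meta.tsv"))
    except Exception as exc:
        raise PipelineError("meta", exc) from exc
    counts["genes_pooled"] = len(meta)

    # --- network classification ----------------------------------------
    try:
        relations = load_relations(config.relations)
        cands = candidate_sets(relations, config.driver, config.disease)
        network: list[NetworkGene] = classify_network(cands, meta, alpha=config.alpha)
        write_network(network, stage_out("network.tsv"))
    except Exception as exc:
        raise PipelineError("network", exc) from exc
    counts["candidates_promoted"] = len(cands.promoted_inhibitors)
    counts["candidates_contra"] = len(cands.contra_directional)
    counts["network_genes"] = len(network)

    # --- covariate influence -------------------------------------------
    try:
        cov_map = {s.study_id: s.covariates for s in studies}
        influence: list[InfluenceResult] = []
        for g in sorted({n.gene for n in network} | {config.driver.upper()}):
            effs = effects_by_gene.get(g, [])
            if len(effs) >= 3:
                influence.append(mlr_influence(effs, cov_map))
            else:
                logger.info("gene %s skipped in MLR (fewer than 3 studies)", g)
        write_influence(influence, stage_out("influence.tsv"))
    except Exception as exc:
        raise PipelineError("influence", exc) from exc
    counts["genes_mlr"] = len(influence)

    # --- enrichment -----------------------------------------------------
    try:
        collection = read_gmt(config.gmt)
        query = {n.gene for n in network} | {config.driver.upper()}
        if query & collection.background:
            results: list[EnrichmentResult] = enrich(
                query, collection,
                alpha_p=config.enrich_alpha_p, alpha_q=config.enrich_alpha_q,
            )
        else:
            logger.warning("no network gene in the enrichment background; "
                           "writing empty enrichment table")
            results = []
        write_enrichment(results, stage_out("enrichment.tsv"))
    except Exception as exc:
        raise PipelineError("enrichment", exc) from exc
    counts["enriched_sets"] = len(results)

    # --- manifest & finalize -------------------------------------------
    manifest = {
        "megapath_version": __version__,
        "inputs": {
            "studies": [{"path": s.path, "sha256": _sha256(s.path)}
                        for s in config.studies],
            "relations": {"path": config.relations, "sha256": _sha256(config.relations)},
            "gmt": {"path": config.gmt, "sha256": _sha256(config.gmt)},
        },
        "parameters": {
            "driver": config.driver, "disease": config.disease,
            "alpha": config.alpha, "enrich_alpha_p": config.enrich_alpha_p,
            "enrich_alpha_q": config.enrich_alpha_q, "min_k": config.min_k,
            "aggregation": config.aggregation,
            "min_total_samples": config.min_total_samples, "seed": config.seed,
        },
        "versions": _library_versions(),
        "counts": counts,
    }
    for partial, final in partials:
        partial.replace(final)
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def _library_versions() -> dict[str, str]:
    import numpy, pandas, scipy, statsmodels  # noqa: E401

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "statsmodels": statsmodels.__version__,
    }
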