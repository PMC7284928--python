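"""Synthetic desk-scale input bundle: eight case/control expression studies,
a literature relation table for the driver–disease network, and a GMT
collection — with planted effects so every pipeline stage is testable
without any download.

The study designs (control/case counts, country, study age) mirror the
eight published myocardial-infarction microarray cohorts used for the
pooled analysis; one accession contributes two independent sub-studies and
is kept as two entries. The relation table encodes the nine-gene
PPARG–MI network: three genes promoted by the driver that inhibit the
disease, three contra-directional down-regulated targets, two
contra-directional up-regulated targets, plus decoy genes that fail either
significance or direction. The gene-set generator emits GO-term–shaped sets
whose sizes and query overlaps reproduce the published enrichment layout.

Generation model, per study ``s`` and gene ``g``::

    δ_gs ~ Normal(LFC_g + covariate terms, τ²)     (study-level true effect)
    control samples ~ Normal(baseline_g, σ²)
    case samples    ~ Normal(baseline_g + δ_gs, σ²)

with ``baseline_g ~ Uniform(4, 12)`` on the log2 scale and σ = 1.0 by
default, which leaves recovery of the weaker planted effects deliberately
marginal at the published sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import GeneSet, GeneSetCollection, write_gmt
from .expression_io import ExpressionStudy, GroupRule, StudyCovariates
from .meta import FIXED, RANDOM, MetaResult
from .relations import Polarity, RelationTriple, RelationType, write_relations

DRIVER = "PPARG"
DISEASE = "MI"

#: (study_id, n_control, n_case, country, study_age) for the eight cohorts.
STUDY_DESIGNS: tuple[tuple[str, int, int, str, int], ...] = (
    ("GSE24519", 4, 34, "Italy", 3),
    ("GSE24591", 4, 34, "Italy", 3),
    ("GSE34198", 48, 49, "Czech Republic", 6),
    ("GSE48060", 21, 31, "USA", 6),
    ("GSE60993a", 7, 10, "South Korea", 5),
    ("GSE60993b", 7, 17, "South Korea", 5),
    ("GSE62646", 14, 84, "Poland", 6),
    ("GSE66360", 50, 49, "USA", 5),
)

#: Published pooled statistics of the nine network genes:
#: gene -> (category, random-effects flag, k studies, pooled LFC, p-value).
NETWORK_GENE_STATS: dict[str, tuple[str, int, int, float, float]] = {
    "SOD1":    ("promoted_inhibitor", 0, 4, -0.28, 0.048),
    "CAV1":    ("promoted_inhibitor", 0, 7, -0.24, 0.0050),
    "POU5F1":  ("promoted_inhibitor", 1, 5, -0.23, 0.041),
    "ALB":     ("contra_down",        1, 6, -1.35, 0.0050),
    "ACADM":   ("contra_down",        0, 6, -0.32, 0.0034),
    "ADIPOR2": ("contra_down",        0, 6, -0.16, 0.031),
    "RELA":    ("contra_up",          0, 4,  0.28, 0.008),
    "MYD88":   ("contra_up",          0, 3,  0.23, 0.047),
    "PPARG":   ("driver",             0, 5, -0.52, 2e-9),
}

#: GO-term–shaped enrichment layout: (set_id, name, set_size, overlap with
#: the 9-gene network query).
GENESET_LAYOUT: tuple[tuple[str, str, int, int], ...] = (
    ("GO:0007584", "response to nutrient", 370, 7),
    ("GO:0031667", "response to nutrient levels", 730, 7),
    ("GO:0009991", "response to extracellular stimulus", 761, 7),
    ("GO:0010035", "response to inorganic substance", 803, 6),
    ("GO:0062012", "regulation of small molecule metabolic process", 422, 5),
    ("GO:0019216", "regulation of lipid metabolic process", 441, 5),
    ("GO:0071496", "cellular response to external stimulus", 451, 5),
    ("GO:0010038", "response to metal ion", 533, 5),
)

#: Group rule matching the characteristics strings the writer emits.
DEFAULT_GROUP_RULE = GroupRule(case="myocardial infarction", control="healthy control")

# decoy genes wired into the relation table
_DECOY_NULL_PROMOTED = ("DECOYP1", "DECOYP2")   # promoted pattern, no true effect
_DECOY_NULL_CONTRA = ("DECOYC1",)               # contra_down pattern, no true effect
_DECOY_NULL_CONTRA_UP = ("DECOYU1",)            # contra_up pattern, no true effect
_DECOY_WRONG_DIRECTION = ("DECOYW1",)           # promoted pattern, planted UP
_DECOY_NO_DISEASE_EDGE = ("DECOYX1",)           # driver edge only


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines a synthetic bundle, including the seed."""

    seed: int = 0
    n_genes: int = 160
    study_designs: tuple[tuple[str, int, int, str, int], ...] = STUDY_DESIGNS
    planted_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(_default_planted())
    )
    tau_sq: float = 0.0
    noise_sd: float = 1.0
    covariate_effects: Mapping[str, float] | None = None
    baseline_range: tuple[float, float] = (4.0, 12.0)

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.tau_sq < 0:
            raise ValueError("tau_sq must be ≥ 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        ids = [d[0] for d in self.study_designs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate study_id in study_designs")
        for _, n_ctrl, n_case, _, _ in self.study_designs:
            if n_ctrl < 1 or n_case < 1:
                raise ValueError("group sizes must be positive")


def _default_planted() -> dict[str, float]:
    planted = {g: stats_[3] for g, stats_ in NETWORK_GENE_STATS.items()}
    planted[_DECOY_WRONG_DIRECTION[0]] = 0.5  # significant but wrong-direction decoy
    return planted


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default bundle configuration; keyword overrides for tests."""
    return SimulationConfig(seed=seed, **overrides)


def gene_names(config: SimulationConfig) -> list[str]:
    """Deterministic gene roster: planted genes first, then null fillers."""
    planted = sorted(config.planted_effects)
    decoys = [g for g in (*_DECOY_NULL_PROMOTED, *_DECOY_NULL_CONTRA,
                          *_DECOY_NULL_CONTRA_UP, *_DECOY_NO_DISEASE_EDGE)
              if g not in planted]
    roster = planted + decoys
    n_fill = max(0, config.n_genes - len(roster))
    roster += [f"NULL{i:04d}" for i in range(1, n_fill + 1)]
    return roster


def generate_studies(config: SimulationConfig) -> list[ExpressionStudy]:
    """Simulate the full study list; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genes = gene_names(config)
    lo, hi = config.baseline_range
    baseline = rng.uniform(lo, hi, size=len(genes))
    true_lfc = np.array([config.planted_effects.get(g, 0.0) for g in genes])

    studies: list[ExpressionStudy] = []
    for study_id, n_ctrl, n_case, country, age in config.study_designs:
        delta = true_lfc.copy()
        if config.covariate_effects:
            for factor, slope in config.covariate_effects.items():
                value = {"sample_size": n_ctrl + n_case, "study_age": age}.get(factor)
                if value is None:
                    raise ValueError(f"unknown covariate factor {factor!r}")
                delta = delta + slope * value
        if config.tau_sq > 0:
            delta = delta + rng.normal(0.0, math.sqrt(config.tau_sq), size=len(genes))
        ctrl = rng.normal(baseline[:, None], config.noise_sd, size=(len(genes), n_ctrl))
        case = rng.normal((baseline + delta)[:, None], config.noise_sd,
                          size=(len(genes), n_case))
        samples = [f"{study_id}_C{i+1}" for i in range(n_ctrl)] + \
                  [f"{study_id}_M{i+1}" for i in range(n_case)]
        matrix = pd.DataFrame(np.hstack([ctrl, case]), index=genes, columns=samples)
        matrix.index.name = "gene"
        groups = pd.Series(["control"] * n_ctrl + ["case"] * n_case,
                           index=samples, name="group")
        studies.append(ExpressionStudy(study_id, matrix, groups,
                                       StudyCovariates(country, float(age))))
    return studies


def generate_relations(
    config: SimulationConfig | None = None,
    include_decoys: bool = True,
    network_only: bool = False,
) -> list[RelationTriple]:
    """The nine-gene driver–disease relation fixture, plus wired decoys.

    Promoted inhibitors: driver →+ gene, gene ⊣ disease.
    Contra (down): driver →+ gene, disease ⊣ gene.
    Contra (up): driver ⊣ gene, disease →+ gene.
    """
    triples: list[RelationTriple] = []

    def edge(src: str, tgt: str, pol: Polarity, rtype: RelationType) -> None:
        triples.append(RelationTriple(src, tgt, pol, rtype, ("synthetic",)))

    def wire(gene: str, category: str) -> None:
        if category == "promoted_inhibitor":
            edge(DRIVER, gene, Polarity.POSITIVE, RelationType.EXPRESSION_REGULATION)
            edge(gene, DISEASE, Polarity.NEGATIVE, RelationType.ACTIVATION_INHIBITION)
        elif category == "contra_down":
            edge(DRIVER, gene, Polarity.POSITIVE, RelationType.EXPRESSION_REGULATION)
            edge(DISEASE, gene, Polarity.NEGATIVE, RelationType.EXPRESSION_REGULATION)
        elif category == "contra_up":
            edge(DRIVER, gene, Polarity.NEGATIVE, RelationType.EXPRESSION_REGULATION)
            edge(DISEASE, gene, Polarity.POSITIVE, RelationType.EXPRESSION_REGULATION)

    for gene, (category, *_rest) in NETWORK_GENE_STATS.items():
        if category != "driver":
            wire(gene, category)
    if include_decoys and not network_only:
        for g in (*_DECOY_NULL_PROMOTED, *_DECOY_WRONG_DIRECTION):
            wire(g, "promoted_inhibitor")
        for g in _DECOY_NULL_CONTRA:
            wire(g, "contra_down")
        for g in _DECOY_NULL_CONTRA_UP:
            wire(g, "contra_up")
        for g in _DECOY_NO_DISEASE_EDGE:
            edge(DRIVER, g, Polarity.POSITIVE, RelationType.OTHER)
    return triples


def table_meta_results() -> dict[str, MetaResult]:
    """Published pooled statistics of the nine network genes as MetaResult
    records (standard error back-derived from the normal two-sided p).

    Heterogeneity fields that the published table does not report are NaN.
    """
    out: dict[str, MetaResult] = {}
    for gene, (_cat, flag, k, lfc, p) in NETWORK_GENE_STATS.items():
        z = float(stats.norm.isf(p / 2.0))
        se = abs(lfc) / z if z > 0 else float("nan")
        out[gene] = MetaResult(
            gene=gene, k=k, pooled_lfc=lfc, se=se, p_value=p,
            q_stat=float("nan"), df=k - 1, i_sq=float("nan"),
            p_q=float("nan"), tau_sq=float("nan"),
            model=RANDOM if flag else FIXED,
        )
    return out


def network_query() -> frozenset[str]:
    """The nine-gene enrichment query (eight network genes plus the driver)."""
    return frozenset(NETWORK_GENE_STATS)


def generate_genesets(
    config: SimulationConfig | None = None,
    n_decoy_sets: int = 4,
    decoy_set_size: int = 50,
    decoy_pool: int = 5000,
) -> GeneSetCollection:
    """GO-shaped gene sets reproducing the published sizes and query overlaps.

    Each layout set contains the prescribed number of network-query genes
    and is padded to size with background filler genes drawn (without
    replacement, per set) from a shared decoy pool, so sets overlap each
    other realistically. ``n_decoy_sets`` additional sets are disjoint from
    the query.
    """
    seed = config.seed if config is not None else 0
    rng = np.random.default_rng(seed)
    query = sorted(network_query())
    pool = [f"BG{i:05d}" for i in range(1, decoy_pool + 1)]

    sets: dict[str, GeneSet] = {}
    for set_id, name, size, overlap in GENESET_LAYOUT:
        hit = list(rng.choice(query, size=overlap, replace=False))
        fill = list(rng.choice(pool, size=size - overlap, replace=False))
        sets[set_id] = GeneSet(set_id, name, frozenset(hit + fill))
    for i in range(1, n_decoy_sets + 1):
        sid = f"DECOYSET{i:02d}"
        fill = list(rng.choice(pool, size=decoy_set_size, replace=False))
        sets[sid] = GeneSet(sid, f"decoy set {i}", frozenset(fill))
    background = frozenset().union(*(s.members for s in sets.values())) | set(query)
    return GeneSetCollection(sets, background)


def write_series_matrix(study: ExpressionStudy, path: str | Path) -> None:
    """Write a study in the series-matrix dialect the reader consumes."""
    cov = study.covariates
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f'!Series_geo_accession\t"{study.study_id}"\n')
        if cov.country is not None:
            fh.write(f'!Series_country\t"{cov.country}"\n')
        if cov.study_age is not None:
            fh.write(f'!Series_study_age\t"{cov.study_age:g}"\n')
        fh.write("!Sample_geo_accession\t" +
                 "\t".join(f'"{s}"' for s in study.matrix.columns) + "\n")
        chars = {
            "case": "disease state: myocardial infarction",
            "control": "disease state: healthy control",
        }
        fh.write("!Sample_characteristics_ch1\t" +
                 "\t".join(f'"{chars[study.groups[s]]}"' for s in study.matrix.columns) +
                 "\n")
        fh.write("!series_matrix_table_begin\n")
        fh.write("ID_REF\t" + "\t".join(f'"{s}"' for s in study.matrix.columns) + "\n")
        for gene, row in study.matrix.iterrows():
            fh.write(str(gene) + "\t" +
                     "\t".join(f"{v:.6g}" for v in row.to_numpy()) + "\n")
        fh.write("!series_matrix_table_end\n")


def write_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, object]:
    """Write the whole bundle (studies, relations, GMT) to ``out_dir``.

    Returns a manifest dict with the file paths, usable to assemble a
    pipeline configuration. Deterministic given ``config.seed``.
    """
    out = Path(out_dir)
    (out / "studies").mkdir(parents=True, exist_ok=True)
    study_paths: list[str] = []
    for study in generate_studies(config):
        p = out / "studies" / f"{study.study_id}_series_matrix.txt"
        write_series_matrix(study, p)
        study_paths.append(str(p))
    rel_path = out / "relations.tsv"
    write_relations(generate_relations(config), rel_path)
    gmt_path = out / "genesets.gmt"
    write_gmt(generate_genesets(config), gmt_path)
    return {
        "studies": study_paths,
        "relations": str(rel_path),
        "gmt": str(gmt_path),
        "group_rule": {"case": DEFAULT_GROUP_RULE.case,
                       "control": DEFAULT_GROUP_RULE.control},
        "driver": DRIVER,
        "disease": DISEASE,
        "seed": config.seed,
    }
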