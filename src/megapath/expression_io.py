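"""Readers, probe mapping, scale normalisation and selection rules for
case/control expression studies.

Two on-disk dialects are supported:

* the GEO *series matrix* text export (``!``-prefixed metadata lines and a
  tab-separated value block between ``!series_matrix_table_begin/end``);
* a plain gene×sample TSV plus a two-column sample→group file whose ``#``
  header lines carry the study-level covariates.

Sample group assignment is always rule-driven — regular expressions matched
against the concatenated per-sample metadata — never inferred from the
expression values themselves, so an ingest is reproducible from the rule.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class StudyCovariates:
    """Study-level covariate record.

    ``study_age`` follows the convention current year − year of study + 1
    (in years); ``country`` is the country of origin of the cohort.
    """

    country: str | None = None
    study_age: float | None = None


@dataclass(frozen=True)
class GroupRule:
    """Regex rule mapping per-sample metadata to case/control labels.

    Each pattern is searched (``re.search``, case-insensitive) in the
    concatenation of all metadata fields of a sample. Samples matching
    neither pattern are dropped; matching both is an error.
    """

    case: str
    control: str


@dataclass
class ExpressionStudy:
    """One case/control study: log2 gene×sample matrix, labels, covariates."""

    study_id: str
    matrix: pd.DataFrame  # rows: genes/probes, columns: samples
    groups: pd.Series  # index: samples, values: "case"/"control"
    covariates: StudyCovariates = field(default_factory=StudyCovariates)

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != list(self.groups.index):
            self.groups = self.groups.reindex(self.matrix.columns)
        if self.groups.isna().any():
            raise ValueError(f"{self.study_id}: samples without a group label")
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"{self.study_id}: unknown group labels {sorted(bad)}")

    @property
    def n_case(self) -> int:
        return int((self.groups == CASE).sum())

    @property
    def n_control(self) -> int:
        return int((self.groups == CONTROL).sum())

    @property
    def n_total(self) -> int:
        return int(len(self.groups))


class SeriesMatrixError(ValueError):
    """Malformed series-matrix file."""


def _unquote(tok: str) -> str:
    tok = tok.strip()
    if len(tok) >= 2 and tok[0] == '"' and tok[-1] == '"':
        tok = tok[1:-1]
    return tok


def read_series_matrix(
    path: str | Path,
    group_rule: GroupRule | Mapping[str, str],
    study_id: str | None = None,
    covariates: StudyCovariates | None = None,
) -> ExpressionStudy:
    """Parse a GEO-series-matrix–style file into an :class:`ExpressionStudy`.

    ``group_rule`` maps samples to case/control via regexes on the sample
    metadata lines (``!Sample_…``). Study covariates are taken, in order of
    precedence, from the ``covariates`` argument, then from optional
    ``!Series_country`` / ``!Series_study_age`` metadata lines.

    Raises :class:`SeriesMatrixError` when the table block is malformed and
    ``ValueError`` ("no cases"/"no controls") when a group ends up empty.
    """
    path = Path(path)
    if not isinstance(group_rule, GroupRule):
        group_rule = GroupRule(**dict(group_rule))

    series_meta: dict[str, list[str]] = {}
    sample_meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    table_closed = False
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                table_closed = True
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                key, *vals = line.split("\t")
                vals = [_unquote(v) for v in vals]
                target = sample_meta if key.startswith("!Sample_") else series_meta
                target.setdefault(key.lstrip("!"), []).extend(vals)
    if not table_lines:
        raise SeriesMatrixError(f"{path}: no series_matrix table block found")
    if not table_closed:
        raise SeriesMatrixError(f"{path}: table block never closed "
                                f"(missing !series_matrix_table_end)")

    try:
        table = pd.read_csv(io.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SeriesMatrixError(f"{path}: cannot parse table block: {exc}") from exc
    table.columns = [_unquote(str(c)) for c in table.columns]
    table.index = [_unquote(str(i)) for i in table.index]
    non_numeric = table.apply(pd.to_numeric, errors="coerce")
    bad_rows = non_numeric.isna().all(axis=1) & ~table.isna().all(axis=1)
    if bad_rows.any():
        first = int(np.argmax(bad_rows.to_numpy())) + 2  # +header +1-based
        raise SeriesMatrixError(f"{path}: non-numeric table row at block line {first}")
    matrix = non_numeric

    # per-sample searchable metadata string
    n_samples = matrix.shape[1]
    per_sample: list[str] = ["" for _ in range(n_samples)]
    for key, vals in sample_meta.items():
        if len(vals) == n_samples:
            for i, v in enumerate(vals):
                per_sample[i] += f"{key}={v};"
    case_re = re.compile(group_rule.case, re.IGNORECASE)
    control_re = re.compile(group_rule.control, re.IGNORECASE)
    labels: dict[str, str] = {}
    for sample, meta in zip(matrix.columns, per_sample):
        is_case = bool(case_re.search(meta))
        is_control = bool(control_re.search(meta))
        if is_case and is_control:
            raise ValueError(f"{path}: sample {sample!r} matches both group rules")
        if is_case:
            labels[sample] = CASE
        elif is_control:
            labels[sample] = CONTROL
    if not any(v == CASE for v in labels.values()):
        raise ValueError(f"{path}: no cases matched the group rule")
    if not any(v == CONTROL for v in labels.values()):
        raise ValueError(f"{path}: no controls matched the group rule")
    dropped = [s for s in matrix.columns if s not in labels]
    if dropped:
        logger.info("%s: %d sample(s) matched neither group rule and were dropped",
                    path.name, len(dropped))
    keep = [s for s in matrix.columns if s in labels]
    matrix = matrix[keep]
    groups = pd.Series({s: labels[s] for s in keep}, name="group")

    if covariates is None:
        country = series_meta.get("Series_country", [None])[0]
        age_tok = series_meta.get("Series_study_age", [None])[0]
        covariates = StudyCovariates(
            country=country, study_age=float(age_tok) if age_tok else None
        )
    if study_id is None:
        study_id = series_meta.get("Series_geo_accession", [path.stem])[0] or path.stem
    return ExpressionStudy(study_id, matrix, groups, covariates)


def read_matrix_tsv(
    matrix_path: str | Path,
    groups_path: str | Path,
    study_id: str | None = None,
) -> ExpressionStudy:
    """Read the plain-TSV dialect: gene×sample matrix + sample/group file.

    The group file is two tab-separated columns (``sample``, ``group``) with
    optional ``#key=value`` header lines carrying ``study_id``, ``country``
    and ``study_age``.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0).astype(float)
    meta: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
    with Path(groups_path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
                continue
            sample, _, group = line.partition("\t")
            if sample == "sample" and group == "group":
                continue
            rows.append((sample, group))
    groups = pd.Series(dict(rows), name="group")
    cov = StudyCovariates(
        country=meta.get("country") or None,
        study_age=float(meta["study_age"]) if meta.get("study_age") else None,
    )
    sid = study_id or meta.get("study_id") or Path(matrix_path).stem
    return ExpressionStudy(sid, matrix, groups.reindex(matrix.columns), cov)


def write_matrix_tsv(
    study: ExpressionStudy, matrix_path: str | Path, groups_path: str | Path
) -> None:
    """Write the plain-TSV dialect read back by :func:`read_matrix_tsv`."""
    study.matrix.to_csv(matrix_path, sep="\t", float_format="%.10g", index_label="gene")
    with Path(groups_path).open("w", encoding="utf-8") as fh:
        fh.write(f"#study_id={study.study_id}\n")
        if study.covariates.country is not None:
            fh.write(f"#country={study.covariates.country}\n")
        if study.covariates.study_age is not None:
            fh.write(f"#study_age={study.covariates.study_age:g}\n")
        fh.write("sample\tgroup\n")
        for sample, group in study.groups.items():
            fh.write(f"{sample}\t{group}\n")


def map_probes(
    study: ExpressionStudy,
    platform_map: Mapping[str, str] | pd.DataFrame,
    aggregation: str = "max_mean",
) -> ExpressionStudy:
    """Collapse probe-level rows to gene symbols.

    ``platform_map`` maps probe id → gene symbol (dict, or a DataFrame with
    ``probe``/``gene`` columns). Probes without a mapping are dropped (count
    logged). Aggregation of multiple probes per gene:

    * ``max_mean`` (default) — keep the probe with the highest mean signal
      across samples, verbatim;
    * ``mean`` / ``median`` — per-sample mean/median over the probes.
    """
    if aggregation not in ("max_mean", "mean", "median"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if isinstance(platform_map, pd.DataFrame):
        platform_map = dict(zip(platform_map["probe"], platform_map["gene"]))
    if not platform_map:
        raise ValueError("empty platform map")
    probe_to_gene = {str(p): str(g).strip().upper() for p, g in platform_map.items()}

    mapped = study.matrix.index.to_series().map(probe_to_gene)
    n_dropped = int(mapped.isna().sum())
    if n_dropped:
        logger.info("%s: %d probe(s) without gene mapping dropped",
                    study.study_id, n_dropped)
    mat = study.matrix.loc[mapped.notna()]
    genes = mapped.dropna()

    if aggregation == "max_mean":
        order = mat.mean(axis=1, skipna=True)
        best = (
            pd.DataFrame({"_gene": genes.to_numpy(), "_mean": order.to_numpy(),
                          "_probe": np.arange(len(mat))})
            .sort_values(["_gene", "_mean"], ascending=[True, False], kind="stable")
            .drop_duplicates("_gene")
        )
        out = mat.iloc[best["_probe"].to_numpy()]
        out.index = best["_gene"].to_numpy()
        out = out.sort_index()
    else:
        grouped = mat.groupby(genes.to_numpy())
        out = grouped.mean() if aggregation == "mean" else grouped.median()
    out.index.name = "gene"
    return replace(study, matrix=out, groups=study.groups)


def ensure_log2(
    study: ExpressionStudy, linear_max: float = 50.0, pseudocount: float = 1.0
) -> ExpressionStudy:
    """Bring the matrix onto log2 scale if it looks linear.

    Heuristic: a maximum value above ``linear_max`` indicates a linear-scale
    matrix, which is transformed by ``log2(x + pseudocount)``; otherwise the
    matrix passes through unchanged. Negative values on a matrix judged
    linear-scale are an error (they cannot be intensities).
    """
    vmax = float(np.nanmax(study.matrix.to_numpy()))
    if vmax <= linear_max:
        logger.debug("%s: matrix judged log2 scale (max %.3g), unchanged",
                     study.study_id, vmax)
        return study
    vmin = float(np.nanmin(study.matrix.to_numpy()))
    if vmin < 0:
        raise ValueError(
            f"{study.study_id}: negative values (min {vmin:.3g}) on a matrix "
            f"judged linear scale (max {vmax:.3g})"
        )
    logger.info("%s: matrix judged linear scale (max %.3g), applying log2(x+%g)",
                study.study_id, vmax, pseudocount)
    return replace(study, matrix=np.log2(study.matrix + pseudocount), groups=study.groups)


def drop_sparse_genes(study: ExpressionStudy, max_missing_frac: float = 0.2) -> ExpressionStudy:
    """Drop rows with more than ``max_missing_frac`` missing values."""
    frac = study.matrix.isna().mean(axis=1)
    keep = frac <= max_missing_frac
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: %d gene(s) with >%d%% missing values dropped",
                    study.study_id, n_dropped, int(100 * max_missing_frac))
    return replace(study, matrix=study.matrix.loc[keep], groups=study.groups)


@dataclass(frozen=True)
class SelectionCriteria:
    """Dataset-selection rules applied before pooling.

    ``min_total_samples`` is an exclusive lower bound (a study qualifies only
    when it has strictly more samples). Metadata assertions (organism, array
    design, case/control layout) are upstream facts supplied by the caller;
    ``require_metadata`` lets a config assert them as booleans.
    """

    min_total_samples: int = 10
    require_metadata: Mapping[str, bool] = field(default_factory=dict)


def validate_selection(
    study: ExpressionStudy, criteria: SelectionCriteria | None = None
) -> tuple[bool, list[str]]:
    """Check a study against the selection criteria; returns (ok, reasons)."""
    criteria = criteria or SelectionCriteria()
    reasons: list[str] = []
    if study.n_case == 0:
        reasons.append("no case samples")
    if study.n_control == 0:
        reasons.append("no control samples")
    if study.n_total <= criteria.min_total_samples:
        reasons.append(f"sample size ≤ {criteria.min_total_samples}")
    for key, ok in criteria.require_metadata.items():
        if not ok:
            reasons.append(f"metadata criterion failed: {key}")
    return (not reasons, reasons)
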