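"""Per-study, per-gene effect sizes: log2 fold-change and its sampling variance.

The effect size is the difference of case and control group means on the
log2 scale. Its sampling variance is Welch-style,
``s²_case/n_case + s²_control/n_control`` with unbiased sample variances —
group variances are not pooled, because the studies come from heterogeneous
array platforms. Genes with no spread in either group receive a small
variance floor so they cannot acquire infinite meta-analysis weight.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .expression_io import CASE, CONTROL, ExpressionStudy

logger = logging.getLogger(__name__)

VAR_FLOOR = 1e-8

EFFECTS_COLUMNS = ("gene", "study_id", "lfc", "var", "n_case", "n_control")


@dataclass(frozen=True)
class GeneEffect:
    """log2 fold-change of one gene in one study, with sampling variance."""

    gene: str
    study_id: str
    lfc: float
    var: float
    n_case: int
    n_control: int


def study_lfc(
    study: ExpressionStudy,
    var_floor: float = VAR_FLOOR,
    min_group_n: int = 2,
) -> list[GeneEffect]:
    """Compute per-gene effects for one study.

    Missing values are excluded pairwise (group means and variances use the
    non-missing samples of that gene). A gene is skipped — with a logged
    count — when either group retains fewer than ``min_group_n`` usable
    samples, since no variance can be estimated. A gene whose spread is zero
    in both groups gets ``var_floor`` instead of a zero variance.
    """
    case = study.matrix.loc[:, (study.groups == CASE).to_numpy()].to_numpy(dtype=float)
    ctrl = study.matrix.loc[:, (study.groups == CONTROL).to_numpy()].to_numpy(dtype=float)
    n_case = np.sum(~np.isnan(case), axis=1)
    n_ctrl = np.sum(~np.isnan(ctrl), axis=1)
    usable = (n_case >= min_group_n) & (n_ctrl >= min_group_n)
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("%s: %d gene(s) skipped (fewer than %d usable samples in a group)",
                    study.study_id, n_skipped, min_group_n)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows are filtered below
        mean_case = np.nanmean(case, axis=1)
        mean_ctrl = np.nanmean(ctrl, axis=1)
        var_case = np.nanvar(case, axis=1, ddof=1)
        var_ctrl = np.nanvar(ctrl, axis=1, ddof=1)
        lfc = mean_case - mean_ctrl
        var = var_case / n_case + var_ctrl / n_ctrl
    var = np.where(var <= 0, var_floor, var)

    genes = study.matrix.index.to_numpy()
    return [
        GeneEffect(str(genes[i]), study.study_id, float(lfc[i]), float(var[i]),
                   int(n_case[i]), int(n_ctrl[i]))
        for i in np.flatnonzero(usable)
    ]


def collect_effects(studies: Iterable[ExpressionStudy], **kwargs) -> dict[str, list[GeneEffect]]:
    """Group effects from several studies by gene, ready for pooling."""
    by_gene: dict[str, list[GeneEffect]] = {}
    for study in studies:
        for eff in study_lfc(study, **kwargs):
            by_gene.setdefault(eff.gene, []).append(eff)
    return by_gene


def effects_frame(effects: Iterable[GeneEffect]) -> pd.DataFrame:
    """Effects as a tidy DataFrame with the on-disk column order."""
    return pd.DataFrame([e.__dict__ for e in effects], columns=list(EFFECTS_COLUMNS))


def write_effects(effects: Iterable[GeneEffect], path: str | Path) -> None:
    effects_frame(effects).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_effects(path: str | Path) -> dict[str, list[GeneEffect]]:
    df = pd.read_csv(path, sep="\t")
    by_gene: dict[str, list[GeneEffect]] = {}
    for row in df.itertuples(index=False):
        eff = GeneEffect(str(row.gene), str(row.study_id), float(row.lfc),
                         float(row.var), int(row.n_case), int(row.n_control))
        by_gene.setdefault(eff.gene, []).append(eff)
    return by_gene
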