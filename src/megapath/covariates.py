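"""Study-covariate influence on per-study effect sizes (meta-regression by OLS).

For one gene the per-study log2 fold-changes are regressed on study-level
factors — total sample size (numeric), study age (numeric, years) and country
(unordered categorical, dummy-coded against the alphabetically first level) —
and each factor is assessed with a partial F-test (type-II sum of squares:
full model vs. the model with that factor's columns removed).

With only a handful of studies the full design is easily overparameterized.
When the residual degrees of freedom fall below one, factors are dropped in
the order country → study_age until the model is estimable; dropped factors
report p = 1 and are flagged as not estimable. Factors whose columns are
collinear with the rest of the design likewise report p = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effect_size import GeneEffect
from .expression_io import StudyCovariates

logger = logging.getLogger(__name__)

FACTORS = ("sample_size", "country", "study_age")
_REDUCTION_ORDER = ("country", "study_age")

INFLUENCE_COLUMNS = ("gene", "p_sample_size", "p_country", "p_study_age",
                     "r_sq", "k", "reduced_model_flag")


@dataclass(frozen=True)
class InfluenceResult:
    """Per-gene MLR influence p-values for the study-level factors."""

    gene: str
    factor_p: Mapping[str, float]
    k: int
    r_sq: float
    not_estimable: frozenset[str] = field(default_factory=frozenset)


def _design_columns(
    factor: str, sample_size: np.ndarray, study_age: np.ndarray, countries: Sequence[str]
) -> np.ndarray:
    if factor == "sample_size":
        return sample_size[:, None]
    if factor == "study_age":
        return study_age[:, None]
    levels = sorted(set(countries))
    # alphabetical reference level; k-1 dummies
    return np.column_stack(
        [np.asarray([c == lev for c in countries], dtype=float) for lev in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(countries), 0))


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of the design, via least squares."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def mlr_influence(
    effects: Sequence[GeneEffect],
    covariates: Mapping[str, StudyCovariates],
) -> InfluenceResult:
    """Partial-F influence p-values for sample size, country and study age.

    ``covariates`` maps study_id → :class:`StudyCovariates`; every effect's
    study must have a record. Sample size is ``n_case + n_control`` taken
    from the effects themselves. Requires at least 3 studies.
    """
    k = len(effects)
    if k < 3:
        raise ValueError("insufficient studies for MLR (need ≥ 3)")
    missing = [e.study_id for e in effects if e.study_id not in covariates]
    if missing:
        raise KeyError(f"no covariate record for studies: {sorted(set(missing))}")
    gene = effects[0].gene
    order = sorted(range(k), key=lambda i: effects[i].study_id)  # order-invariant
    eff = [effects[i] for i in order]
    y = np.array([e.lfc for e in eff], dtype=float)
    sample_size = np.array([e.n_case + e.n_control for e in eff], dtype=float)
    study_age = np.array(
        [np.nan if covariates[e.study_id].study_age is None
         else float(covariates[e.study_id].study_age) for e in eff]
    )
    countries = [covariates[e.study_id].country or "unknown" for e in eff]
    if np.isnan(study_age).any():
        raise ValueError(f"{gene}: study_age missing for some studies")

    included = list(FACTORS)
    not_estimable: set[str] = set()
    cols = {f: _design_columns(f, sample_size, study_age, countries) for f in FACTORS}
    # a factor contributing no columns (single country) is not estimable at all
    for f in FACTORS:
        if cols[f].shape[1] == 0:
            included.remove(f)
            not_estimable.add(f)

    def build(factors: Iterable[str]) -> np.ndarray:
        parts = [np.ones((k, 1))] + [cols[f] for f in FACTORS if f in set(factors)]
        return np.hstack(parts)

    while True:
        x_full = build(included)
        rss_full, rank_full = _rss(x_full, y)
        df_resid = k - rank_full
        if df_resid >= 1:
            break
        droppable = [f for f in _REDUCTION_ORDER if f in included]
        if not droppable:
            break
        dropped = droppable[0]
        included.remove(dropped)
        not_estimable.add(dropped)
        logger.info("%s: factor %s dropped (model not estimable with k=%d)",
                    gene, dropped, k)

    tss = float(np.sum((y - y.mean()) ** 2))
    eps = 1e-12 * max(tss, 1.0)
    r_sq = 0.0 if tss <= eps else max(0.0, 1.0 - rss_full / tss)

    factor_p: dict[str, float] = {}
    for f in FACTORS:
        if f not in included or df_resid < 1:
            factor_p[f] = 1.0
            not_estimable.add(f)
            continue
        rss_red, rank_red = _rss(build([g for g in included if g != f]), y)
        q = rank_full - rank_red
        if q <= 0:  # columns collinear with the rest of the design
            factor_p[f] = 1.0
            not_estimable.add(f)
            continue
        num = max(0.0, rss_red - rss_full)
        if rss_full <= eps:
            # saturated fit: the factor either explains nothing or everything
            factor_p[f] = 1.0 if num <= eps else float(np.finfo(float).tiny)
            continue
        f_stat = (num / q) / (rss_full / df_resid)
        factor_p[f] = max(float(stats.f.sf(f_stat, q, df_resid)), float(np.finfo(float).tiny))
    return InfluenceResult(gene, factor_p, k, r_sq, frozenset(not_estimable))


def influence_frame(results: Iterable[InfluenceResult]) -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene,
            "p_sample_size": r.factor_p["sample_size"],
            "p_country": r.factor_p["country"],
            "p_study_age": r.factor_p["study_age"],
            "r_sq": r.r_sq,
            "k": r.k,
            "reduced_model_flag": int(bool(r.not_estimable)),
        }
        for r in sorted(results, key=lambda r: r.gene)
    ]
    return pd.DataFrame(rows, columns=list(INFLUENCE_COLUMNS))


def write_influence(results: Iterable[InfluenceResult], path: str | Path) -> None:
    influence_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")
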