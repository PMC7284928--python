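"""Per-gene meta-analysis of study-level log2 fold-changes ("mega-analysis").

For each gene measured in at least ``min_k`` studies:

* **fixed effects** — inverse-variance pooling, weights ``w_i = 1/var_i``;
* **heterogeneity** — Cochran's ``Q = Σ w_i (y_i − ŷ_F)²`` with
  ``df = k − 1``, ``I² = max(0, 100·(Q − df)/Q)`` and an upper-tail
  chi-square p-value for Q;
* **random effects** — DerSimonian–Laird: between-study variance
  ``τ² = max(0, (Q − df)/(Σw − Σw²/Σw))`` and re-weighting by
  ``1/(var_i + τ²)``.

Model selection follows the rule that heterogeneity no larger than its
expectation is treated as absent: when ``Q ≤ df`` (equivalently ``I² = 0``)
the fixed-effects model is selected, otherwise the random-effects model.
Two-sided p-values use the normal approximation ``z = pooled/se``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effect_size import GeneEffect

logger = logging.getLogger(__name__)

FIXED = "fixed"
RANDOM = "random"

_P_FLOOR = 5e-324  # smallest subnormal; keeps p strictly positive

META_COLUMNS = ("gene", "model", "k", "lfc", "se", "p_value",
                "q_stat", "df", "i_sq", "p_q", "tau_sq")


@dataclass(frozen=True)
class MetaResult:
    """Pooled per-gene result with heterogeneity statistics."""

    gene: str
    k: int
    pooled_lfc: float
    se: float
    p_value: float
    q_stat: float
    df: int
    i_sq: float
    p_q: float
    tau_sq: float
    model: str  # "fixed" | "random"


def _check_effects(effects: Sequence[GeneEffect], min_k: int) -> tuple[np.ndarray, np.ndarray]:
    if len(effects) < min_k:
        raise ValueError(f"need at least {min_k} studies, got {len(effects)}")
    y = np.array([e.lfc for e in effects], dtype=float)
    v = np.array([e.var for e in effects], dtype=float)
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    return y, v


def fixed_effects(effects: Sequence[GeneEffect]) -> tuple[float, float]:
    """Inverse-variance pooled estimate and its standard error."""
    y, v = _check_effects(effects, 1)
    w = 1.0 / v
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    return pooled, se


def heterogeneity(
    effects: Sequence[GeneEffect], pooled_fixed: float
) -> tuple[float, int, float, float]:
    """Cochran's Q, its df, I² (%) and the chi-square upper-tail p of Q."""
    y, v = _check_effects(effects, 2)
    w = 1.0 / v
    q = float(np.sum(w * (y - pooled_fixed) ** 2))
    df = len(effects) - 1
    i_sq = 0.0 if q <= df else 100.0 * (q - df) / q
    p_q = float(stats.chi2.sf(q, df))
    return q, df, i_sq, p_q


def random_effects(effects: Sequence[GeneEffect]) -> tuple[float, float, float]:
    """DerSimonian–Laird pooled estimate, standard error and τ²."""
    y, v = _check_effects(effects, 2)
    w = 1.0 / v
    pooled_f = float(np.sum(w * y) / np.sum(w))
    q, df, _, _ = heterogeneity(effects, pooled_f)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau_sq = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (v + tau_sq)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(math.sqrt(1.0 / np.sum(w_star)))
    return pooled, se, tau_sq


def pool_gene(
    effects: Sequence[GeneEffect],
    gene: str | None = None,
    het_p_threshold: float | None = None,
) -> MetaResult:
    """Pool one gene: fixed fit, heterogeneity, DL random fit, model choice.

    Default selection rule: fixed effects iff ``Q ≤ df`` (heterogeneity no
    larger than its expectation, i.e. ``I² = 0``). Passing
    ``het_p_threshold`` switches to a significance-based rule — fixed
    effects iff ``p_Q > het_p_threshold`` — under which mild, non-significant
    heterogeneity still uses the common-effect model. ``tau²`` is reported
    as 0 whenever the fixed model is selected.
    """
    y, v = _check_effects(effects, 2)
    gene = gene or effects[0].gene
    pooled_f, se_f = fixed_effects(effects)
    q, df, i_sq, p_q = heterogeneity(effects, pooled_f)
    use_fixed = (q <= df) if het_p_threshold is None else (p_q > het_p_threshold)
    if use_fixed:
        pooled, se, tau_sq, model = pooled_f, se_f, 0.0, FIXED
    else:
        pooled, se, tau_sq = random_effects(effects)
        model = RANDOM
    z = pooled / se if se > 0 else math.inf * np.sign(pooled)
    p = max(float(2.0 * stats.norm.sf(abs(z))), _P_FLOOR) if pooled != 0 else 1.0
    return MetaResult(gene, len(effects), pooled, se, p, q, df, i_sq, p_q, tau_sq, model)


def mega_analyze(
    effects_by_gene: Mapping[str, Sequence[GeneEffect]],
    min_k: int = 2,
    het_p_threshold: float | None = None,
) -> dict[str, MetaResult]:
    """Pool every gene measured in at least ``min_k`` studies.

    Genes with fewer studies are omitted (their count is logged): a pooled
    estimate from a single study would have no heterogeneity assessment.
    ``het_p_threshold`` is forwarded to :func:`pool_gene`.
    """
    if min_k < 2:
        raise ValueError(f"min_k must be ≥ 2, got {min_k}")
    results: dict[str, MetaResult] = {}
    n_omitted = 0
    for gene, effects in effects_by_gene.items():
        if len(effects) < min_k:
            n_omitted += 1
            continue
        results[gene] = pool_gene(effects, gene, het_p_threshold=het_p_threshold)
    if n_omitted:
        logger.info("%d gene(s) measured in fewer than %d studies omitted from pooling",
                    n_omitted, min_k)
    return results


def bh_adjust(results: Mapping[str, MetaResult]) -> dict[str, float]:
    """Optional Benjamini–Hochberg adjustment of pooled p-values.

    Off by default in the gene filter (the network filter uses raw p);
    provided for callers who want FDR control across all pooled genes.
    """
    from statsmodels.stats.multitest import multipletests

    genes = list(results)
    if not genes:
        return {}
    _, q, _, _ = multipletests([results[g].p_value for g in genes], method="fdr_bh")
    return dict(zip(genes, map(float, q)))


def meta_frame(results: Mapping[str, MetaResult]) -> pd.DataFrame:
    """Results as a DataFrame mirroring the on-disk schema (model flag 0/1)."""
    rows = [
        {
            "gene": r.gene,
            "model": 1 if r.model == RANDOM else 0,
            "k": r.k,
            "lfc": r.pooled_lfc,
            "se": r.se,
            "p_value": r.p_value,
            "q_stat": r.q_stat,
            "df": r.df,
            "i_sq": r.i_sq,
            "p_q": r.p_q,
            "tau_sq": r.tau_sq,
        }
        for r in sorted(results.values(), key=lambda r: r.gene)
    ]
    return pd.DataFrame(rows, columns=list(META_COLUMNS))


def write_meta(results: Mapping[str, MetaResult], path: str | Path) -> None:
    meta_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_meta(path: str | Path) -> dict[str, MetaResult]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, MetaResult] = {}
    for row in df.itertuples(index=False):
        out[str(row.gene)] = MetaResult(
            gene=str(row.gene), k=int(row.k), pooled_lfc=float(row.lfc),
            se=float(row.se), p_value=float(row.p_value), q_stat=float(row.q_stat),
            df=int(row.df), i_sq=float(row.i_sq), p_q=float(row.p_q),
            tau_sq=float(row.tau_sq), model=RANDOM if int(row.model) else FIXED,
        )
    return out
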