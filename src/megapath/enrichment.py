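"""Gene-set over-representation with hypergeometric p, Jaccard similarity and
Benjamini–Hochberg FDR.

Each collection set is tested one-sidedly for over-representation of the
query genes: with a background universe of ``N`` genes, ``K`` of which belong
to the set, and a query of ``n`` genes drawn from the universe, the p-value
is the hypergeometric upper tail ``P(X ≥ overlap)``. The Jaccard similarity
``|A∩B| / |A∪B|`` between query and set is reported alongside. FDR q-values
are computed across the whole collection before any significance filter.

The background defaults to the union of all collection members; callers with
a defined assay universe should override it, since the p-values (not the
Jaccard values) depend on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .relations import normalize_symbol

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ("set_id", "name", "set_size", "overlap",
                      "p_value", "q_value", "jaccard")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over a common background universe."""

    sets: Mapping[str, GeneSet]
    background: frozenset[str]

    def restricted(self, background: Iterable[str]) -> "GeneSetCollection":
        """Re-universe the collection; members outside it are dropped (logged)."""
        bg = frozenset(normalize_symbol(g) for g in background)
        new_sets: dict[str, GeneSet] = {}
        dropped = 0
        for sid, s in self.sets.items():
            kept = s.members & bg
            dropped += len(s.members) - len(kept)
            if kept:
                new_sets[sid] = GeneSet(sid, s.name, kept)
        if dropped:
            logger.info("%d set member(s) outside the background dropped", dropped)
        return GeneSetCollection(new_sets, bg)


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    set_name: str
    set_size: int
    overlap: int
    p_value: float
    q_value: float
    jaccard: float


class GmtError(ValueError):
    """Malformed GMT file."""


def read_gmt(path: str | Path, background: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``id<TAB>description<TAB>genes…``.

    Duplicate genes within a line are deduplicated; the background defaults
    to the union of all members unless overridden.
    """
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtError(f"{path}:{lineno}: expected ≥ 3 tab-separated fields")
            set_id, name, *genes = fields
            members = frozenset(normalize_symbol(g) for g in genes if g.strip())
            if not members:
                raise GmtError(f"{path}:{lineno}: set {set_id!r} has no members")
            sets[set_id] = GeneSet(set_id, name, members)
    if not sets:
        raise GmtError(f"{path}: no gene sets")
    collection = GeneSetCollection(
        sets, frozenset().union(*(s.members for s in sets.values()))
    )
    if background is not None:
        collection = collection.restricted(background)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in collection.sets.values():
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")


def jaccard(query_size: int, set_size: int, overlap: int) -> float:
    """Jaccard similarity from the three counts: overlap / union size."""
    if overlap > min(query_size, set_size):
        raise ValueError(
            f"overlap {overlap} exceeds a set size ({query_size}, {set_size})"
        )
    if min(query_size, set_size, overlap) < 0:
        raise ValueError("counts must be non-negative")
    union = query_size + set_size - overlap
    return overlap / union if union else 0.0


def hypergeom_upper_tail(population: int, successes: int, draws: int, overlap: int) -> float:
    """P(X ≥ overlap) for a hypergeometric draw (one-sided over-representation)."""
    return float(stats.hypergeom.sf(overlap - 1, population, successes, draws))


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha_p: float = 0.005,
    alpha_q: float = 0.005,
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in every collection set.

    The query is restricted to the background before testing (dropped genes
    logged; an empty restricted query is an error). BH q-values are computed
    across the whole collection, then results are filtered to
    ``p < alpha_p`` and ``q < alpha_q`` and sorted by (p, set_id). Pass
    ``alpha_p = alpha_q = 1.1`` to retrieve all sets unfiltered.
    """
    q_genes = frozenset(normalize_symbol(g) for g in query)
    if not q_genes:
        raise ValueError("empty query")
    in_bg = q_genes & collection.background
    n_outside = len(q_genes) - len(in_bg)
    if n_outside:
        logger.info("%d query gene(s) outside the background dropped", n_outside)
    if not in_bg:
        raise ValueError("no query gene is in the background universe")

    n_pop = len(collection.background)
    n_query = len(in_bg)
    records = []
    for sid in sorted(collection.sets):
        s = collection.sets[sid]
        members = s.members & collection.background
        overlap = len(in_bg & members)
        p = hypergeom_upper_tail(n_pop, len(members), n_query, overlap)
        records.append((s, len(members), overlap, p))
    _, q_values, _, _ = multipletests([r[3] for r in records], method="fdr_bh")
    results = [
        EnrichmentResult(
            s.set_id, s.name, size, overlap, p, float(qv),
            jaccard(n_query, size, overlap),
        )
        for (s, size, overlap, p), qv in zip(records, q_values)
    ]
    results = [r for r in results if r.p_value < alpha_p and r.q_value < alpha_q]
    return sorted(results, key=lambda r: (r.p_value, r.set_id))


def enrichment_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "set_id": r.set_id, "name": r.set_name, "set_size": r.set_size,
            "overlap": r.overlap, "p_value": r.p_value, "q_value": r.q_value,
            "jaccard": r.jaccard,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=list(ENRICHMENT_COLUMNS))


def write_enrichment(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    enrichment_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")
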